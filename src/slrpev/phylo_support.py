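"""Dual branch-support parsing and clade-support classification.

Maximum-likelihood gene trees in this workflow carry two support measures
on internal nodes, written as "SH-aLRT/UFBoot" labels (e.g. "96.7/99").
Node support is classified by the display convention used for SLRP trees:
*strong* when both values exceed 95, *moderate* when both exceed 85, and
*weak* otherwise (strict comparisons, so 95 exactly is not strong).
Orthology-group statements are clade-plus-support claims, tested with
:func:`supported_monophyly` on the rooted tree as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import dendropy

CATEGORY_RANK = {"weak": 0, "moderate": 1, "strong": 2}


class SupportParseError(ValueError):
    """Raised when an internal node label is not a valid 'x/y' support pair."""


@dataclass(frozen=True)
class NodeSupport:
    sh_alrt: float
    ufboot: float

    def __post_init__(self) -> None:
        for value, name in ((self.sh_alrt, "SH-aLRT"), (self.ufboot, "UFBoot")):
            if not 0.0 <= value <= 100.0:
                raise SupportParseError(
                    f"{name} value {value} outside [0, 100]"
                )


class SupportTree:
    """A tree whose internal nodes may carry (SH-aLRT, UFBoot) support."""

    def __init__(self, tree: dendropy.Tree) -> None:
        self.tree = tree
        self.support: dict[dendropy.Node, Optional[NodeSupport]] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            label = node.label
            if label is None or label == "":
                self.support[node] = None
                continue
            parts = label.split("/")
            if len(parts) != 2:
                raise SupportParseError(
                    f"internal node label {label!r} is not an "
                    f"'SH-aLRT/UFBoot' pair (near tips "
                    f"{[l.taxon.label for l in node.leaf_iter()][:3]})"
                )
            try:
                sh, uf = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SupportParseError(
                    f"non-numeric support in node label {label!r}"
                ) from exc
            self.support[node] = NodeSupport(sh, uf)

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_support_labels(source: str | Path) -> SupportTree:
    """Parse a newick tree (string or file path) with 'x/y' support labels."""
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    tree.is_rooted = True  # rooting is taken as given in the input
    return SupportTree(tree)


def classify_support(support: NodeSupport | tuple[float, float]) -> str:
    """'strong' if both supports > 95, 'moderate' if both > 85, else 'weak'."""
    if support is None:
        raise ValueError("node has no support values")
    if isinstance(support, tuple):
        support = NodeSupport(*support)
    if support.sh_alrt > 95 and support.ufboot > 95:
        return "strong"
    if support.sh_alrt > 85 and support.ufboot > 85:
        return "moderate"
    return "weak"


def supported_monophyly(
    stree: SupportTree,
    tips: Sequence[str],
    min_category: str = "strong",
) -> bool:
    """True iff ``tips`` form a clade whose stem support reaches the category.

    Monophyly is evaluated on the rooted tree as given.  The stem node of
    the clade must carry support classified at or above ``min_category``.
    Unknown tips are an error listing them.
    """
    if min_category not in CATEGORY_RANK:
        raise ValueError(f"unknown support category {min_category!r}")
    known = set(stree.tip_names)
    unknown = sorted(set(tips) - known)
    if unknown:
        raise ValueError(f"tips not in tree: {unknown}")
    mrca = stree.tree.mrca(taxon_labels=list(tips))
    clade_tips = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    if clade_tips != set(tips):
        return False
    support = stree.support.get(mrca)
    if support is None:
        return False
    return CATEGORY_RANK[classify_support(support)] >= CATEGORY_RANK[min_category]


def node_classification_report(stree: SupportTree) -> list[dict]:
    """One row per supported internal node: values and category."""
    rows = []
    for i, (node, support) in enumerate(stree.support.items()):
        if support is None:
            continue
        rows.append(
            {
                "node": i,
                "tips": ",".join(
                    sorted(l.taxon.label for l in node.leaf_iter())[:4]
                ),
                "sh_alrt": support.sh_alrt,
                "ufboot": support.ufboot,
                "category": classify_support(support),
            }
        )
    return rows
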