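"""Cluster amplification by tandem duplication, WGD inheritance, and loss.

The canonical SLRP clusters of jawed vertebrates (A-D) are modeled as the
outcome of a small number of events on a lineage tree of gene clusters:
the default "2R tree" has a stem leading to the pre-1R ancestor R, a first
whole-genome duplication producing the A/B and C/D ancestral clusters, and
a second round producing the four extant clusters.  A *scenario* is a root
cluster composition (one gene lineage per clade) plus ordered tandem
duplication and loss events on named branches; WGD nodes pass the whole
cluster to both children, so replay is deterministic inheritance with
per-branch edits.

Two searches are provided, both exact:

* :func:`min_tandem_duplications` — minimal number of tandem duplications
  explaining per-cluster copy counts for one clade, with losses free.
* :func:`infer_parsimony_scenario` — full reconstruction from observed
  per-cluster gene compositions under orthology-group and timing
  constraints, minimizing duplications first, then losses, with a
  deterministic preorder tie-break.

Because duplications copy a lineage within its own clade and losses hit a
single lineage, clades never interact: the optimizer decomposes per clade,
which keeps the exhaustive search exact and fast at the family sizes this
model is meant for (a handful of lineages per clade).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

__all__ = [
    "HistoryTree",
    "TandemDup",
    "Loss",
    "Scenario",
    "ScenarioError",
    "ObservedFamily",
    "TimingConstraint",
    "InfeasibleConstraints",
    "InferenceResult",
    "default_2r_tree",
    "canonical_scenario",
    "canonical_slrp_family",
    "replay",
    "min_tandem_duplications",
    "infer_parsimony_scenario",
    "check_2r_topology",
]


class ScenarioError(ValueError):
    """Raised when a scenario is structurally invalid for its history."""


class HistoryTree:
    """A rooted tree of cluster lineages; branches are named by child node.

    Nodes must have zero or two children (a single-node tree is allowed).
    ``aliases`` maps alternative branch names (e.g. ``"stem"``) onto
    canonical child-node names.
    """

    def __init__(
        self,
        parent: Mapping[str, Optional[str]],
        aliases: Optional[Mapping[str, str]] = None,
    ) -> None:
        roots = [n for n, p in parent.items() if p is None]
        if len(roots) != 1:
            raise ScenarioError(f"history tree needs exactly one root, got {roots}")
        self.parent = dict(parent)
        self.root = roots[0]
        self.children: dict[str, list[str]] = {n: [] for n in parent}
        for node, par in parent.items():
            if par is not None:
                if par not in parent:
                    raise ScenarioError(f"unknown parent node {par!r} for {node!r}")
                self.children[par].append(node)
        for node, kids in self.children.items():
            if len(kids) > 2:
                raise ScenarioError(
                    f"history tree must be binary; node {node!r} has "
                    f"{len(kids)} children"
                )
        self.aliases = dict(aliases or {})
        self._preorder = self._compute_preorder()
        self._subtree: dict[str, frozenset[str]] = {}
        for node in reversed(self._preorder):
            nodes = {node}
            for c in self.children[node]:
                nodes |= self._subtree[c]
            self._subtree[node] = frozenset(nodes)

    def _compute_preorder(self) -> list[str]:
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.children[node]))
        if len(order) != len(self.parent):
            raise ScenarioError("history tree is disconnected")
        return order

    @property
    def preorder(self) -> list[str]:
        return list(self._preorder)

    @property
    def tips(self) -> list[str]:
        return [n for n in self._preorder if not self.children[n]]

    @property
    def branches(self) -> list[str]:
        """Non-root nodes in preorder; each names the branch above it."""
        return [n for n in self._preorder if n != self.root]

    def resolve_branch(self, name: str) -> str:
        branch = self.aliases.get(name, name)
        if branch not in self.parent or branch == self.root:
            raise ScenarioError(f"unknown branch {name!r}")
        return branch

    def subtree_nodes(self, node: str) -> frozenset[str]:
        return self._subtree[node]

    def subtree_tips(self, node: str) -> frozenset[str]:
        return frozenset(n for n in self._subtree[node] if not self.children[n])

    def on_path(self, branch: str, tip: str) -> bool:
        """True if ``branch`` lies on the root-to-``tip`` path."""
        return tip in self._subtree[branch]


def default_2r_tree() -> HistoryTree:
    """The gnathostome 2R history: stem -> R -> {AB, CD} -> {A, B, C, D}."""
    return HistoryTree(
        {
            "root": None,
            "R": "root",
            "AB": "R",
            "CD": "R",
            "A": "AB",
            "B": "AB",
            "C": "CD",
            "D": "CD",
        },
        aliases={"stem": "R"},
    )


@dataclass(frozen=True)
class TandemDup:
    """Tandem duplication on ``branch``: ``parent`` lineage spawns ``child``."""

    branch: str
    parent: str
    child: str


@dataclass(frozen=True)
class Loss:
    """Loss of ``lineage`` on ``branch`` (removed from the whole subtree)."""

    branch: str
    lineage: str


Event = Union[TandemDup, Loss]


@dataclass(frozen=True)
class Scenario:
    """A replayable event history on a :class:`HistoryTree`."""

    root_composition: tuple[tuple[str, str], ...]  # (clade, lineage) pairs
    events: tuple[Event, ...] = ()

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if isinstance(e, TandemDup))

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if isinstance(e, Loss))

    @property
    def clade_of_root_lineage(self) -> dict[str, str]:
        return {lineage: clade for clade, lineage in self.root_composition}

    def to_dict(self) -> dict:
        return {
            "root_composition": [list(pair) for pair in self.root_composition],
            "events": [
                (
                    {"type": "tandem_dup", "branch": e.branch,
                     "parent": e.parent, "child": e.child}
                    if isinstance(e, TandemDup)
                    else {"type": "loss", "branch": e.branch,
                          "lineage": e.lineage}
                )
                for e in self.events
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, data: Mapping) -> "Scenario":
        events: list[Event] = []
        for ev in data.get("events", []):
            if ev["type"] == "tandem_dup":
                events.append(TandemDup(ev["branch"], ev["parent"], ev["child"]))
            elif ev["type"] == "loss":
                events.append(Loss(ev["branch"], ev["lineage"]))
            else:
                raise ScenarioError(f"unknown event type {ev['type']!r}")
        return cls(
            root_composition=tuple(
                (clade, lineage) for clade, lineage in data["root_composition"]
            ),
            events=tuple(events),
        )


def canonical_scenario() -> Scenario:
    """The hypothesized amplification scenario of the canonical SLRPs.

    Starting from one lineage per clade (c1, c2, c3a, c4), a stem tandem
    duplication creates the Clade 3b lineage before 1R (yielding the
    five-gene vertebrate ancestral cluster), the A/B ancestor loses 3a,
    a second tandem duplication on the C/D branch creates 3a', and
    cluster-specific losses produce the four extant compositions.
    """
    return Scenario(
        root_composition=(("1", "c1"), ("2", "c2"), ("3", "c3a"), ("4", "c4")),
        events=(
            TandemDup("R", "c3a", "c3b"),
            Loss("AB", "c3a"),
            TandemDup("CD", "c3a", "c3a'"),
            Loss("B", "c3b"),
            Loss("B", "c4"),
            Loss("C", "c3a'"),
            Loss("D", "c1"),
        ),
    )


def replay(
    scenario: Scenario, history: HistoryTree
) -> dict[str, tuple[str, ...]]:
    """Replay a scenario, returning the composition at every node.

    Compositions are ordered lineage tuples (a new tandem copy is inserted
    next to its parent lineage).  Raises :class:`ScenarioError` naming the
    offending event if an event references a lineage absent on its branch.
    """
    events_by_branch: dict[str, list[Event]] = {}
    for ev in scenario.events:
        branch = history.resolve_branch(ev.branch)
        events_by_branch.setdefault(branch, []).append(ev)
    comp: dict[str, tuple[str, ...]] = {}
    root_lineages = [lineage for _, lineage in scenario.root_composition]
    if len(set(root_lineages)) != len(root_lineages):
        raise ScenarioError("duplicate lineage labels in root composition")
    comp[history.root] = tuple(root_lineages)
    for node in history.preorder:
        if node == history.root:
            continue
        current = list(comp[history.parent[node]])
        for ev in events_by_branch.get(node, []):
            if isinstance(ev, TandemDup):
                if ev.parent not in current:
                    raise ScenarioError(
                        f"duplication event {ev} references lineage "
                        f"{ev.parent!r} absent on branch {node!r}"
                    )
                if ev.child in current:
                    raise ScenarioError(
                        f"duplication event {ev} re-creates existing lineage "
                        f"{ev.child!r}"
                    )
                current.insert(current.index(ev.parent) + 1, ev.child)
            else:
                if ev.lineage not in current:
                    raise ScenarioError(
                        f"loss event {ev} references lineage "
                        f"{ev.lineage!r} absent on branch {node!r}"
                    )
                current.remove(ev.lineage)
        comp[node] = tuple(current)
    return comp


def min_tandem_duplications(
    counts: Mapping[str, int],
    history: HistoryTree,
    clade: str = "3",
) -> tuple[int, Scenario]:
    """Minimal tandem duplications explaining per-tip copy counts (losses free).

    Each duplication on a branch adds one copy to every descendant tip, so a
    tip observed with ``c`` copies needs at least ``c - 1`` duplications on
    its root-to-tip path.  The search enumerates duplication placements in
    increasing number until every tip is covered; the returned witness
    scenario replays to at least the observed counts at every tip.
    """
    for tip, c in counts.items():
        if tip not in history.tips:
            raise ValueError(f"unknown tip {tip!r}")
        if c < 0:
            raise ValueError(f"negative copy count for tip {tip!r}")
    branches = history.branches
    tips = [t for t in history.tips]
    needed = {t: max(0, counts.get(t, 0) - 1) for t in tips}
    lower = max(needed.values(), default=0)
    upper = sum(needed.values())
    root_lineage = f"{clade}.1"

    def witness(placement: Sequence[str]) -> Scenario:
        events = []
        for i, branch in enumerate(
            sorted(placement, key=history.branches.index), start=1
        ):
            events.append(TandemDup(branch, root_lineage, f"{clade}.{i + 1}"))
        return Scenario(
            root_composition=((clade, root_lineage),), events=tuple(events)
        )

    for d in range(lower, upper + 1):
        for placement in itertools.combinations_with_replacement(branches, d):
            ok = all(
                sum(1 for b in placement if history.on_path(b, tip)) >= needed[tip]
                for tip in tips
            )
            if ok:
                return d, witness(placement)
    return upper, witness([])  # unreachable: upper always covers


@dataclass(frozen=True)
class TimingConstraint:
    """Requires ``lineage`` (an orthology-group name) to exist at ``node``."""

    lineage: str
    node: str


class InfeasibleConstraints(Exception):
    """Raised when no scenario can satisfy the supplied constraints."""

    def __init__(self, message: str, constraint: Optional[TimingConstraint] = None):
        super().__init__(message)
        self.constraint = constraint


@dataclass
class ObservedFamily:
    """Observed per-cluster gene compositions plus orthology groups.

    ``tips`` maps each tip (extant cluster) to ``{gene_name: clade_label}``.
    ``orthology_groups`` maps a lineage name to the genes required to
    descend from a single lineage at their last common ancestral node.
    Gene names must be unique across tips; a gene belongs to at most one
    group, and all genes of a group must share a clade label.
    """

    tips: dict[str, dict[str, str]]
    orthology_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for tip, genes in self.tips.items():
            for gene in genes:
                if gene in seen:
                    raise ValueError(
                        f"gene name {gene!r} appears in tips "
                        f"{seen[gene]!r} and {tip!r}; names must be unique"
                    )
                seen[gene] = tip
        grouped: set[str] = set()
        for name, genes in self.orthology_groups.items():
            clades = set()
            for gene in genes:
                if gene not in seen:
                    raise ValueError(
                        f"orthology group {name!r} references unknown gene "
                        f"{gene!r}"
                    )
                if gene in grouped:
                    raise ValueError(
                        f"gene {gene!r} belongs to more than one orthology group"
                    )
                grouped.add(gene)
                clades.add(self.clade_of_gene(gene))
            if len(clades) > 1:
                raise ValueError(
                    f"orthology group {name!r} mixes clades {sorted(clades)}"
                )

    def tip_of_gene(self, gene: str) -> str:
        for tip, genes in self.tips.items():
            if gene in genes:
                return tip
        raise KeyError(gene)

    def clade_of_gene(self, gene: str) -> str:
        return self.tips[self.tip_of_gene(gene)][gene]

    @property
    def clades(self) -> list[str]:
        return sorted({c for genes in self.tips.values() for c in genes.values()})

    def ungrouped_genes(self) -> list[str]:
        grouped = {g for genes in self.orthology_groups.values() for g in genes}
        return [
            gene
            for tip in self.tips
            for gene in self.tips[tip]
            if gene not in grouped
        ]


def canonical_slrp_family() -> tuple[ObservedFamily, tuple[TimingConstraint, ...]]:
    """The four gnathostome canonical-SLRP cluster compositions.

    Tip compositions follow the conserved cluster gene lists (cluster A:
    ecm2, aspn, omd, ogn; B: ecmX, bgn; C: ecm2L, dcn1, lum, kera, epyc;
    D: fmod, dcn2, lumL, prelp, optc), with orthology groups from the
    per-clade gene phylogenies and timing constraints carrying the
    cyclostome evidence: the Clade 3a and 3b lineages already existed in
    the pre-1R ancestor, and the lumL lineage (3a') existed in the C/D
    ancestral cluster.
    """
    family = ObservedFamily(
        tips={
            "A": {"ecm2": "1", "aspn": "2", "omd": "3", "ogn": "4"},
            "B": {"ecmX": "1", "bgn": "2"},
            "C": {"ecm2L": "1", "dcn1": "2", "lum": "3", "kera": "3", "epyc": "4"},
            "D": {"fmod": "3", "dcn2": "2", "lumL": "3", "prelp": "3", "optc": "4"},
        },
        orthology_groups={
            "c1": ("ecm2", "ecmX", "ecm2L"),
            "c2": ("aspn", "bgn", "dcn1", "dcn2"),
            "3a": ("lum", "fmod"),
            "3a'": ("lumL",),
            "3b": ("omd", "kera", "prelp"),
            "c4": ("ogn", "epyc", "optc"),
        },
    )
    constraints = (
        TimingConstraint("3a", "R"),
        TimingConstraint("3b", "R"),
        TimingConstraint("3a'", "CD"),
    )
    return family, constraints


@dataclass
class InferenceResult:
    """Most parsimonious scenario plus its replayed node compositions."""

    scenario: Scenario
    node_compositions: dict[str, tuple[str, ...]]
    n_duplications: int
    n_losses: int


# ---------------------------------------------------------------------------
# parsimony inference internals


@dataclass(frozen=True)
class _Lineage:
    name: str
    clade: str
    present_tips: frozenset[str]
    timing_nodes: frozenset[str]


_INF = 10**9


def _min_losses_for_lineage(
    history: HistoryTree,
    creation_node: str,
    lineage: _Lineage,
) -> tuple[int, list[Loss]]:
    """Minimal losses placing ``lineage`` exactly on its present tips.

    The lineage exists from ``creation_node`` downward; it must be present
    at every tip in ``present_tips``, absent at every other descendant
    tip, and alive at every timing node.  Returns (cost, loss events), or
    cost ``_INF`` when impossible (e.g. a timing node inside a subtree
    with no surviving tips at a tip position).
    """
    required = lineage.present_tips | lineage.timing_nodes

    def subtree_has_required(node: str) -> bool:
        return bool(history.subtree_nodes(node) & required)

    def rec(node: str) -> tuple[int, list[Loss]]:
        # lineage alive entering the branch above `node`
        is_tip = not history.children[node]
        can_lose = not subtree_has_required(node)
        if is_tip:
            if node in lineage.present_tips:
                return 0, []
            if node in lineage.timing_nodes:
                return _INF, []  # must exist at a tip where it is not observed
            return 1, [Loss(node, lineage.name)]
        keep_cost = 0
        keep_losses: list[Loss] = []
        for child in history.children[node]:
            c, l = rec(child)
            keep_cost += c
            keep_losses.extend(l)
        if can_lose and 1 <= keep_cost:
            return 1, [Loss(node, lineage.name)]
        return keep_cost, keep_losses

    if not history.children[creation_node]:
        if creation_node in lineage.present_tips:
            return 0, []
        return _INF, []
    cost = 0
    losses: list[Loss] = []
    for child in history.children[creation_node]:
        c, l = rec(child)
        if c >= _INF:
            return _INF, []
        cost += c
        losses.extend(l)
    return cost, losses


def _partitions(
    items: list[tuple[str, frozenset[str], bool]],
) -> "list[list[list[int]]]":
    """All set partitions of item indices, blocks tip-disjoint, <=1 explicit.

    ``items`` holds (name, tip_set, is_explicit_group).  Explicit orthology
    groups are never merged with one another; ungrouped genes may join any
    block whose tip set is disjoint from theirs.
    """
    result: list[list[list[int]]] = []
    n = len(items)

    def extend(i: int, blocks: list[list[int]]) -> None:
        if i == n:
            result.append([list(b) for b in blocks])
            return
        name, tips_i, explicit_i = items[i]
        for block in blocks:
            block_tips = frozenset().union(*(items[j][1] for j in block))
            block_explicit = any(items[j][2] for j in block)
            if tips_i & block_tips:
                continue
            if explicit_i and block_explicit:
                continue
            block.append(i)
            extend(i + 1, blocks)
            block.pop()
        blocks.append([i])
        extend(i + 1, blocks)
        blocks.pop()

    extend(0, [])
    return result


def _lineage_alive_at(
    history: HistoryTree,
    creation_node: str,
    losses: Sequence[Loss],
    lineage_name: str,
    node: str,
) -> bool:
    """True if the lineage exists at ``node`` given its creation and losses."""
    if node not in history.subtree_nodes(creation_node):
        return False
    for loss in losses:
        if loss.lineage == lineage_name and node in history.subtree_nodes(
            loss.branch
        ):
            return False
    return True


def _assign_dup_parents(
    history: HistoryTree,
    root_lin: _Lineage,
    root_losses: Sequence[Loss],
    created: list[tuple[_Lineage, str, list[Loss]]],  # (lineage, branch, losses)
) -> Optional[list[TandemDup]]:
    """Pick a valid parent for every duplication, or None if impossible.

    A duplication on branch b may copy any same-clade lineage alive at the
    top of b, or one created earlier on b itself.  Candidates are tried in
    deterministic order (root lineage first, then by name).
    """
    losses_by_name: dict[str, list[Loss]] = {root_lin.name: list(root_losses)}
    creation_of: dict[str, str] = {root_lin.name: history.root}
    for lin, branch, lin_losses in created:
        losses_by_name[lin.name] = list(lin_losses)
        creation_of[lin.name] = branch
    dups: list[TandemDup] = []
    for lin, branch, _ in created:
        top = history.parent[branch]
        candidates = [root_lin.name] + sorted(
            l.name for l, _, _ in created if l.name != lin.name
        )
        parent = None
        for cand in candidates:
            if cand == lin.name:
                continue
            alive_at_top = _lineage_alive_at(
                history, creation_of[cand], losses_by_name[cand], cand, top
            )
            same_branch = creation_of[cand] == branch and cand != lin.name
            if alive_at_top or same_branch:
                parent = cand
                break
        if parent is None:
            return None
        dups.append(TandemDup(branch, parent, lin.name))
    return dups


def _solve_clade(
    history: HistoryTree,
    clade: str,
    group_genes: dict[str, tuple[str, ...]],
    group_tips: dict[str, frozenset[str]],
    ungrouped: list[tuple[str, str]],  # (gene, tip)
    timing: dict[str, frozenset[str]],  # group name -> required nodes
) -> tuple[int, int, list[TandemDup], list[Loss], dict[str, str]]:
    """Exact per-clade optimum: (dups, losses, dup events, loss events,
    gene -> lineage name)."""
    items: list[tuple[str, frozenset[str], bool]] = [
        (name, tips, True) for name, tips in sorted(group_tips.items())
    ] + [(gene, frozenset({tip}), False) for gene, tip in sorted(ungrouped)]
    if not items:
        return 0, 0, [], [], {}
    branch_order = {b: i for i, b in enumerate(history.branches)}

    partitions = sorted(_partitions(items), key=len)
    best: Optional[tuple] = None
    first_feasible_size: Optional[int] = None
    infeasible_reason: Optional[str] = None

    for blocks in partitions:
        if first_feasible_size is not None and len(blocks) > first_feasible_size:
            break
        lineages = []
        for block in blocks:
            names = [items[i][0] for i in block if items[i][2]]
            name = names[0] if names else items[block[0]][0]
            tips = frozenset().union(*(items[i][1] for i in block))
            timing_nodes = frozenset().union(
                *(timing.get(items[i][0], frozenset()) for i in block)
            )
            lineages.append(_Lineage(name, clade, tips, timing_nodes))
        n_dups = len(lineages) - 1
        # enumerate the root lineage and creation branches for the rest
        for root_idx in range(len(lineages)):
            root_lin = lineages[root_idx]
            if root_lin.timing_nodes - history.subtree_nodes(history.root):
                continue
            others = [l for i, l in enumerate(lineages) if i != root_idx]
            choices: list[list[str]] = []
            feasible = True
            for lin in others:
                req = lin.present_tips | lin.timing_nodes
                valid = [
                    b for b in history.branches if req <= history.subtree_nodes(b)
                ]
                if not valid:
                    feasible = False
                    infeasible_reason = (
                        f"lineage {lin.name!r} must cover nodes {sorted(req)} "
                        f"but no single branch subtree contains them all"
                    )
                    break
                choices.append(valid)
            if not feasible:
                continue
            root_cost, root_losses = _min_losses_for_lineage(
                history, history.root, root_lin
            )
            if root_cost >= _INF:
                infeasible_reason = (
                    f"root lineage {root_lin.name!r} cannot satisfy its "
                    f"timing constraints"
                )
                continue
            for combo in itertools.product(*choices):
                total = root_cost
                losses = list(root_losses)
                created: list[tuple[_Lineage, str, list[Loss]]] = []
                valid_combo = True
                for lin, branch in zip(others, combo):
                    cost, lin_losses = _min_losses_for_lineage(
                        history, branch, lin
                    )
                    if cost >= _INF:
                        valid_combo = False
                        break
                    total += cost
                    losses.extend(lin_losses)
                    created.append((lin, branch, lin_losses))
                if not valid_combo:
                    continue
                dups = _assign_dup_parents(
                    history, root_lin, root_losses, created
                )
                if dups is None:
                    continue
                key = (
                    total,
                    tuple(
                        sorted(
                            (branch_order[d.branch], d.parent, d.child)
                            for d in dups
                        )
                    ),
                    tuple(
                        sorted(
                            (branch_order[l.branch], l.lineage) for l in losses
                        )
                    ),
                )
                if best is None or (n_dups, *key) < best[0]:
                    gene_to_lineage: dict[str, str] = {}
                    for block, lin in zip(blocks, lineages):
                        for i in block:
                            item_name, _, explicit = items[i]
                            if explicit:
                                for gene in group_genes[item_name]:
                                    gene_to_lineage[gene] = lin.name
                            else:
                                gene_to_lineage[item_name] = lin.name
                    best = ((n_dups, *key), dups, losses, gene_to_lineage)
                    first_feasible_size = len(blocks)
    if best is None:
        raise InfeasibleConstraints(
            infeasible_reason
            or f"no feasible scenario for clade {clade!r} under the "
            f"supplied constraints"
        )
    (n_dups, total, _, _), dups, losses, gene_to_lineage = best
    return n_dups, total, dups, losses, gene_to_lineage


def infer_parsimony_scenario(
    family: ObservedFamily,
    history: Optional[HistoryTree] = None,
    constraints: Sequence[TimingConstraint] = (),
) -> InferenceResult:
    """Reconstruct the most parsimonious amplification scenario.

    The objective is lexicographic: fewest tandem duplications, then
    fewest losses, then a deterministic canonical tie-break (earliest
    branches in preorder).  The root composition is fixed at one lineage
    per observed clade label, so clade-forming duplications are never
    free.  Raises :class:`InfeasibleConstraints` when the orthology/timing
    constraints cannot be satisfied.
    """
    if history is None:
        history = default_2r_tree()
    unknown_tips = set(family.tips) - set(history.tips)
    if unknown_tips:
        raise ValueError(f"observed tips not in history: {sorted(unknown_tips)}")
    group_names = set(family.orthology_groups)
    timing: dict[str, set[str]] = {}
    for c in constraints:
        if c.lineage not in group_names:
            raise ValueError(
                f"timing constraint references unknown orthology group "
                f"{c.lineage!r}"
            )
        node = history.aliases.get(c.node, c.node)
        if node not in history.parent:
            raise InfeasibleConstraints(
                f"timing constraint node {c.node!r} not in history", c
            )
        timing.setdefault(c.lineage, set()).add(node)

    all_dups: list[TandemDup] = []
    all_losses: list[Loss] = []
    gene_to_lineage: dict[str, str] = {}
    root_composition: list[tuple[str, str]] = []
    n_dups_total = 0
    n_losses_total = 0
    root_lineage_names: dict[str, str] = {}

    for clade in family.clades:
        clade_group_genes = {
            name: tuple(genes)
            for name, genes in family.orthology_groups.items()
            if genes and family.clade_of_gene(genes[0]) == clade
        }
        clade_group_tips = {
            name: frozenset(family.tip_of_gene(g) for g in genes)
            for name, genes in clade_group_genes.items()
        }
        clade_ungrouped = [
            (gene, family.tip_of_gene(gene))
            for gene in family.ungrouped_genes()
            if family.clade_of_gene(gene) == clade
        ]
        clade_timing = {
            name: frozenset(nodes)
            for name, nodes in timing.items()
            if name in clade_group_genes
        }
        d, l, dups, losses, mapping = _solve_clade(
            history,
            clade,
            clade_group_genes,
            clade_group_tips,
            clade_ungrouped,
            clade_timing,
        )
        n_dups_total += d
        n_losses_total += l
        all_dups.extend(dups)
        all_losses.extend(losses)
        gene_to_lineage.update(mapping)
        # the root lineage of the clade is the one no duplication creates
        created = {dup.child for dup in dups}
        lineage_names = set(mapping.values())
        root_name = sorted(lineage_names - created)[0] if lineage_names else None
        if root_name is not None:
            root_composition.append((clade, root_name))
            root_lineage_names[clade] = root_name

    branch_order = {b: i for i, b in enumerate(history.branches)}
    events: list[Event] = []
    for branch in history.branches:
        branch_dups = sorted(
            (d for d in all_dups if d.branch == branch),
            key=lambda d: (d.parent, d.child),
        )
        # parents created on the same branch must be emitted first
        emitted: list[TandemDup] = []
        pending = list(branch_dups)
        available = set(root_lineage_names.values()) | {
            d.child for d in all_dups if branch_order[d.branch] < branch_order[branch]
        }
        while pending:
            progress = False
            for d in list(pending):
                if d.parent in available:
                    emitted.append(d)
                    available.add(d.child)
                    pending.remove(d)
                    progress = True
            if not progress:
                emitted.extend(pending)
                break
        events.extend(emitted)
        events.extend(
            sorted(
                (l for l in all_losses if l.branch == branch),
                key=lambda l: l.lineage,
            )
        )
    scenario = Scenario(
        root_composition=tuple(sorted(root_composition)), events=tuple(events)
    )
    node_compositions = replay(scenario, history)
    # internal consistency: the witness must replay to the observed tips
    for tip, genes in family.tips.items():
        observed = {gene_to_lineage[g] for g in genes}
        replayed = set(node_compositions.get(tip, ()))
        if observed != replayed:
            raise AssertionError(
                f"inferred scenario does not replay tip {tip!r}: "
                f"{sorted(replayed)} vs observed {sorted(observed)}"
            )
    return InferenceResult(
        scenario=scenario,
        node_compositions=node_compositions,
        n_duplications=n_dups_total,
        n_losses=n_losses_total,
    )


def check_2r_topology(tree, labels: Optional[Mapping[str, str]] = None) -> bool:
    """Test whether a gene tree is compatible with the ((A,B),(C,D)) pattern.

    ``tree`` is a newick string or a ``dendropy.Tree`` whose tips are
    labeled (directly, or through ``labels``) by cluster in {A, B, C, D},
    at most one tip per cluster.  With three or fewer labeled tips any
    resolved topology is compatible (loss can explain the missing tip);
    with four, the induced unrooted quartet must not be AC|BD or AD|BC.
    """
    import dendropy

    if isinstance(tree, str):
        tree = dendropy.Tree.get(
            data=tree,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    tip_cluster: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else leaf.label
        cluster = labels.get(name) if labels is not None else name
        if cluster in ("A", "B", "C", "D"):
            if cluster in tip_cluster.values():
                raise ValueError(f"duplicate cluster label {cluster!r} among tips")
            tip_cluster[name] = cluster
    if len(tip_cluster) < 4:
        return True
    allowed = ({"A", "B"}, {"C", "D"})
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {
            tip_cluster[l.taxon.label if l.taxon else l.label]
            for l in node.leaf_iter()
            if (l.taxon.label if l.taxon else l.label) in tip_cluster
        }
        if len(below) == 2 and below not in allowed:
            return False
    return True
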