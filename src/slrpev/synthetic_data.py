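"""Ground-truth generators for every pipeline input.

Every stage of the toolkit can be exercised without downloads: this module
simulates (a) clustered gene families evolving by tandem duplication,
whole-genome duplication, and loss on a known history tree, emitting both
the per-tip gene coordinate tables and the true scenario; (b) proteins
carrying or lacking the LRRCE capping motif, built constructively from an
LRR consensus template so the motif post-conditions hold by design;
(c) TPM expression matrices with planted per-cell enrichment; and (d) qPCR
Cp tables with known fold changes that the normalization recovers exactly
at zero noise.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import motif
from .cluster_evolution import (
    HistoryTree,
    Loss,
    Scenario,
    TandemDup,
    ObservedFamily,
    canonical_scenario,
    default_2r_tree,
    replay,
)
from .synteny import GeneLocus

# Residues used to fill unconstrained positions in generated proteins.
# The set avoids C (so motif-free constructs can never satisfy the
# C-anchored LRRCE patterns) and the [FYMPVAIS] class letters (so relaxed
# constructs do not accidentally satisfy the standard C-terminal block).
_FILL_ALPHABET = "DEGHKQRTW"


@dataclass(frozen=True)
class ClusterSimConfig:
    """Forward-simulation settings for a clustered gene family.

    Rates are expected events per branch (Poisson); coordinates in the
    emitted tables are 1-based and inclusive.
    """

    seed: int = 0
    n_clades: int = 4
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    gene_length: int = 5_000
    intergene_gap: int = 20_000
    chromosome: str = "chr1"
    anchor_name: str = "atp2b1"

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_clades < 1:
            raise ValueError("need at least one clade")


@dataclass(frozen=True)
class ExpressionSpec:
    """Planted-enrichment expression matrix settings.

    ``enriched`` holds (gene_index, sample_index, fold) triples with
    fold > 1; ``noise_cv`` is the multiplicative coefficient of variation.
    """

    n_genes: int = 21
    n_samples: int = 13
    enriched: tuple[tuple[int, int, float], ...] = ()
    noise_cv: float = 0.0
    baseline_log_mean: float = 3.0
    baseline_log_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for g, s, fold in self.enriched:
            if not (0 <= g < self.n_genes and 0 <= s < self.n_samples):
                raise ValueError(f"enriched cell ({g}, {s}) out of range")
            if fold <= 1:
                raise ValueError(f"effect size must be > 1, got {fold}")


@dataclass(frozen=True)
class QpcrSpec:
    """Known-fold qPCR table settings; one fold must equal 1."""

    folds: tuple[tuple[str, float], ...] = (("s1", 1.0), ("s2", 2.0), ("s3", 4.0))
    noise_sd: float = 0.0
    target: str = "target"
    reference_genes: tuple[str, ...] = ("eef1a", "actin", "gapdh")

    def __post_init__(self) -> None:
        values = [f for _, f in self.folds]
        if any(f < 1 for f in values):
            raise ValueError("true folds must be >= 1")
        if min(values) != 1.0:
            raise ValueError("one fold must equal 1 (the reference point)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_cluster_family(
    config: ClusterSimConfig,
    history: Optional[HistoryTree] = None,
    scenario: Optional[Scenario] = None,
) -> tuple[dict[str, list[GeneLocus]], Scenario]:
    """Simulate cluster evolution; return per-tip gene tables + true scenario.

    If ``scenario`` is given it is replayed as-is (e.g. the ``canonical``
    preset); otherwise events are drawn per branch at the configured
    Poisson rates.  The emitted tip tables are exactly the replay of the
    returned scenario, with genes laid left-to-right and a neighbor anchor
    gene planted downstream of each cluster.
    """
    if history is None:
        history = default_2r_tree()
    if scenario is None:
        scenario = _draw_scenario(config, history)
    compositions = replay(scenario, history)
    clade_of = {lin: clade for clade, lin in scenario.root_composition}
    for ev in scenario.events:
        if isinstance(ev, TandemDup):
            clade_of[ev.child] = clade_of[ev.parent]
    tables: dict[str, list[GeneLocus]] = {}
    step = config.gene_length + config.intergene_gap
    for tip in history.tips:
        loci: list[GeneLocus] = []
        pos = 1
        for lineage in compositions[tip]:
            loci.append(
                GeneLocus(
                    genome=f"genome_{tip}",
                    chromosome=config.chromosome,
                    start=pos,
                    end=pos + config.gene_length - 1,
                    strand="+",
                    name=f"{tip}_{lineage}",
                    family="slrp",
                    clade=clade_of[lineage],
                )
            )
            pos += step
        loci.append(
            GeneLocus(
                genome=f"genome_{tip}",
                chromosome=config.chromosome,
                start=pos,
                end=pos + config.gene_length - 1,
                strand="+",
                name=config.anchor_name,
                family="neighbor",
                clade=None,
            )
        )
        tables[tip] = loci
    return tables, scenario


def _draw_scenario(config: ClusterSimConfig, history: HistoryTree) -> Scenario:
    rng = np.random.default_rng(config.seed)
    root = tuple(
        (str(i + 1), f"c{i + 1}") for i in range(config.n_clades)
    )
    current: dict[str, list[str]] = {history.root: [lin for _, lin in root]}
    events: list = []
    counter = 0
    for node in history.preorder:
        if node == history.root:
            continue
        comp = list(current[history.parent[node]])
        n_dup = int(rng.poisson(config.dup_rate))
        n_loss = int(rng.poisson(config.loss_rate))
        for _ in range(n_dup):
            if not comp:
                break
            parent = comp[int(rng.integers(len(comp)))]
            counter += 1
            child = f"{parent}.d{counter}"
            events.append(TandemDup(node, parent, child))
            comp.insert(comp.index(parent) + 1, child)
        for _ in range(n_loss):
            if not comp:
                break
            events.append(Loss(node, comp.pop(int(rng.integers(len(comp))))))
        current[node] = comp
    return Scenario(root_composition=root, events=tuple(events))


def observed_family_from_tables(
    tables: Mapping[str, Sequence[GeneLocus]],
) -> ObservedFamily:
    """Build an :class:`ObservedFamily` from simulated tip tables.

    Simulated gene names encode their true lineage (``tip_lineage``), so
    orthology groups are exact: one group per lineage, holding its gene
    copy at every tip where it survived.
    """
    tips: dict[str, dict[str, str]] = {}
    groups: dict[str, list[str]] = {}
    for tip, loci in tables.items():
        tips[tip] = {}
        for g in loci:
            if g.family != "slrp":
                continue
            tips[tip][g.name] = g.clade
            lineage = g.name.split("_", 1)[1]
            groups.setdefault(lineage, []).append(g.name)
    return ObservedFamily(
        tips=tips,
        orthology_groups={k: tuple(v) for k, v in sorted(groups.items())},
    )


def _realize_elements(elements, rng: np.random.Generator) -> str:
    out = []
    for el in elements:
        if isinstance(el, motif.Fixed):
            out.append(el.residue)
        elif isinstance(el, motif.ResidueClass):
            out.append(el.residues[int(rng.integers(len(el.residues)))])
        elif isinstance(el, motif.Wildcard):
            k = int(rng.integers(el.min_repeat, el.max_repeat + 1))
            out.append(
                "".join(
                    _FILL_ALPHABET[int(i)]
                    for i in rng.integers(len(_FILL_ALPHABET), size=k)
                )
            )
        else:
            raise TypeError(el)
    return "".join(out)


def _lrr_window(rng: np.random.Generator, allow_n: bool = True) -> str:
    lset = "LIV"
    nset = "NTS" if allow_n else "TS"
    fill = lambda: _FILL_ALPHABET[int(rng.integers(len(_FILL_ALPHABET)))]
    l = lambda: lset[int(rng.integers(len(lset)))]
    n = nset[int(rng.integers(len(nset)))]
    return "".join(
        [l(), fill(), fill(), l(), fill(), l(), fill(), fill(), n, fill(), l()]
    )


def generate_lrr_protein(
    n_lrr: int = 8,
    lrrce_mode: str = "standard",
    seed: int = 0,
    max_retries: int = 20,
) -> str:
    """Generate a protein with a controlled LRRCE status.

    ``lrrce_mode``: ``standard`` (carries a standard-motif match, hence
    also a relaxed one), ``relaxed`` (carries a relaxed match but no
    standard one — the C-terminal spacer is 11 residues, legal for
    X(8,12)-C but not for X(8,9)-[FYMPVAIS]-X-C), or ``none`` (no match of
    either pattern; the sequence contains no cysteine).  Post-conditions
    are verified with the motif engine at generation time; an explicit
    error is raised if they cannot be met within ``max_retries``.
    """
    if n_lrr < 0:
        raise ValueError("n_lrr must be >= 0")
    if lrrce_mode not in ("standard", "relaxed", "none"):
        raise ValueError(f"unknown lrrce_mode {lrrce_mode!r}")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        parts = [
            "".join(
                _FILL_ALPHABET[int(i)]
                for i in rng.integers(len(_FILL_ALPHABET), size=15)
            )
        ]
        for _ in range(n_lrr):
            parts.append(_lrr_window(rng))
        if lrrce_mode == "standard":
            parts.append(_realize_elements(motif.STANDARD_LRRCE.elements, rng))
        elif lrrce_mode == "relaxed":
            # standard pattern minus its C-terminal X(8,9)-[FYMPVAIS]-X-C,
            # then an 11-residue spacer free of [FYMPVAIS], then C
            prefix = motif.STANDARD_LRRCE.elements[:-4]
            parts.append(_realize_elements(prefix, rng))
            parts.append("G" * 11 + "C")
        parts.append(
            "".join(
                _FILL_ALPHABET[int(i)]
                for i in rng.integers(len(_FILL_ALPHABET), size=10)
            )
        )
        seq = "".join(parts)
        std, _ = motif.has_lrrce(seq, "standard")
        rel, _ = motif.has_lrrce(seq, "relaxed")
        ok = {
            "standard": std,
            "relaxed": rel and not std,
            "none": not std and not rel,
        }[lrrce_mode]
        if ok:
            return seq
    raise RuntimeError(
        f"could not satisfy lrrce_mode={lrrce_mode!r} in {max_retries} attempts"
    )


def generate_expression_matrix(
    spec: ExpressionSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a non-negative TPM matrix plus the planted-enrichment mask.

    Baselines are log-normal per gene (strictly positive, heavy-tailed);
    enriched cells are baseline x fold; multiplicative log-normal noise
    with the configured coefficient of variation is applied cell-wise.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:03d}" for i in range(spec.n_genes)]
    samples = [f"s{j + 1:02d}" for j in range(spec.n_samples)]
    baseline = rng.lognormal(
        spec.baseline_log_mean, spec.baseline_log_sigma, size=spec.n_genes
    )
    values = np.tile(baseline[:, None], (1, spec.n_samples))
    mask = np.zeros((spec.n_genes, spec.n_samples), dtype=bool)
    for g, s, fold in spec.enriched:
        values[g, s] *= fold
        mask[g, s] = True
    if spec.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
        noise = rng.lognormal(-(sigma**2) / 2, sigma, size=values.shape)
        values = values * noise
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    mask_df = pd.DataFrame(mask, index=genes, columns=samples)
    return matrix, mask_df


def generate_qpcr_table(spec: QpcrSpec, seed: int = 0) -> pd.DataFrame:
    """Generate a Cp table (samples x genes) with known target folds.

    Cp values are built by inverting the normalization model: the target
    Cp is the per-sample reference mean plus a constant offset minus
    log2(fold), so qpcr_normalize recovers the true folds exactly at zero
    noise.  A per-sample loading shift is applied to all genes; it cancels
    in the delta-Cp and emulates input-amount variation.
    """
    rng = np.random.default_rng(seed)
    samples = [s for s, _ in spec.folds]
    ref_base = {g: 18.0 + 2.0 * i for i, g in enumerate(spec.reference_genes)}
    target_base = 26.0
    rows = []
    for sample, fold in spec.folds:
        shift = float(rng.normal(0.0, 0.5))
        row = {"sample": sample}
        for gene in spec.reference_genes:
            row[gene] = (
                ref_base[gene] + shift + float(rng.normal(0.0, spec.noise_sd))
            )
        row[spec.target] = (
            target_base
            + shift
            - float(np.log2(fold))
            + float(rng.normal(0.0, spec.noise_sd))
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


__all__ = [
    "ClusterSimConfig",
    "ExpressionSpec",
    "QpcrSpec",
    "simulate_cluster_family",
    "observed_family_from_tables",
    "generate_lrr_protein",
    "generate_expression_matrix",
    "generate_qpcr_table",
    "canonical_scenario",
]
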