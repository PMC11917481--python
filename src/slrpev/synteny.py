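"""Tandem-cluster detection and cross-genome anchoring for SLRP loci.

Canonical SLRP genes sit in four conserved genomic clusters (A-D) in jawed
vertebrates.  Given BED-like gene coordinate tables, this module chains
family genes into tandem clusters (single-linkage on inter-gene gaps),
orients clusters by the field convention (Clade 1 genes first and/or
Clade 4 genes last along the cluster), and anchors clusters between
genomes through shared neighbor genes (e.g. the Atp2b family), which is
the synteny evidence used to call locus orthology.

The default clustering gap of 200 kb reflects the qualitative usage in
comparative work on these loci: genes "more than 200 kb away" are not
treated as tandemly arranged, while pairs tens of kb apart are.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

CLADE_LABELS = {"1", "2", "3", "3a", "3b", "4", "non-canonical", "none"}

TABLE_COLUMNS = [
    "genome",
    "chromosome",
    "start",
    "end",
    "strand",
    "name",
    "family",
    "clade",
]


@dataclass(frozen=True)
class GeneLocus:
    """A positioned, clade-labeled gene record (1-based inclusive coords)."""

    genome: str
    chromosome: str
    start: int
    end: int
    strand: str
    name: str
    family: str = "slrp"
    clade: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(
                f"negative or zero coordinate for {self.name!r}: "
                f"{self.start}..{self.end}"
            )
        if self.start > self.end:
            raise ValueError(
                f"start > end for {self.name!r}: {self.start}..{self.end}"
            )
        if self.family == "slrp" and self.clade is None:
            raise ValueError(f"SLRP record {self.name!r} lacks a clade label")


@dataclass(frozen=True)
class TandemCluster:
    """An ordered run of family genes on one chromosome."""

    genome: str
    chromosome: str
    members: tuple[GeneLocus, ...]
    reversed_: bool = False
    ambiguous: bool = False

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.members)

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(g.start for g in self.members),
            max(g.end for g in self.members),
        )


def detect_tandem_clusters(
    loci: Sequence[GeneLocus],
    max_gap: int = 200_000,
    min_genes: int = 2,
) -> tuple[list[TandemCluster], list[GeneLocus]]:
    """Chain family genes into tandem clusters by single linkage.

    Two successive genes on the same chromosome belong to the same cluster
    when the gap between their spans (next.start - current.end - 1) is at
    most ``max_gap``.  Runs shorter than ``min_genes`` are returned as
    singletons.  All loci must come from a single genome.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    genomes = {g.genome for g in loci}
    if len(genomes) > 1:
        raise ValueError(f"loci span multiple genomes: {sorted(genomes)}")
    family = sorted(
        (g for g in loci if g.family == "slrp"),
        key=lambda g: (g.chromosome, g.start, g.end, g.name),
    )
    clusters: list[TandemCluster] = []
    leftovers: list[GeneLocus] = []
    run: list[GeneLocus] = []

    def flush(run: list[GeneLocus]) -> None:
        if len(run) >= min_genes:
            clusters.append(
                TandemCluster(run[0].genome, run[0].chromosome, tuple(run))
            )
        else:
            leftovers.extend(run)

    for gene in family:
        if (
            run
            and gene.chromosome == run[-1].chromosome
            and gene.start - run[-1].end - 1 <= max_gap
        ):
            run.append(gene)
        else:
            if run:
                flush(run)
            run = [gene]
    if run:
        flush(run)
    return clusters, leftovers


def _extremity_clades(cluster: TandemCluster) -> tuple[Optional[str], Optional[str]]:
    first = cluster.members[0].clade
    last = cluster.members[-1].clade
    return first, last


def orient_cluster(cluster: TandemCluster) -> TandemCluster:
    """Orient a cluster so Clade 1 genes lead and/or Clade 4 genes trail.

    If a Clade-1 member sits at one extremity it is put first; otherwise,
    if a Clade-4 member sits at one extremity it is put last.  A cluster
    with the deciding clade at both extremities keeps its order and is
    flagged ambiguous.  Idempotent.
    """
    if len(cluster.members) < 2:
        return cluster
    first, last = _extremity_clades(cluster)
    for clade, want_first in (("1", True), ("4", False)):
        at_first = first == clade
        at_last = last == clade
        if at_first and at_last:
            return replace(cluster, ambiguous=True)
        if at_first or at_last:
            should_reverse = (at_last and want_first) or (at_first and not want_first)
            if should_reverse:
                return replace(
                    cluster,
                    members=tuple(reversed(cluster.members)),
                    reversed_=not cluster.reversed_,
                )
            return cluster
    return cluster


def _normalize_anchor_name(name: str) -> str:
    """Case-fold and strip trailing paralog suffixes ('Atp2b1' -> 'atp2b')."""
    return re.sub(r"\d+[a-z]*$", "", name.lower())


def _neighbors_near_cluster(
    cluster: TandemCluster, loci: Sequence[GeneLocus], window: int
) -> set[str]:
    on_chrom = sorted(
        (g for g in loci if g.chromosome == cluster.chromosome),
        key=lambda g: (g.start, g.end, g.name),
    )
    member_idx = [
        i for i, g in enumerate(on_chrom) if g.name in set(cluster.names)
    ]
    lo = max(0, min(member_idx) - window)
    hi = min(len(on_chrom), max(member_idx) + window + 1)
    return {
        _normalize_anchor_name(g.name)
        for g in on_chrom[lo:hi]
        if g.family == "neighbor"
    }


def shared_neighbors(
    table_a: Sequence[GeneLocus],
    table_b: Sequence[GeneLocus],
    window: int = 10,
    max_gap: int = 200_000,
) -> list[tuple[TandemCluster, TandemCluster, frozenset[str]]]:
    """Anchor clusters across two genomes by conserved neighbor genes.

    For every pair of clusters (one per genome), the anchors are the
    normalized neighbor gene names found within ``window`` genes of both
    clusters; pairs with at least one anchor are reported.
    """
    clusters_a, _ = detect_tandem_clusters(list(table_a), max_gap=max_gap)
    clusters_b, _ = detect_tandem_clusters(list(table_b), max_gap=max_gap)
    pairs = []
    for ca in clusters_a:
        anchors_a = _neighbors_near_cluster(ca, table_a, window)
        for cb in clusters_b:
            anchors_b = _neighbors_near_cluster(cb, table_b, window)
            common = frozenset(anchors_a & anchors_b)
            if common:
                pairs.append((ca, cb, common))
    return pairs


def read_gene_table(path: str | Path) -> list[GeneLocus]:
    """Read a BED-like TSV gene table (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} lacks columns: {missing}")
    loci = []
    for row in df.itertuples(index=False):
        clade = row.clade
        if pd.isna(clade) or clade in ("", "none"):
            clade = None
        loci.append(
            GeneLocus(
                genome=row.genome,
                chromosome=row.chromosome,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                name=row.name,
                family=row.family,
                clade=clade,
            )
        )
    return loci


def write_gene_table(loci: Iterable[GeneLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "genome": g.genome,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "name": g.name,
                "family": g.family,
                "clade": g.clade if g.clade is not None else "none",
            }
            for g in loci
        ],
        columns=TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def cluster_report(
    clusters: Sequence[TandemCluster], singletons: Sequence[GeneLocus]
) -> pd.DataFrame:
    """Tabular cluster report: one row per gene with its cluster id."""
    rows = []
    for i, cluster in enumerate(clusters, start=1):
        for pos, g in enumerate(cluster.members, start=1):
            rows.append(
                {
                    "cluster": f"cluster_{i}",
                    "position": pos,
                    "genome": g.genome,
                    "chromosome": g.chromosome,
                    "start": g.start,
                    "end": g.end,
                    "name": g.name,
                    "clade": g.clade,
                }
            )
    for g in singletons:
        rows.append(
            {
                "cluster": "singleton",
                "position": 1,
                "genome": g.genome,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "name": g.name,
                "clade": g.clade,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "position",
            "genome",
            "chromosome",
            "start",
            "end",
            "name",
            "clade",
        ],
    )
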