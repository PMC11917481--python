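"""Expression enrichment on TPM matrices and qPCR relative quantification.

Tissue bias of SLRP expression is summarized per gene by row Z-scores over
a TPM matrix (genes x samples): z = (x - row mean) / row sd (sd with n-1
denominator).  A cell is called *strongly* enriched when Z > 1 and
TPM > 50, *weakly* enriched when Z > 1 and TPM <= 50, and unenriched
otherwise (strict inequalities; the thresholds are configurable).  A gene
is exclusively enriched in a sample group when all of its enriched calls
fall in that group.

qPCR relative quantification normalizes the target crossing point against
the geometric mean of three reference-gene expressions — equivalently the
arithmetic mean of their Cp values: dCp(s) = Cp_target(s) - mean(Cp_refs(s)),
fold(s) = E^(max dCp - dCp(s)) with amplification efficiency E = 2, so the
least-expressed sample defines the 1-fold reference point and every fold
is >= 1.

Z-scores are computed on raw TPM, across whatever samples the supplied
matrix contains; reproducing published calls requires the same sample
panel the publication used.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORY_STRONG = "strong"
CATEGORY_WEAK = "weak"
CATEGORY_NONE = "none"

DEFAULT_REFERENCE_GENES = ("eef1a", "actin", "gapdh")


def zscores(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-gene (row) Z-scores across samples.

    Constant rows get Z = 0 everywhere, with a warning.  Fewer than two
    samples is a usage error.
    """
    if matrix.shape[1] < 2:
        raise ValueError("Z-scores need at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sds == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) assigned Z = 0: "
            f"{list(matrix.index[constant])[:5]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - means) / sds
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def classify_enrichment(
    matrix: pd.DataFrame,
    z_threshold: float = 1.0,
    tpm_threshold: float = 50.0,
) -> pd.DataFrame:
    """Per-cell enrichment calls: long table (gene, sample, tpm, z, category).

    strong: Z > z_threshold and TPM > tpm_threshold;
    weak:   Z > z_threshold and TPM <= tpm_threshold;
    none:   otherwise.  All comparisons are strict on Z.
    """
    if z_threshold <= 0 or tpm_threshold <= 0:
        raise ValueError("thresholds must be positive")
    z = zscores(matrix)
    rows = []
    for gene in matrix.index:
        for sample in matrix.columns:
            tpm = float(matrix.at[gene, sample])
            zv = float(z.at[gene, sample])
            if zv > z_threshold and tpm > tpm_threshold:
                category = CATEGORY_STRONG
            elif zv > z_threshold:
                category = CATEGORY_WEAK
            else:
                category = CATEGORY_NONE
            rows.append(
                {"gene": gene, "sample": sample, "tpm": tpm, "z": zv,
                 "category": category}
            )
    return pd.DataFrame(rows, columns=["gene", "sample", "tpm", "z", "category"])


def exclusive_enrichment(
    calls: pd.DataFrame,
    sample_groups: Mapping[str, str],
    group: str,
) -> pd.DataFrame:
    """Per-gene enriched groups and exclusivity to a named group.

    A gene is exclusive to ``group`` iff it has at least one non-``none``
    call and every such call falls in a sample mapped to ``group``.  A
    call in an unmapped sample is an error naming the sample.
    """
    enriched = calls[calls["category"] != CATEGORY_NONE]
    unmapped = sorted(set(enriched["sample"]) - set(sample_groups))
    if unmapped:
        raise ValueError(f"enriched sample(s) not mapped to a group: {unmapped}")
    records = []
    for gene in calls["gene"].unique():
        gene_groups = sorted(
            {
                sample_groups[s]
                for s in enriched.loc[enriched["gene"] == gene, "sample"]
            }
        )
        records.append(
            {
                "gene": gene,
                "enriched_groups": tuple(gene_groups),
                "exclusive": bool(gene_groups) and gene_groups == [group],
            }
        )
    return pd.DataFrame(records, columns=["gene", "enriched_groups", "exclusive"])


def qpcr_normalize(
    cp_table: pd.DataFrame,
    target: str,
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
    efficiency: float = 2.0,
) -> pd.Series:
    """Per-sample relative fold for ``target`` from a Cp table (samples x genes).

    dCp(s) = Cp_target(s) - mean(Cp of reference genes in s); the sample
    with the highest dCp (lowest expression) is the 1-fold reference point:
    fold(s) = efficiency ** (max dCp - dCp(s)).  The minimum fold is
    exactly 1 and all folds are >= 1.
    """
    if target not in cp_table.columns:
        raise ValueError(f"target gene {target!r} not in Cp table")
    missing = [g for g in reference_genes if g not in cp_table.columns]
    if missing:
        raise ValueError(f"reference gene(s) missing from Cp table: {missing}")
    refs = cp_table[list(reference_genes)]
    if refs.isna().any().any() or cp_table[target].isna().any():
        raise ValueError("missing Cp value for a reference or target gene")
    delta_cp = cp_table[target] - refs.mean(axis=1)
    folds = efficiency ** (delta_cp.max() - delta_cp)
    return folds


def load_catshark_tpm() -> pd.DataFrame:
    """Packaged TPM panel: 21 catshark SLRP genes x 13 tissues/stages.

    A transcribed selection of published small-spotted catshark
    transcriptome quantifications (adult skeletal tissues, sensory organs,
    and embryonic stages), indexed by gene.  The full published panel
    covers 31 samples; Z-scores computed on this 13-sample selection will
    not exactly reproduce calls made on the full panel.
    """
    with resources.files("slrpev.data").joinpath("catshark_tpm.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("gene").drop(columns=["clade"])


def load_catshark_clades() -> pd.Series:
    """Clade assignment column of the packaged catshark TPM panel."""
    with resources.files("slrpev.data").joinpath("catshark_tpm.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("gene")["clade"]
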