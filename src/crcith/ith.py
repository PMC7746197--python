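"""Per-gene intra-tumor heterogeneity (ITH) scores and gene-panel summaries.

The ITH-score of gene g in tumor t is the sample SD (ddof=1) of its
log2(CPM) values over that tumor's biopsies; the inter-tumor score pools all
biopsies of all tumors.  Scores are binned into per-column quartiles, genes
with score strictly > 0.5 are "high-ITH", and three gene panels (stromal:
stroma score > 0.5; CNA: copy-number SD > 0.5; housekeeping: curated flag)
are summarized by their quartile distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTER_TUMOR = "inter_tumor"


@dataclass
class ITHTable:
    """Per-gene ITH-scores, one column per tumor plus the inter-tumor column."""

    scores: pd.DataFrame  # genes x tumor columns
    inter_tumor: pd.Series  # genes
    quartile: pd.DataFrame | None = None  # genes x (tumors + inter_tumor), bins 1-4
    high_threshold: float = 0.5

    @property
    def gene_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.scores.columns)

    def high_ith(self, threshold: float | None = None) -> pd.DataFrame:
        """Boolean mask: score strictly above the threshold (0.5 exactly excluded)."""
        thr = self.high_threshold if threshold is None else threshold
        return self.scores > thr

    def full(self) -> pd.DataFrame:
        """Scores with the inter-tumor column appended."""
        out = self.scores.copy()
        out[INTER_TUMOR] = self.inter_tumor
        return out


def _as_tumor_map(tumor_grouping, samples) -> pd.Series:
    grouping = pd.Series(tumor_grouping)
    missing = [s for s in samples if s not in grouping.index]
    if missing:
        raise ValueError(f"samples without tumor assignment: {missing}")
    return grouping.reindex(samples)


def gene_ith_scores(expr: pd.DataFrame, tumor_grouping) -> ITHTable:
    """SD of log2(CPM) per gene within each tumor, plus the pooled inter-tumor SD.

    Parameters
    ----------
    expr : DataFrame, genes x samples, log2(CPM) units.
    tumor_grouping : mapping sample_id -> tumor_id; every tumor needs >= 2
        biopsies in ``expr``.
    """
    grouping = _as_tumor_map(tumor_grouping, expr.columns)
    sizes = grouping.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(
            f"ITH-score needs >=2 biopsies per tumor; offending tumors: "
            f"{sorted(small.index)}"
        )
    scores = {
        tumor: expr.loc[:, grouping[grouping == tumor].index].std(axis=1, ddof=1)
        for tumor in sizes.sort_index().index
    }
    table = ITHTable(
        scores=pd.DataFrame(scores),
        inter_tumor=expr.std(axis=1, ddof=1).rename(INTER_TUMOR),
    )
    return table


def _column_bins(col: np.ndarray) -> np.ndarray:
    # quartile boundaries of the column itself; boundary ties go to the lower bin
    q = np.quantile(col, [0.25, 0.5, 0.75])
    return 1 + (col[:, None] > q[None, :]).sum(axis=1)


def quartile_bins(ith: ITHTable) -> ITHTable:
    """Bin genes into quartiles 1-4 within each column (tumors and inter-tumor)."""
    full = ith.full()
    bins = np.column_stack([_column_bins(full[c].to_numpy()) for c in full.columns])
    ith.quartile = pd.DataFrame(bins, index=full.index, columns=full.columns)
    return ith


def high_ith_counts(ith: ITHTable, threshold: float = 0.5) -> pd.Series:
    """Number of genes per tumor with ITH-score strictly > threshold."""
    return ith.scores.gt(threshold).sum(axis=0).rename("high_ith_genes")


def compute_cna_score(copy_numbers: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Per-gene SD (ddof=1) of copy numbers across samples.

    Genes scoring strictly > ``threshold`` are considered CNA genes.
    """
    if copy_numbers.shape[1] < 2:
        raise ValueError("CNA score needs >= 2 samples")
    score = copy_numbers.std(axis=1, ddof=1).rename("cna_score")
    score.attrs["cna_genes"] = list(score.index[score > threshold])
    return score


def make_gene_panels(
    gene_meta: pd.DataFrame,
    cna_score: pd.Series | None = None,
    stroma_threshold: float = 0.5,
    cna_threshold: float = 0.5,
) -> dict[str, list[str]]:
    """Stromal / CNA / housekeeping gene panels from the annotation table.

    Genes missing a stroma score are treated as non-stromal (score 0).
    """
    stroma = gene_meta.get("stroma_score")
    if stroma is None:
        stroma = pd.Series(0.0, index=gene_meta.index)
    stroma = stroma.fillna(0.0)
    if cna_score is None:
        cna_score = gene_meta.get("cna_score", pd.Series(0.0, index=gene_meta.index))
    cna_score = pd.Series(cna_score).reindex(gene_meta.index).fillna(0.0)
    hk = gene_meta.get("housekeeping", pd.Series(False, index=gene_meta.index))
    return {
        "stromal": list(gene_meta.index[stroma > stroma_threshold]),
        "cna": list(gene_meta.index[cna_score > cna_threshold]),
        "housekeeping": list(gene_meta.index[hk.astype(bool)]),
    }


def panel_quartile_distribution(ith: ITHTable, panel: list[str]) -> pd.DataFrame:
    """Quartile distribution of a gene panel, per column.

    Returns a (tumors + inter_tumor) x 4 DataFrame of proportions summing to
    1 per row.
    """
    if ith.quartile is None:
        quartile_bins(ith)
    members = ith.quartile.index.intersection(panel)
    if len(members) == 0:
        raise ValueError("panel has no genes in the ITH table")
    sub = ith.quartile.loc[members]
    out = pd.DataFrame(
        {q: (sub == q).mean(axis=0) for q in (1, 2, 3, 4)}
    )
    out.columns = [f"Q{q}" for q in (1, 2, 3, 4)]
    return out


__all__ = [
    "ITHTable",
    "INTER_TUMOR",
    "gene_ith_scores",
    "quartile_bins",
    "high_ith_counts",
    "compute_cna_score",
    "make_gene_panels",
    "panel_quartile_distribution",
]
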