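"""Protein NPX panel statistics and the pipeline's generic exact tests.

NPX (normalized protein expression) is the log2-scale relative unit of
proximity-extension assays.  QC removes flagged (failed) samples first and
then proteins whose detection fraction across the remaining samples is
strictly below 75 %.  Panels (e.g. TAM inflammation, cytotoxic-T response)
are summarized as per-sample mean NPX and compared between molecular
subtypes with the Wilcoxon rank-sum test; cluster/MSI enrichment uses
Fisher's exact test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: pooled sample size above which the Wilcoxon switches to the normal
#: approximation even without ties
EXACT_WILCOXON_MAX_N = 50

STAR_BINS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class NPXData:
    """Wide NPX matrix (samples x proteins) with detection flags and sample QC."""

    values: pd.DataFrame
    detected: pd.DataFrame
    flagged: pd.Series  # per-sample boolean: assay failure

    def __post_init__(self):
        if not self.values.index.equals(self.detected.index) or not (
            self.values.columns.equals(self.detected.columns)
        ):
            raise ValueError("values and detection flags must be aligned")
        self.flagged = self.flagged.reindex(self.values.index).fillna(False)


def qc_filter_npx(npx: NPXData, detection_threshold: float = 0.75) -> NPXData:
    """Drop flagged samples, then proteins detected in < threshold of samples.

    The boundary is strict: a protein detected in exactly the threshold
    fraction is retained.  Idempotent.
    """
    keep_samples = ~npx.flagged.astype(bool)
    values = npx.values.loc[keep_samples]
    detected = npx.detected.loc[keep_samples]
    frac = detected.mean(axis=0)
    keep_prot = frac >= detection_threshold
    if not keep_prot.any():
        raise ValueError("QC removed every protein")
    dropped = int((~keep_prot).sum())
    if dropped:
        logger.info("QC removed %d low-detection protein(s)", dropped)
    return NPXData(
        values=values.loc[:, keep_prot],
        detected=detected.loc[:, keep_prot],
        flagged=npx.flagged.loc[keep_samples],
    )


def panel_mean(npx_values: pd.DataFrame, panel: list[str]) -> pd.Series:
    """Per-sample arithmetic mean NPX over the panel's proteins.

    Missing panel members are skipped (denominator adjusted); having none
    left is an error.
    """
    present = [p for p in panel if p in npx_values.columns]
    if not present:
        raise ValueError("no panel protein survives in the NPX matrix")
    if len(present) < len(panel):
        logger.warning(
            "%d of %d panel proteins missing from NPX matrix",
            len(panel) - len(present),
            len(panel),
        )
    return npx_values[present].mean(axis=1).rename("panel_mean")


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode`` is "exact" (full permutation distribution of U), "normal"
    (large-sample approximation with tie and continuity corrections) or
    "auto" (exact when the pooled sample is small and untied).  Returns
    (U statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return float(x.size * y.size / 2.0), 1.0
    if mode == "auto":
        mode = "normal" if ties or pooled.size > EXACT_WILCOXON_MAX_N else "exact"
    if mode == "exact":
        if ties:
            raise ValueError("exact mode requires untied data")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif mode == "normal":
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fisher_exact(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table; two-sided p, sample odds ratio.

    p sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed one (within a
    1 + 1e-7 relative tolerance).  The odds ratio is ad/bc with a 0.5
    continuity correction applied to every cell when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    _, p = stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a * d / (b * c)), float(min(p, 1.0))


def _stars(p: float) -> str:
    for cut, mark in STAR_BINS:
        if p < cut:
            return mark
    return ""


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def subtype_panel_test(
    panel_means: pd.Series,
    calls,
    immune_subtypes: tuple[str, ...],
) -> pd.DataFrame:
    """Wilcoxon comparisons of a panel mean between subtypes, per classifier.

    ``calls`` is a list of :class:`~crcith.classify.SubtypeCall` (or an
    equivalent DataFrame).  For each classifier: every subtype pair, plus the
    pooled immune-related subtype set vs the rest.  Groups with < 2 samples
    are skipped (logged).  Unadjusted p-values carry star annotations
    (0.05 / 0.01 / 0.001); a Benjamini-Hochberg column is added per
    classifier for transparency.
    """
    from crcith.classify import calls_to_frame

    df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    rows = []
    for clf, grp in df.groupby("classifier_id"):
        labels = grp.set_index("sample_id")["label"]
        labels = labels[labels.index.isin(panel_means.index)]
        values = panel_means.reindex(labels.index)
        comparisons = []
        subtypes = sorted(labels.unique())
        for i, a in enumerate(subtypes):
            for b in subtypes[i + 1 :]:
                comparisons.append((a, b, values[labels == a], values[labels == b]))
        immune_mask = labels.isin(immune_subtypes)
        comparisons.append(
            ("immune_set", "rest", values[immune_mask], values[~immune_mask])
        )
        clf_rows = []
        for name_a, name_b, va, vb in comparisons:
            if len(va) < 2 or len(vb) < 2:
                logger.info(
                    "%s: %s vs %s skipped (group too small)", clf, name_a, name_b
                )
                continue
            u, p = wilcoxon_rank_sum(va.to_numpy(), vb.to_numpy())
            clf_rows.append(
                {
                    "classifier_id": clf,
                    "group_a": name_a,
                    "group_b": name_b,
                    "n_a": len(va),
                    "n_b": len(vb),
                    "U": u,
                    "p": p,
                    "stars": _stars(p),
                }
            )
        if clf_rows:
            q = _bh_adjust(np.array([r["p"] for r in clf_rows]))
            for r, qv in zip(clf_rows, q):
                r["p_bh"] = float(qv)
        rows.extend(clf_rows)
    return pd.DataFrame(
        rows,
        columns=["classifier_id", "group_a", "group_b", "n_a", "n_b", "U", "p",
                 "stars", "p_bh"],
    )


def cluster_enrichment(
    tumor_cluster_labels: pd.Series, msi_status: pd.Series
) -> dict:
    """Fisher test of MSI/MSS status against a two-cluster tumor assignment.

    Returns the 2x2 table, odds ratio, two-sided p, and per-cluster MSI/MSS
    composition percentages.
    """
    labels = pd.Series(tumor_cluster_labels)
    status = pd.Series(msi_status).reindex(labels.index)
    if status.isna().any():
        raise ValueError("MSI status missing for some tumors")
    clusters = sorted(labels.unique())
    if len(clusters) != 2:
        raise ValueError(f"need exactly 2 clusters, got {clusters}")
    table = np.array(
        [
            [
                int(((labels == cl) & (status == st)).sum())
                for st in ("MSI", "MSS")
            ]
            for cl in clusters
        ]
    )
    odds, p = fisher_exact(table)
    composition = {}
    for cl, row in zip(clusters, table):
        tot = row.sum()
        composition[str(cl)] = {
            "MSI_pct": 100.0 * row[0] / tot,
            "MSS_pct": 100.0 * row[1] / tot,
            "n": int(tot),
        }
    return {
        "table": table,
        "clusters": clusters,
        "odds_ratio": odds,
        "p": p,
        "composition": composition,
    }


__all__ = [
    "NPXData",
    "qc_filter_npx",
    "panel_mean",
    "wilcoxon_rank_sum",
    "fisher_exact",
    "subtype_panel_test",
    "cluster_enrichment",
]
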