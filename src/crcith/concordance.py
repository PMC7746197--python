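"""Subtype-call concordance within tumors and its link to expression ITH.

A tumor is discordant for a classifier when its biopsies receive >= 2
distinct primary labels (UNCLASSIFIED counts as its own label; uncertain
dual calls are compared by primary label).  Discordance fractions are
stratified by colorectal side, and intra-tumor expression correlation is
compared between biopsies of concordant and discordant tumors with a
Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from crcith.classify import SubtypeCall

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceRecord:
    tumor_id: str
    classifier_id: str
    labels: tuple[str, ...]  # per-biopsy primary labels, sample order
    n_distinct: int

    @property
    def discordant(self) -> bool:
        return self.n_distinct >= 2


def tumor_concordance(
    calls: list[SubtypeCall], tumor_grouping
) -> list[ConcordanceRecord]:
    """One record per (tumor, classifier); compares primary labels."""
    grouping = pd.Series(tumor_grouping)
    df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "classifier_id": [c.classifier_id for c in calls],
            "label": [c.label for c in calls],
            "uncertain": [c.uncertain for c in calls],
        }
    )
    missing = set(df["sample_id"]) - set(grouping.index)
    if missing:
        raise ValueError(f"calls for samples without tumor assignment: {sorted(missing)}")
    df["tumor_id"] = grouping.reindex(df["sample_id"]).to_numpy()
    expected = grouping.value_counts()
    records = []
    for (tumor, clf), grp in df.groupby(["tumor_id", "classifier_id"], sort=True):
        if len(grp) < expected[tumor]:
            absent = set(grouping.index[grouping == tumor]) - set(grp["sample_id"])
            raise ValueError(
                f"missing {clf} call for biopsies {sorted(absent)} of tumor {tumor}"
            )
        if grp["uncertain"].any():
            logger.info(
                "tumor %s / %s: uncertain dual calls compared by primary label",
                tumor,
                clf,
            )
        labels = tuple(grp.sort_values("sample_id")["label"])
        records.append(
            ConcordanceRecord(
                tumor_id=str(tumor),
                classifier_id=str(clf),
                labels=labels,
                n_distinct=len(set(labels)),
            )
        )
    return records


def records_to_frame(records: list[ConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tumor_id": [r.tumor_id for r in records],
            "classifier_id": [r.classifier_id for r in records],
            "labels": [";".join(r.labels) for r in records],
            "n_distinct": [r.n_distinct for r in records],
            "discordant": [r.discordant for r in records],
        }
    )


def discordance_by_location(
    records: list[ConcordanceRecord], sample_meta: pd.DataFrame
) -> pd.DataFrame:
    """Discordant-tumor fraction per (stratum, classifier).

    Strata are "all", "proximal" and "distal"; a stratum with no tumors is
    absent from the result rather than reported as 0.
    """
    side = sample_meta.groupby("tumor_id")["side"].first()
    df = records_to_frame(records)
    unknown = set(df["tumor_id"]) - set(side.index)
    if unknown:
        raise ValueError(f"records for tumors absent from metadata: {sorted(unknown)}")
    df["side"] = side.reindex(df["tumor_id"]).to_numpy()
    rows = []
    for stratum in ("all", "proximal", "distal"):
        sub = df if stratum == "all" else df[df["side"] == stratum]
        if sub.empty:
            continue
        for clf, grp in sub.groupby("classifier_id"):
            rows.append(
                {
                    "stratum": stratum,
                    "classifier_id": clf,
                    "n_tumors": len(grp),
                    "n_discordant": int(grp["discordant"].sum()),
                    "discordant_fraction": float(grp["discordant"].mean()),
                }
            )
    return pd.DataFrame(rows)


def intra_tumor_correlation(expr: pd.DataFrame, tumor_grouping) -> pd.Series:
    """Mean pairwise Pearson r of each biopsy to its co-biopsies.

    ``expr`` is genes x samples (already filtered); every tumor needs >= 2
    biopsies and no biopsy may have constant expression.
    """
    grouping = pd.Series(tumor_grouping).reindex(expr.columns)
    if grouping.isna().any():
        raise ValueError("every sample needs a tumor assignment")
    out = {}
    for tumor, cols in grouping.groupby(grouping).groups.items():
        cols = list(cols)
        if len(cols) < 2:
            raise ValueError(f"tumor {tumor} has fewer than 2 biopsies")
        x = expr[cols].to_numpy(dtype=float)
        if (x.std(axis=0) == 0).any():
            bad = [c for c, s in zip(cols, x.std(axis=0)) if s == 0]
            raise ValueError(f"constant expression vector(s): {bad}")
        r = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(r, np.nan)
        for c, val in zip(cols, np.nanmean(r, axis=1)):
            out[c] = float(val)
    return pd.Series(out, name="intra_tumor_r").reindex(expr.columns)


def correlation_vs_discordance_test(
    intra_r: pd.Series, discordant_count: pd.Series
) -> tuple[float, float]:
    """Wilcoxon rank-sum: biopsies with 0 discordant classifiers vs >= 1.

    ``discordant_count`` gives, per biopsy, the number of classifiers (0-3)
    that call its tumor discordantly.  Returns (U, two-sided p).
    """
    from crcith.protein import wilcoxon_rank_sum

    counts = discordant_count.reindex(intra_r.index)
    if counts.isna().any():
        raise ValueError("discordant_count must cover every biopsy")
    g0 = intra_r[counts == 0]
    g1 = intra_r[counts >= 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both concordant and discordant biopsies are required")
    return wilcoxon_rank_sum(g0.to_numpy(), g1.to_numpy())


__all__ = [
    "ConcordanceRecord",
    "tumor_concordance",
    "records_to_frame",
    "discordance_by_location",
    "intra_tumor_correlation",
    "correlation_vs_discordance_test",
]
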