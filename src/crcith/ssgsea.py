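"""Single-sample gene set enrichment (ssGSEA) and pathway-ITH summaries.

Per sample, genes are ordered by decreasing expression (ties broken by gene
id for determinism) and replaced by their rank from the bottom, so the top
gene has rank N.  A gene set's score is the integral (sum over all ranked
positions) of a running sum that steps up by ``rank^alpha`` (normalized over
the set) at member genes and down by 1/(N - m) elsewhere.  Because only
ranks enter, scores are invariant to any within-sample monotone transform
of expression, for every alpha.

Pathway heterogeneity within a tumor is summarized by the gene sets with the
largest SD of enrichment score across the tumor's biopsies (top 5000 by
default) and by median-normalized per-biopsy score deltas.  Gene-set
similarity edges (mean of Jaccard and overlap coefficients, threshold
0.375) are exported for enrichment-map network tools.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, members = parts[0], parts[2:]
        seen: list[str] = []
        for m in members:
            if m and m not in seen:
                seen.append(m)
        if not seen:
            raise ValueError(f"gene set {name!r} is empty")
        sets[name] = seen
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(members) for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def ssgsea_scores(
    expr: pd.DataFrame, sets: dict[str, list[str]], alpha: float = 0.75
) -> pd.DataFrame:
    """ssGSEA running-sum scores, one row per gene set, one column per sample."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    genes = list(expr.index)
    n = len(genes)
    measured = set(genes)
    memberships = {}
    for name, members in sets.items():
        hit = [g for g in members if g in measured]
        if not hit:
            logger.info("gene set %s has no measured genes; omitted", name)
            continue
        memberships[name] = set(hit)
    if not memberships:
        raise ValueError("no gene set overlaps the measured genes")

    scores = np.zeros((len(memberships), expr.shape[1]))
    names = list(memberships)
    gene_arr = np.array(genes)
    for si, sample in enumerate(expr.columns):
        vals = expr[sample].to_numpy(dtype=float)
        # descending expression, ties by gene id (lexicographic) for determinism
        order = np.lexsort((gene_arr, -vals))
        ordered_genes = gene_arr[order]
        weights = (n - np.arange(n)).astype(float) ** alpha  # rank from bottom
        for ki, name in enumerate(names):
            members = memberships[name]
            in_set = np.fromiter(
                (g in members for g in ordered_genes), dtype=bool, count=n
            )
            m = int(in_set.sum())
            steps = np.where(in_set, weights / weights[in_set].sum(), 0.0)
            if n > m:
                steps = steps - (~in_set) / (n - m)
            scores[ki, si] = np.cumsum(steps).sum()
    return pd.DataFrame(scores, index=names, columns=expr.columns)


def top_varying_sets(
    scores: pd.DataFrame, tumor_grouping, n: int = 5000
) -> dict[str, list[str]]:
    """Per tumor: the n gene sets with the largest score SD across biopsies."""
    grouping = pd.Series(tumor_grouping).reindex(scores.columns)
    if grouping.isna().any():
        raise ValueError("every sample needs a tumor assignment")
    out = {}
    for tumor, cols in grouping.groupby(grouping).groups.items():
        if len(cols) < 2:
            raise ValueError(f"tumor {tumor} has fewer than 2 biopsies")
        sd = scores[list(cols)].std(axis=1, ddof=1)
        ranked = sd.sort_values(ascending=False, kind="stable")
        out[tumor] = list(ranked.index[: min(n, len(ranked))])
    return out


def median_normalize_scores(scores: pd.DataFrame, tumor_grouping) -> pd.DataFrame:
    """Per-set, per-biopsy delta from the tumor's median score."""
    grouping = pd.Series(tumor_grouping).reindex(scores.columns)
    if grouping.isna().any():
        raise ValueError("every sample needs a tumor assignment")
    out = scores.copy()
    for tumor, cols in grouping.groupby(grouping).groups.items():
        if len(cols) < 2:
            raise ValueError(f"tumor {tumor} has fewer than 2 biopsies")
        cols = list(cols)
        out[cols] = scores[cols].sub(scores[cols].median(axis=1), axis=0)
    return out


def enrichment_map_edges(
    sets: dict[str, list[str]], similarity_threshold: float = 0.375
) -> pd.DataFrame:
    """Set-set similarity edges: mean of Jaccard and overlap coefficients."""
    names = list(sets)
    members = {k: set(v) for k, v in sets.items()}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = len(members[a] & members[b])
            if inter == 0:
                continue
            union = len(members[a] | members[b])
            overlap = inter / min(len(members[a]), len(members[b]))
            sim = 0.5 * (inter / union + overlap)
            if sim >= similarity_threshold:
                rows.append({"set_a": a, "set_b": b, "similarity": sim})
    return pd.DataFrame(rows, columns=["set_a", "set_b", "similarity"])


class SSGSEAScorer(TransformerMixin, BaseEstimator):
    """ssGSEA as a transformer: samples x genes in, samples x gene sets out."""

    def __init__(self, gene_sets: dict[str, list[str]] | None = None,
                 alpha: float = 0.75):
        self.gene_sets = gene_sets
        self.alpha = alpha

    def fit(self, X, y=None):
        if not self.gene_sets:
            raise ValueError("gene_sets must be provided")
        self.set_names_ = list(self.gene_sets)
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            expr = X.T
        else:
            X = np.asarray(X, dtype=float)
            expr = pd.DataFrame(
                X.T,
                index=[f"G{j}" for j in range(X.shape[1])],
                columns=[f"S{i}" for i in range(X.shape[0])],
            )
        return ssgsea_scores(expr, self.gene_sets, self.alpha).T


__all__ = [
    "read_gmt",
    "write_gmt",
    "ssgsea_scores",
    "top_varying_sets",
    "median_normalize_scores",
    "enrichment_map_edges",
    "SSGSEAScorer",
]
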