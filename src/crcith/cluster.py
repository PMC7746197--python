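"""Hierarchical clustering with multiscale-bootstrap clade support.

Samples are clustered on 1 - Pearson correlation distance with Ward.D2
linkage (Lance-Williams recurrence on squared dissimilarities, square-root
heights).  Clade support follows the multiscale bootstrap: features are
resampled with replacement at several scales r (resample size ceil(r * n)),
the per-scale bootstrap probability BP_r of each observed clade is recorded,
and the model

    BP_r = Phi(-(d * sqrt(r) + c / sqrt(r)))

is fitted by weighted least squares; the approximately unbiased support is
AU = Phi(c - d) * 100.  Clades with AU >= 95 are flagged significant
(corresponding to a clade p-value <= 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))
AU_SIGNIFICANT = 95.0


@dataclass
class ClusterTree:
    """Agglomerative merge structure over named leaves.

    ``linkage`` is a scipy linkage matrix ((n-1) x 4); AU and BP are on the
    0-100 scale, one value per internal node, set by
    :func:`multiscale_bootstrap`.
    """

    linkage: np.ndarray
    leaf_ids: list[str]
    au: np.ndarray | None = None
    bp: np.ndarray | None = None
    au_degenerate: np.ndarray | None = None
    bp_by_scale: np.ndarray | None = None  # scales x nodes
    scales: tuple[float, ...] | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def clades(self) -> list[frozenset[str]]:
        """Leaf-id set of each internal node, in merge order."""
        n = self.n_leaves
        members: list[frozenset[str]] = [frozenset([s]) for s in self.leaf_ids]
        out = []
        for a, b, *_ in self.linkage:
            merged = members[int(a)] | members[int(b)]
            members.append(merged)
            out.append(merged)
        return out

    def significant_nodes(self, au_threshold: float = AU_SIGNIFICANT) -> np.ndarray:
        if self.au is None:
            raise ValueError("run multiscale_bootstrap first")
        return self.au >= au_threshold

    def cut(self, k: int) -> pd.Series:
        labels = fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.leaf_ids, name="cluster")

    def to_newick(self) -> str:
        n = self.n_leaves
        reps: list[str] = list(self.leaf_ids)
        height: list[float] = [0.0] * n
        for a, b, h, _ in self.linkage:
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            reps.append(f"({reps[a]}:{la:.6g},{reps[b]}:{lb:.6g})")
            height.append(h)
        return reps[-1] + ";"


def correlation_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between sample columns of a feature x sample matrix."""
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 features")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(matrix.columns, sd) if s == 0]
        raise ValueError(f"constant sample columns: {bad}")
    d = 1.0 - np.corrcoef(x, rowvar=False)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def ward_cluster(distances: pd.DataFrame) -> ClusterTree:
    """Ward.D2 agglomeration of a precomputed distance matrix."""
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    z = linkage(squareform(d, checks=False), method="ward")
    return ClusterTree(linkage=z, leaf_ids=list(distances.index))


def _clade_indicator_sets(z: np.ndarray, n: int) -> list[frozenset[int]]:
    members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    out = []
    for a, b, *_ in z:
        merged = members[int(a)] | members[int(b)]
        members.append(merged)
        out.append(merged)
    return out


def multiscale_bootstrap(
    matrix: pd.DataFrame,
    tree: ClusterTree | None = None,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    nboot: int = 100,
    seed: int = 0,
) -> ClusterTree:
    """AU/BP support for every internal node of the observed tree.

    ``matrix`` is features x samples; the bootstrap resamples features with
    replacement (the convention for sample-clustering support).  BP is
    reported at scale r = 1.  Nodes whose BP_r are all 0 or all 1 cannot be
    fitted; their AU falls back to 100 * BP_1 and is flagged in
    ``tree.au_degenerate``.
    """
    scales = tuple(float(s) for s in scales)
    if min(scales) >= 1.0 or max(scales) <= 1.0:
        raise ValueError("scales must span values below and above 1")
    if nboot < 50:
        raise ValueError("nboot must be >= 50 per scale")
    if tree is None:
        tree = ward_cluster(correlation_distance(matrix))
    x = matrix.to_numpy(dtype=float)
    n_feat, n_samp = x.shape
    obs_clades = _clade_indicator_sets(tree.linkage, n_samp)
    n_nodes = len(obs_clades)
    clade_index = {c: i for i, c in enumerate(obs_clades)}
    rng = np.random.default_rng(seed)

    bp_by_scale = np.zeros((len(scales), n_nodes))
    for si, r in enumerate(scales):
        m = int(np.ceil(r * n_feat))
        hits = np.zeros(n_nodes)
        for _ in range(nboot):
            rows = rng.integers(0, n_feat, size=m)
            xb = x[rows]
            sd = xb.std(axis=0)
            if (sd == 0).any():
                continue  # degenerate resample: counts as a miss for every clade
            d = 1.0 - np.corrcoef(xb, rowvar=False)
            np.fill_diagonal(d, 0.0)
            zb = linkage(squareform(np.clip((d + d.T) / 2, 0, None), checks=False),
                         method="ward")
            for c in _clade_indicator_sets(zb, n_samp):
                idx = clade_index.get(c)
                if idx is not None:
                    hits[idx] += 1
        bp_by_scale[si] = hits / nboot

    one = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    au = np.empty(n_nodes)
    degen = np.zeros(n_nodes, dtype=bool)
    for node in range(n_nodes):
        au[node], degen[node] = _fit_au(bp_by_scale[:, node], np.asarray(scales), nboot)
    tree.bp = bp_by_scale[one] * 100.0
    tree.au = au
    tree.au_degenerate = degen
    tree.bp_by_scale = bp_by_scale
    tree.scales = scales
    if degen.any():
        logger.info("degenerate AU fit for %d node(s); AU set to BP at scale 1",
                    int(degen.sum()))
    return tree


def _fit_au(bp: np.ndarray, scales: np.ndarray, nboot: int) -> tuple[float, bool]:
    """WLS fit of the two-parameter multiscale model for one node."""
    if np.all((bp == 0.0) | (bp == 1.0)):
        one = int(np.argmin(np.abs(scales - 1.0)))
        return 100.0 * bp[one], True
    eps = 1.0 / (nboot + 1.0)
    bpc = np.clip(bp, eps, 1.0 - eps)
    z = -norm.ppf(bpc)  # z = d*sqrt(r) + c/sqrt(r)
    design = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    # weights: inverse variance of z, var(BP) = Phi(1-Phi)/nboot, delta method
    w = nboot * norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
    for _ in range(2):  # initial fit + one refit at fitted values
        wd = design * w[:, None]
        beta, *_ = np.linalg.lstsq(wd.T @ design, wd.T @ z, rcond=None)
        zfit = design @ beta
        pfit = np.clip(norm.cdf(-zfit), eps, 1.0 - eps)
        w = nboot * norm.pdf(zfit) ** 2 / (pfit * (1.0 - pfit))
    d, c = beta
    return float(norm.cdf(c - d) * 100.0), False


def tumor_pure_clades(tree: ClusterTree, tumor_grouping) -> pd.Series:
    """True for every tumor whose biopsy set is exactly some internal node."""
    grouping = pd.Series(tumor_grouping).reindex(tree.leaf_ids)
    if grouping.isna().any():
        raise ValueError("every leaf needs a tumor assignment")
    clades = set(tree.clades())
    out = {}
    for tumor, cols in grouping.groupby(grouping).groups.items():
        leaves = frozenset(cols)
        if len(leaves) < 2:
            raise ValueError(f"tumor {tumor} has fewer than 2 leaves")
        out[tumor] = leaves in clades
    return pd.Series(out, name="pure_clade").sort_index()


def majority_cluster_assignment(
    tree: ClusterTree,
    k: int,
    tumor_grouping,
    distances: pd.DataFrame | None = None,
) -> pd.Series:
    """Assign each tumor to the flat cluster holding most of its biopsies.

    The tree is cut at ``k`` clusters.  An exact tie goes to the cluster with
    the smaller mean distance to the tumor's biopsies (requires
    ``distances``; ties are logged).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = tree.cut(k)
    grouping = pd.Series(tumor_grouping).reindex(tree.leaf_ids)
    out = {}
    for tumor, cols in grouping.groupby(grouping).groups.items():
        counts = labels[list(cols)].value_counts()
        top = counts[counts == counts.max()]
        if len(top) == 1:
            out[tumor] = int(top.index[0])
            continue
        logger.info("tumor %s: tied majority between clusters %s", tumor,
                    list(top.index))
        if distances is None:
            out[tumor] = int(sorted(top.index)[0])
            continue
        best, best_d = None, np.inf
        for cl in sorted(top.index):
            members = labels.index[labels == cl]
            d = distances.loc[list(cols), members].to_numpy().mean()
            if d < best_d:
                best, best_d = int(cl), d
        out[tumor] = best
    return pd.Series(out, name="cluster").sort_index()


class CorrelationWardClustering(ClusterMixin, BaseEstimator):
    """Correlation-distance Ward.D2 clustering with optional AU/BP support.

    scikit-learn orientation: X is samples x features.  After ``fit``:
    ``tree_`` (ClusterTree), ``labels_`` (cut at ``n_clusters``), and when
    ``nboot`` > 0 also ``au_``, ``bp_`` and ``significant_``.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        nboot: int = 0,
        scales: tuple[float, ...] = DEFAULT_SCALES,
        au_threshold: float = AU_SIGNIFICANT,
        seed: int = 0,
    ):
        self.n_clusters = n_clusters
        self.nboot = nboot
        self.scales = scales
        self.au_threshold = au_threshold
        self.seed = seed

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            matrix = X.T
        else:
            X = np.asarray(X, dtype=float)
            matrix = pd.DataFrame(
                X.T, columns=[f"S{i}" for i in range(X.shape[0])]
            )
        self.distances_ = correlation_distance(matrix)
        self.tree_ = ward_cluster(self.distances_)
        if self.nboot:
            multiscale_bootstrap(
                matrix, self.tree_, tuple(self.scales), self.nboot, self.seed
            )
            self.au_ = self.tree_.au
            self.bp_ = self.tree_.bp
            self.significant_ = self.tree_.significant_nodes(self.au_threshold)
        self.labels_ = self.tree_.cut(self.n_clusters).to_numpy()
        return self


__all__ = [
    "ClusterTree",
    "DEFAULT_SCALES",
    "AU_SIGNIFICANT",
    "correlation_distance",
    "ward_cluster",
    "multiscale_bootstrap",
    "tumor_pure_clades",
    "majority_cluster_assignment",
    "CorrelationWardClustering",
]
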