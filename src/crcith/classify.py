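"""Single-sample molecular subtype classifiers.

Two retrainable classifier families:

``NearestCentroidSubtyper``
    Nearest-centroid single-sample predictor (SSP).  Class centroids are
    per-gene means of row-standardized training expression over marker
    genes; a sample is assigned by Pearson correlation to each centroid.
    Two calling modes mirror common SSP usage: *nearest* always returns the
    best-correlated class; *predicted* gates on a correlation threshold and
    otherwise returns UNCLASSIFIED.

``KTSPSubtyper``
    k top-scoring-pairs classifier.  For every unordered class pair it
    selects k gene pairs (i, j) maximizing the difference in
    P(expr_i < expr_j) between the two classes, genes disjoint within a
    pair list (greedy).  Prediction is by within-sample rank comparisons
    only, hence invariant to any within-sample monotone transform.  Ties in
    the class tournament, or margins below a threshold, yield an uncertain
    dual call (primary + secondary label).

Both follow the scikit-learn estimator protocol with X as samples x genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class SubtypeCall:
    """One per-sample, per-classifier subtype call."""

    sample_id: str
    classifier_id: str
    label: str
    confidence: float
    mode: str
    secondary_label: str | None = None

    @property
    def uncertain(self) -> bool:
        return self.secondary_label is not None


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in calls])


def _as_expr_frame(X) -> pd.DataFrame:
    """Coerce samples x genes input to a DataFrame."""
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(
        X,
        index=[f"S{i}" for i in range(X.shape[0])],
        columns=[f"G{j}" for j in range(X.shape[1])],
    )


class NearestCentroidSubtyper(ClassifierMixin, BaseEstimator):
    """Nearest-centroid SSP with nearest/predicted gating.

    Parameters
    ----------
    mode : {"nearest", "predicted"}
        nearest always calls the best class; predicted returns UNCLASSIFIED
        when the best correlation falls below ``correlation_threshold``.
    correlation_threshold : float
        Minimum Pearson correlation for a predicted-mode call.
    margin_threshold : float
        When the gap between the two best correlations is below this, the
        runner-up is reported as a secondary label (uncertain call).
    n_markers : int or None
        Number of marker genes selected at fit time (variance ranking with a
        class-mean separation filter); None keeps every gene.
    min_coverage : float
        Minimum fraction of marker genes a sample must provide.
    """

    def __init__(
        self,
        mode: str = "predicted",
        correlation_threshold: float = 0.15,
        margin_threshold: float = 0.06,
        n_markers: int | None = 1000,
        min_coverage: float = 0.5,
        classifier_id: str = "SSP",
    ):
        self.mode = mode
        self.correlation_threshold = correlation_threshold
        self.margin_threshold = margin_threshold
        self.n_markers = n_markers
        self.min_coverage = min_coverage
        self.classifier_id = classifier_id

    def fit(self, X, y):
        expr = _as_expr_frame(X)
        y = pd.Series(np.asarray(y, dtype=object), index=expr.index)
        counts = y.value_counts()
        if len(counts) < 2:
            raise ValueError("need at least two classes")
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"every class needs >=2 training samples; too small: "
                f"{sorted(small.index)}"
            )
        mu = expr.mean(axis=0)
        sd = expr.std(axis=0, ddof=1).replace(0.0, 1.0)
        z = (expr - mu) / sd
        class_means = z.groupby(y).mean()  # classes x genes
        if self.n_markers is not None and self.n_markers < expr.shape[1]:
            # balanced per-class selection: each class contributes its top
            # genes by one-vs-rest standardized mean separation
            per_class = max(1, self.n_markers // len(counts))
            chosen: set = set()
            for cls in class_means.index:
                rest = class_means.drop(index=cls).max(axis=0)
                sep = (class_means.loc[cls] - rest).sort_values(ascending=False)
                chosen.update(sep.index[:per_class])
            markers = [g for g in expr.columns if g in chosen]
        else:
            markers = list(expr.columns)
        self.classes_ = np.array(sorted(counts.index))
        self.marker_genes_ = list(markers)
        self.gene_means_ = mu[markers]
        self.gene_sds_ = sd[markers]
        self.centroids_ = class_means.loc[self.classes_, markers]
        return self

    def decision_function(self, X) -> pd.DataFrame:
        """Pearson correlation of each sample to each class centroid."""
        check_is_fitted(self, "centroids_")
        expr = _as_expr_frame(X)
        corrs = np.full((expr.shape[0], len(self.classes_)), np.nan)
        for i, (sid, row) in enumerate(expr.iterrows()):
            corrs[i] = self._sample_correlations(row)
        return pd.DataFrame(corrs, index=expr.index, columns=self.classes_)

    def _sample_correlations(self, sample: pd.Series) -> np.ndarray:
        present = [g for g in self.marker_genes_ if g in sample.index]
        present = [g for g in present if np.isfinite(sample[g])]
        coverage = len(present) / len(self.marker_genes_)
        if coverage < self.min_coverage:
            raise ValueError(
                f"sample covers only {coverage:.0%} of marker genes "
                f"({len(present)}/{len(self.marker_genes_)}); "
                f"need >= {self.min_coverage:.0%}"
            )
        v = (sample[present] - self.gene_means_[present]) / self.gene_sds_[present]
        v = v.to_numpy(dtype=float)
        c = self.centroids_[present].to_numpy(dtype=float)
        vc = v - v.mean()
        cc = c - c.mean(axis=1, keepdims=True)
        denom = np.sqrt((vc**2).sum() * (cc**2).sum(axis=1))
        denom[denom == 0] = np.nan
        return cc @ vc / denom

    def predict_calls(self, X, mode: str | None = None) -> list[SubtypeCall]:
        mode = mode or self.mode
        if mode not in ("nearest", "predicted"):
            raise ValueError(f"unknown mode {mode!r}")
        corr = self.decision_function(X)
        calls = []
        for sid, row in corr.iterrows():
            order = row.sort_values(ascending=False)
            best, second = order.index[0], order.index[1]
            conf = float(order.iloc[0])
            label = best
            secondary = None
            if mode == "predicted" and conf < self.correlation_threshold:
                label = UNCLASSIFIED
            elif conf - float(order.iloc[1]) < self.margin_threshold:
                secondary = second
            calls.append(
                SubtypeCall(
                    sample_id=str(sid),
                    classifier_id=self.classifier_id,
                    label=str(label),
                    confidence=conf,
                    mode=mode,
                    secondary_label=None if secondary is None else str(secondary),
                )
            )
        return calls

    def predict(self, X):
        return np.array([c.label for c in self.predict_calls(X)])

    def to_json(self) -> str:
        check_is_fitted(self, "centroids_")
        return json.dumps(
            {
                "family": "centroid",
                "params": self.get_params(),
                "classes": list(map(str, self.classes_)),
                "marker_genes": self.marker_genes_,
                "gene_means": self.gene_means_.tolist(),
                "gene_sds": self.gene_sds_.tolist(),
                "centroids": self.centroids_.to_numpy().tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NearestCentroidSubtyper":
        d = json.loads(text)
        model = cls(**d["params"])
        model.classes_ = np.array(d["classes"])
        model.marker_genes_ = d["marker_genes"]
        model.gene_means_ = pd.Series(d["gene_means"], index=d["marker_genes"])
        model.gene_sds_ = pd.Series(d["gene_sds"], index=d["marker_genes"])
        model.centroids_ = pd.DataFrame(
            d["centroids"], index=model.classes_, columns=d["marker_genes"]
        )
        return model


class KTSPSubtyper(ClassifierMixin, BaseEstimator):
    """k top-scoring-pairs subtype classifier (one pair list per class pair)."""

    def __init__(
        self,
        k: int = 25,
        margin_threshold: int = 0,
        n_candidate_genes: int = 300,
        min_expression_quantile: float = 0.25,
        classifier_id: str = "kTSP",
    ):
        self.k = k
        self.margin_threshold = margin_threshold
        self.n_candidate_genes = n_candidate_genes
        self.min_expression_quantile = min_expression_quantile
        self.classifier_id = classifier_id

    def fit(self, X, y):
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError("k must be an odd positive integer")
        expr = _as_expr_frame(X)
        y = pd.Series(np.asarray(y, dtype=object), index=expr.index)
        counts = y.value_counts()
        small = counts[counts < 3]
        if len(small):
            raise ValueError(
                f"every class needs >=3 training samples; too small: "
                f"{sorted(small.index)}"
            )
        self.classes_ = np.array(sorted(counts.index))
        # within-sample ranks: the only quantity kTSP ever sees
        ranks = np.apply_along_axis(rankdata, 1, expr.to_numpy(dtype=float))
        genes = np.array(expr.columns)
        # low-abundance transcripts have unstable ranks at bulk sequencing
        # depth; keep pair candidates above the expression quantile
        mean_expr = expr.to_numpy(dtype=float).mean(axis=0)
        floor = np.quantile(mean_expr, self.min_expression_quantile)
        abundant = mean_expr >= floor
        self.pairs_: dict[tuple[str, str], list[tuple[str, str]]] = {}
        self.pair_scores_: dict[tuple[str, str], list[float]] = {}
        for a_i in range(len(self.classes_)):
            for b_i in range(a_i + 1, len(self.classes_)):
                a, b = self.classes_[a_i], self.classes_[b_i]
                ra_full = ranks[np.asarray(y == a)]
                rb_full = ranks[np.asarray(y == b)]
                # per-class-pair candidate filter: genes whose within-sample
                # rank moves the most between the two classes
                shift = np.abs(ra_full.mean(axis=0) - rb_full.mean(axis=0))
                shift = np.where(abundant, shift, -1.0)
                n_cand = min(self.n_candidate_genes, expr.shape[1])
                cand = np.sort(np.argsort(-shift)[:n_cand])
                pairs, scores = self._select_pairs(
                    ra_full[:, cand], rb_full[:, cand]
                )
                self.pairs_[(a, b)] = [
                    (str(genes[cand[i]]), str(genes[cand[j]])) for i, j in pairs
                ]
                self.pair_scores_[(a, b)] = scores
        return self

    def _select_pairs(self, ra: np.ndarray, rb: np.ndarray):
        """Top-k disjoint gene pairs for one class pair.

        Primary score: |P(x_i < x_j | a) - P(x_i < x_j | b)|.  Secondary
        tie-break: |mean rank difference gap| between the classes.
        """
        pa = (ra[:, :, None] < ra[:, None, :]).mean(axis=0)
        pb = (rb[:, :, None] < rb[:, None, :]).mean(axis=0)
        score = np.abs(pa - pb)
        da = (ra[:, :, None] - ra[:, None, :]).mean(axis=0)
        db = (rb[:, :, None] - rb[:, None, :]).mean(axis=0)
        tiebreak = np.abs(da - db)
        n = score.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        order = np.lexsort((iu, ju, -tiebreak[iu, ju], -score[iu, ju]))
        chosen, chosen_scores, used = [], [], set()
        for idx in order:
            i, j = int(iu[idx]), int(ju[idx])
            if i in used or j in used:
                continue
            # orient the pair so that "i < j" is the class-a direction
            if pa[i, j] >= pb[i, j]:
                chosen.append((i, j))
            else:
                chosen.append((j, i))
            chosen_scores.append(float(score[i, j]))
            used.update((i, j))
            if len(chosen) == self.k:
                break
        if len(chosen) < self.k:
            logger.warning(
                "only %d admissible disjoint pairs (k=%d); using all",
                len(chosen),
                self.k,
            )
        return chosen, chosen_scores

    def predict_calls(self, X) -> list[SubtypeCall]:
        check_is_fitted(self, "pairs_")
        expr = _as_expr_frame(X)
        calls = []
        for sid, row in expr.iterrows():
            calls.append(self._call_sample(str(sid), row))
        return calls

    def _call_sample(self, sid: str, sample: pd.Series) -> SubtypeCall:
        wins = {c: 0 for c in self.classes_}
        any_pair = False
        for (a, b), pairs in self.pairs_.items():
            votes_a = 0
            used = 0
            for gi, gj in pairs:
                if gi not in sample.index or gj not in sample.index:
                    logger.info("pair (%s, %s) skipped for %s", gi, gj, sid)
                    continue
                used += 1
                if sample[gi] < sample[gj]:
                    votes_a += 1
            if used == 0:
                continue
            any_pair = True
            if votes_a * 2 > used:
                wins[a] += 1
            elif votes_a * 2 < used:
                wins[b] += 1
            else:  # even vote (only possible with skipped pairs): half win each
                wins[a] += 0.5
                wins[b] += 0.5
        if not any_pair:
            raise ValueError(f"all gene pairs missing for sample {sid}")
        ranking = sorted(wins.items(), key=lambda kv: (-kv[1], kv[0]))
        (best, w1), (second, w2) = ranking[0], ranking[1]
        margin = w1 - w2
        secondary = second if margin <= self.margin_threshold else None
        return SubtypeCall(
            sample_id=sid,
            classifier_id=self.classifier_id,
            label=str(best),
            confidence=float(margin),
            mode="nearest",
            secondary_label=None if secondary is None else str(secondary),
        )

    def predict(self, X):
        return np.array([c.label for c in self.predict_calls(X)])

    def to_json(self) -> str:
        check_is_fitted(self, "pairs_")
        return json.dumps(
            {
                "family": "ktsp",
                "params": self.get_params(),
                "classes": list(map(str, self.classes_)),
                "pairs": {f"{a}|{b}": v for (a, b), v in self.pairs_.items()},
                "scores": {f"{a}|{b}": v for (a, b), v in self.pair_scores_.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "KTSPSubtyper":
        d = json.loads(text)
        model = cls(**d["params"])
        model.classes_ = np.array(d["classes"])
        model.pairs_ = {
            tuple(k.split("|")): [tuple(p) for p in v] for k, v in d["pairs"].items()
        }
        model.pair_scores_ = {tuple(k.split("|")): v for k, v in d["scores"].items()}
        return model


__all__ = [
    "UNCLASSIFIED",
    "SubtypeCall",
    "calls_to_frame",
    "NearestCentroidSubtyper",
    "KTSPSubtyper",
]
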