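"""Count normalization: TMM scaling factors, log2(CPM), expression filters.

Raw counts are normalized with the trimmed-mean-of-M-values (TMM) method:
each library is compared with a reference library through gene-wise
log-ratios (M-values) and average log-abundances (A-values), both computed
on library-size-scaled counts.  After discarding the most extreme 30 % of
M-values and 5 % of A-values, the scaling factor is an inverse-variance
weighted mean of the surviving M-values (delta-method binomial weights).
Factors are rescaled so their geometric mean is 1.

log2(CPM) uses a library-size-proportional prior count so that samples with
larger libraries receive proportionally larger priors, keeping the
log-transform comparable across libraries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    counts = pd.DataFrame(counts)
    if (counts.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    if not counts.index.is_unique or not counts.columns.is_unique:
        raise ValueError("gene and sample ids must be unique")
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(
            f"samples with all-zero counts cannot be normalized: {list(zero.index)}"
        )
    return counts


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """TMM normalization factors for a gene x sample count matrix.

    Parameters
    ----------
    counts : DataFrame, genes x samples
        Raw non-negative integer counts.
    trim_m : float
        Fraction of genes trimmed from each tail by M-value rank.
    trim_a : float
        Fraction trimmed from each tail by A-value rank.

    Returns
    -------
    Series of per-sample positive factors with geometric mean 1.  Dividing a
    library size by its factor gives the effective library size.
    """
    counts = _validate_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)

    # reference = sample whose upper-quartile CPM is closest to the mean
    f75 = np.quantile(x, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(counts.shape[1])
    for s in range(counts.shape[1]):
        factors[s] = _pair_factor(
            x[:, s], x[:, ref_idx], lib[s], lib[ref_idx], trim_m, trim_a
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Weighted trimmed mean of M-values of one library against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic binomial variance of M (delta method)
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not sel.any():
        return 1.0
    f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
    return float(2.0**f)


def log2_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 2.0,
) -> pd.DataFrame:
    """log2 counts-per-million with TMM-effective library sizes.

    The prior count is scaled per sample in proportion to its effective
    library size: ``prior_s = prior_count * L_s / mean(L)``, and the value is
    ``log2((count + prior_s) / (L_s + 2 * prior_s) * 1e6)``, which is strictly
    monotone in the count.
    """
    counts = _validate_counts(counts)
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    factors = pd.Series(factors).reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("factors must be positive and aligned to samples")
    eff_lib = lib * factors
    prior = prior_count * eff_lib / eff_lib.mean()
    adj_lib = eff_lib + 2.0 * prior
    vals = np.log2(
        (counts.to_numpy(dtype=float) + prior.to_numpy()) / adj_lib.to_numpy() * 1e6
    )
    expr = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    expr.attrs["normalization_factors"] = factors
    return expr


def filter_expressed(
    expr: pd.DataFrame,
    threshold: float = 1.0,
    coding: pd.Series | None = None,
) -> pd.DataFrame:
    """Keep genes whose mean log2(CPM) across samples is strictly > threshold.

    If ``coding`` (boolean Series indexed by gene) is given, non-coding genes
    are dropped first.  Gene order is preserved.
    """
    out = expr
    if coding is not None:
        mask = coding.reindex(out.index).fillna(False).astype(bool)
        out = out.loc[mask]
    keep = out.mean(axis=1) > threshold
    out = out.loc[keep]
    if out.shape[0] == 0:
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return out


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize: mean 0, SD 1 (ddof=1) per row; constant rows map to 0."""
    if matrix.shape[1] < 2:
        raise ValueError("row z-scores need at least two columns")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    # rows constant up to floating-point rounding map to zero, not to
    # rounding noise blown up by a near-zero SD
    tol = 1e-12 * np.maximum(1.0, np.abs(mu))
    constant = sd <= tol
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[np.broadcast_to(constant, z.shape)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


class TMMNormalizer(TransformerMixin, BaseEstimator):
    """TMM + log2(CPM) normalization as a scikit-learn transformer.

    Follows the scikit-learn orientation: ``X`` is samples x genes.  ``fit``
    computes per-sample TMM factors and stores the reference library;
    ``transform`` returns log2(CPM).  Samples unseen at fit time are scaled
    against the stored reference profile.

    Attributes
    ----------
    norm_factors_ : ndarray of per-sample factors for the fitted samples.
    ref_profile_ : counts of the reference library.
    """

    def __init__(
        self,
        trim_m: float = 0.30,
        trim_a: float = 0.05,
        prior_count: float = 2.0,
    ):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.prior_count = prior_count

    def fit(self, X, y=None):
        counts = self._as_frame(X)
        factors = tmm_factors(counts.T, self.trim_m, self.trim_a)
        lib = counts.sum(axis=1)
        f75 = counts.quantile(0.75, axis=1) / lib
        ref = (f75 - f75.mean()).abs().idxmin()
        self.norm_factors_ = factors.to_numpy()
        self.sample_ids_ = list(counts.index)
        self.gene_ids_ = list(counts.columns)
        self.ref_profile_ = counts.loc[ref].to_numpy(dtype=float)
        self.ref_lib_ = float(lib.loc[ref])
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "norm_factors_")
        counts = self._as_frame(X)
        if list(counts.index) == self.sample_ids_:
            factors = pd.Series(self.norm_factors_, index=counts.index)
        else:
            raw = np.array(
                [
                    _pair_factor(
                        row,
                        self.ref_profile_,
                        row.sum(),
                        self.ref_lib_,
                        self.trim_m,
                        self.trim_a,
                    )
                    for row in counts.to_numpy(dtype=float)
                ]
            )
            factors = pd.Series(raw / np.exp(np.mean(np.log(raw))), index=counts.index)
        return log2_cpm(counts.T, factors, self.prior_count).T

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(
            X,
            index=[f"S{i}" for i in range(X.shape[0])],
            columns=[f"G{j}" for j in range(X.shape[1])],
        )
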