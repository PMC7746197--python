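"""NPX QC, panel means, and the generic Wilcoxon / Fisher exact tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from crcith.protein import (
    NPXData,
    cluster_enrichment,
    fisher_exact,
    panel_mean,
    qc_filter_npx,
    subtype_panel_test,
    wilcoxon_rank_sum,
)
from crcith.protein import _stars


def make_npx(values, detected=None, flagged=None):
    values = pd.DataFrame(values)
    if detected is None:
        detected = pd.DataFrame(True, index=values.index, columns=values.columns)
    else:
        detected = pd.DataFrame(detected, index=values.index, columns=values.columns)
    if flagged is None:
        flagged = pd.Series(False, index=values.index)
    else:
        flagged = pd.Series(flagged, index=values.index)
    return NPXData(values=values, detected=detected, flagged=flagged)


class TestQCFilter:
    def test_detection_boundary_is_strict_below(self):
        # 20 samples: protein "low" detected in 14 (70%), "edge" in 15 (75%)
        det = pd.DataFrame(
            {
                "low": [True] * 14 + [False] * 6,
                "edge": [True] * 15 + [False] * 5,
                "good": [True] * 20,
            }
        )
        npx = make_npx(np.zeros((20, 3)), detected=det.to_numpy())
        npx.values.columns = npx.detected.columns = ["low", "edge", "good"]
        out = qc_filter_npx(npx, 0.75)
        assert list(out.values.columns) == ["edge", "good"]

    def test_flagged_samples_dropped_before_detection_fractions(self):
        # protein detected in 2/4 samples, but both misses are flagged
        det = [[True], [True], [False], [False]]
        npx = make_npx(np.zeros((4, 1)), detected=det,
                       flagged=[False, False, True, True])
        out = qc_filter_npx(npx, 0.75)
        assert out.values.shape == (2, 1)

    def test_idempotent(self, rng):
        det = rng.random((30, 10)) < 0.9
        npx = make_npx(rng.normal(size=(30, 10)), detected=det)
        once = qc_filter_npx(npx)
        twice = qc_filter_npx(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_proteins_removed_rejected(self):
        npx = make_npx(np.zeros((4, 2)), detected=np.zeros((4, 2), dtype=bool))
        with pytest.raises(ValueError):
            qc_filter_npx(npx)

    def test_simulated_panel_keeps_68_of_96(self, default_cohort):
        npx = NPXData(
            values=default_cohort.npx,
            detected=default_cohort.npx_detected,
            flagged=default_cohort.sample_meta["flagged"],
        )
        out = qc_filter_npx(npx, 0.75)
        assert out.values.shape[1] == 68


class TestPanelMean:
    def test_two_member_arithmetic(self):
        npx = pd.DataFrame({"p1": [2.0], "p2": [4.0]}, index=["s"])
        assert panel_mean(npx, ["p1", "p2"])["s"] == pytest.approx(3.0)

    def test_missing_members_skipped(self, caplog):
        npx = pd.DataFrame({"p1": [2.0]}, index=["s"])
        mean = panel_mean(npx, ["p1", "ghost"])
        assert mean["s"] == pytest.approx(2.0)

    def test_no_surviving_member_rejected(self):
        npx = pd.DataFrame({"p1": [2.0]}, index=["s"])
        with pytest.raises(ValueError):
            panel_mean(npx, ["ghost"])

    def test_immune_level_ordering_recovered(self, default_cohort):
        tam = panel_mean(default_cohort.npx, default_cohort.panels["TAM_inflammation"])
        lvl = default_cohort.truth.immune_level.reindex(tam.index)
        hi = tam[lvl >= lvl.quantile(0.75)].mean()
        lo = tam[lvl <= lvl.quantile(0.25)].mean()
        assert hi > lo


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating all group assignments of the pooled data."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    us = []
    for comb in itertools.combinations(range(len(pooled)), nx):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.array(us)
    p_low = (us <= u_obs).mean()
    p_high = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_textbook_example(self):
        u, p = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_equal_multisets_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [3, 1, 2])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        for nx, ny in [(2, 3), (3, 3), (4, 4), (5, 3), (4, 6)]:
            x = rng.normal(size=nx)
            y = rng.normal(0.5, 1, size=ny)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            assert p == pytest.approx(wilcoxon_enumeration_oracle(x, y), abs=1e-12)

    def test_exact_and_normal_agree_for_moderate_n(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(0.3, 1, size=20)
        _, pe = wilcoxon_rank_sum(x, y, mode="exact")
        _, pn = wilcoxon_rank_sum(x, y, mode="normal")
        assert abs(pe - pn) < 0.01

    def test_exact_p_invariant_to_monotone_transform(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(1, 1, size=5)
        _, p1 = wilcoxon_rank_sum(x, y, mode="exact")
        _, p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y), mode="exact")
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_all_tied_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_rank_sum([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def fisher_enumeration_oracle(table):
    """Two-sided p summing hypergeometric probabilities <= observed."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    probs = hypergeom.pmf(np.arange(lo, hi + 1), n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


class TestFisher:
    def test_symmetric_table(self):
        _, p = fisher_exact([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_diagonal_table(self):
        odds, p = fisher_exact([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3)
        assert odds > 1  # continuity-corrected sample odds ratio

    def test_matches_enumeration_on_small_tables(self):
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    for d in range(4):
                        t = [[a, b], [c, d]]
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        _, p = fisher_exact(t)
                        assert p == pytest.approx(
                            fisher_enumeration_oracle(t), abs=1e-12
                        )

    def test_transpose_invariance(self, rng):
        for _ in range(10):
            t = rng.integers(1, 10, size=(2, 2))
            _, p1 = fisher_exact(t)
            _, p2 = fisher_exact(t.T)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [1, 2]])


class TestSubtypePanelTest:
    def make_calls(self, labels):
        from crcith.classify import SubtypeCall

        return [
            SubtypeCall(f"s{i}", "SSP", lab, 0.9, "nearest")
            for i, lab in enumerate(labels)
        ]

    def test_identical_panel_means_give_p_one(self):
        labels = ["A"] * 5 + ["B"] * 5
        means = pd.Series(1.0, index=[f"s{i}" for i in range(10)])
        out = subtype_panel_test(means, self.make_calls(labels), ("A",))
        assert (out["p"] == 1.0).all()
        assert (out["stars"] == "").all()

    def test_shifted_immune_group_detected(self, rng):
        labels = ["IMM"] * 10 + ["MET"] * 10
        vals = np.r_[rng.normal(3.0, 0.5, 10), rng.normal(1.0, 0.5, 10)]
        means = pd.Series(vals, index=[f"s{i}" for i in range(20)])
        out = subtype_panel_test(means, self.make_calls(labels), ("IMM",))
        imm = out[(out["group_a"] == "immune_set")].iloc[0]
        assert imm["p"] < 0.05
        assert "p_bh" in out.columns

    def test_small_groups_skipped(self):
        labels = ["A", "B", "B", "B"]
        means = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"s{i}" for i in range(4)])
        out = subtype_panel_test(means, self.make_calls(labels), ("A",))
        assert not ((out["group_a"] == "A") & (out["group_b"] == "B")).any()

    @pytest.mark.parametrize(
        "p,stars", [(0.049, "*"), (0.011, "*"), (0.009, "**"), (0.0009, "***"), (0.2, "")]
    )
    def test_star_bins(self, p, stars):
        assert _stars(p) == stars


class TestClusterEnrichment:
    def test_perfect_separation_p_value(self):
        labels = pd.Series([1] * 8 + [2] * 8, index=[f"T{i}" for i in range(16)])
        status = pd.Series(["MSI"] * 8 + ["MSS"] * 8, index=labels.index)
        out = cluster_enrichment(labels, status)
        from math import comb

        assert out["p"] == pytest.approx(2 / comb(16, 8))
        assert out["composition"]["1"]["MSI_pct"] == 100.0
        assert out["composition"]["2"]["MSS_pct"] == 100.0

    def test_composition_percentages_sum(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        status = pd.Series(["MSI", "MSS", "MSI", "MSS"], index=list("abcd"))
        out = cluster_enrichment(labels, status)
        for comp in out["composition"].values():
            assert comp["MSI_pct"] + comp["MSS_pct"] == pytest.approx(100.0)

    def test_single_cluster_rejected(self):
        labels = pd.Series([1, 1], index=["a", "b"])
        status = pd.Series(["MSI", "MSS"], index=["a", "b"])
        with pytest.raises(ValueError):
            cluster_enrichment(labels, status)
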