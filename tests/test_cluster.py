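"""Correlation-distance Ward clustering and multiscale-bootstrap support."""

import io

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from crcith.cluster import (
    ClusterTree,
    correlation_distance,
    majority_cluster_assignment,
    multiscale_bootstrap,
    tumor_pure_clades,
    ward_cluster,
)


def ward_d2_oracle(d: np.ndarray):
    """Naive Ward.D2: Lance-Williams on squared distances, sqrt heights."""
    n = d.shape[0]
    d2 = d.astype(float) ** 2
    active = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d2[i, j]
    heights, clades = [], []
    next_id = n
    while len(active) > 1:
        (i, j), dij = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(dij))
        merged = active[i] | active[j]
        clades.append(merged)
        ni, nj = sizes[i], sizes[j]
        new = {}
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            new[k] = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
        del active[i], active[j], sizes[i], sizes[j]
        dist = {kk: v for kk, v in dist.items() if i not in kk and j not in kk}
        active[next_id] = merged
        sizes[next_id] = ni + nj
        for k, v in new.items():
            dist[tuple(sorted((k, next_id)))] = v
        next_id += 1
    return np.array(heights), clades


def two_cluster_matrix(rng, n_features=200, spread=0.2):
    """Six samples in two clearly separated groups."""
    a = rng.normal(0, 1, size=n_features)
    b = rng.normal(0, 1, size=n_features)
    cols = {}
    for i in range(3):
        cols[f"a{i}"] = a + rng.normal(0, spread, size=n_features)
        cols[f"b{i}"] = b + rng.normal(0, spread, size=n_features)
    return pd.DataFrame(cols)


class TestCorrelationDistance:
    def test_identical_samples_distance_zero(self, rng):
        v = rng.normal(size=50)
        m = pd.DataFrame({"a": v, "b": v})
        d = correlation_distance(m)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_samples_distance_two(self, rng):
        v = rng.normal(size=50)
        m = pd.DataFrame({"a": v, "b": -v})
        assert correlation_distance(m).loc["a", "b"] == pytest.approx(2.0)

    def test_matches_brute_force_loop(self, rng):
        m = pd.DataFrame(rng.normal(size=(80, 7)))
        d = correlation_distance(m)
        for i in m.columns:
            for j in m.columns:
                want = 0.0 if i == j else 1 - np.corrcoef(m[i], m[j])[0, 1]
                assert abs(d.loc[i, j] - want) < 1e-12

    def test_constant_column_rejected(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            correlation_distance(m)

    def test_affine_transform_invariance(self, rng):
        m = pd.DataFrame(rng.normal(size=(60, 5)))
        m2 = m * 3.5 + 11.0  # per-sample positive affine map
        d1 = correlation_distance(m)
        d2 = correlation_distance(m2)
        assert np.allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)


class TestWardCluster:
    def test_closest_pair_merges_first(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]],
            index=list("xyz"),
            columns=list("xyz"),
        )
        tree = ward_cluster(d)
        assert tree.clades()[0] == frozenset({"x", "y"})

    def test_tree_has_n_minus_one_nodes(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 9)))
        tree = ward_cluster(correlation_distance(m))
        assert tree.linkage.shape[0] == 8

    def test_matches_lance_williams_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(12, 6))
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            dd = pd.DataFrame(d, index=[f"s{i}" for i in range(12)],
                              columns=[f"s{i}" for i in range(12)])
            tree = ward_cluster(dd)
            want_heights, want_clades = ward_d2_oracle(d)
            assert np.allclose(np.sort(tree.heights), np.sort(want_heights),
                               atol=1e-10)
            got = {frozenset(f"s{i}" for i in c) for c in want_clades}
            assert set(tree.clades()) == got

    def test_newick_round_trip(self, rng):
        m = two_cluster_matrix(rng)
        tree = ward_cluster(correlation_distance(m))
        phylo = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        leaves = {leaf.name for leaf in phylo.get_terminals()}
        assert leaves == set(m.columns)


class TestMultiscaleBootstrap:
    def test_perfectly_supported_clades_get_full_support(self, rng):
        m = two_cluster_matrix(rng, spread=0.05)
        tree = multiscale_bootstrap(m, nboot=100, seed=1)
        clades = tree.clades()
        for group in ("a", "b"):
            idx = clades.index(frozenset({f"{group}0", f"{group}1", f"{group}2"}))
            assert tree.bp[idx] == pytest.approx(100.0)
            assert tree.au[idx] == pytest.approx(100.0)

    def test_significance_threshold_includes_95(self):
        tree = ClusterTree(linkage=np.zeros((2, 4)), leaf_ids=list("abc"))
        tree.au = np.array([94.9, 95.0])
        sig = tree.significant_nodes(95.0)
        assert list(sig) == [False, True]

    def test_bp_at_unit_scale_matches_plain_bootstrap(self, rng):
        m = two_cluster_matrix(rng, spread=0.4)
        tree = multiscale_bootstrap(m, nboot=100, seed=3)
        # independent plain bootstrap at r=1 with its own rng
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        x = m.to_numpy()
        obs = tree.clades()
        hits = np.zeros(len(obs))
        g = np.random.default_rng(1234)
        nboot = 400
        for _ in range(nboot):
            xb = x[g.integers(0, x.shape[0], size=x.shape[0])]
            d = 1 - np.corrcoef(xb, rowvar=False)
            np.fill_diagonal(d, 0)
            z = linkage(squareform((d + d.T) / 2, checks=False), method="ward")
            members = [frozenset([s]) for s in m.columns]
            got = set()
            for a, b, *_ in z:
                merged = members[int(a)] | members[int(b)]
                members.append(merged)
                got.add(merged)
            for i, c in enumerate(obs):
                hits[i] += c in got
        plain = 100 * hits / nboot
        # binomial 99% CI at nboot=100 around the plain estimate
        half = 100 * 2.58 * np.sqrt(
            np.maximum(plain / 100 * (1 - plain / 100), 1e-4) / 100
        )
        assert (np.abs(tree.bp - plain) <= half + 2.58 * np.sqrt(
            np.maximum(plain * (100 - plain) / 100, 1.0) / nboot)).all()

    def test_reproducible_with_fixed_seed(self, rng):
        m = two_cluster_matrix(rng, spread=0.4)
        t1 = multiscale_bootstrap(m, nboot=60, seed=5)
        au1, bp1 = t1.au.copy(), t1.bp.copy()
        t2 = multiscale_bootstrap(m, nboot=60, seed=5)
        assert (t2.au == au1).all() and (t2.bp == bp1).all()

    def test_au_at_least_bp_when_bp_decreases_with_scale(self, rng):
        m = two_cluster_matrix(rng, spread=0.55)
        tree = multiscale_bootstrap(m, nboot=200, seed=2)
        scales = np.asarray(tree.scales)
        for node in range(len(tree.au)):
            bp_r = tree.bp_by_scale[:, node]
            if tree.au_degenerate[node] or not (0.05 < bp_r.mean() < 0.95):
                continue
            slope = np.polyfit(scales, bp_r, 1)[0]
            if slope < -0.05:
                assert tree.au[node] >= tree.bp[node] - 1e-9

    def test_scale_grid_must_straddle_one(self, rng):
        m = two_cluster_matrix(rng)
        with pytest.raises(ValueError):
            multiscale_bootstrap(m, scales=(1.1, 1.2, 1.3), nboot=60)
        with pytest.raises(ValueError):
            multiscale_bootstrap(m, nboot=10)


class TestPureCladesAndAssignment:
    def test_separated_tumors_are_pure(self, rng):
        m = two_cluster_matrix(rng, spread=0.1)
        tree = ward_cluster(correlation_distance(m))
        grouping = pd.Series(
            {c: ("TA" if c.startswith("a") else "TB") for c in m.columns}
        )
        pure = tumor_pure_clades(tree, grouping)
        assert pure.all()

    def test_interleaved_biopsy_breaks_purity(self, rng):
        m = two_cluster_matrix(rng, spread=0.1)
        grouping = pd.Series(
            {c: ("TA" if c.startswith("a") else "TB") for c in m.columns}
        )
        grouping["b0"] = "TA"  # TA now claims a leaf deep in the other cluster
        tree = ward_cluster(correlation_distance(m))
        pure = tumor_pure_clades(tree, grouping)
        assert not pure["TA"]

    def test_majority_assignment(self, rng):
        m = two_cluster_matrix(rng, spread=0.1)
        tree = ward_cluster(correlation_distance(m))
        grouping = pd.Series(
            {"a0": "TA", "a1": "TA", "a2": "TA", "b0": "TB", "b1": "TB", "b2": "TA"}
        )
        # TA: 3 biopsies in cluster a + 1 in cluster b -> majority cluster a
        out = majority_cluster_assignment(tree, 2, grouping)
        labels = tree.cut(2)
        assert out["TA"] == labels["a0"]
        assert out["TB"] == labels["b0"]

    def test_tie_resolved_by_mean_distance(self, rng):
        m = two_cluster_matrix(rng, spread=0.1)
        # tumor with a 1-1 split between the clusters
        grouping = pd.Series(
            {"a0": "TA", "a1": "TA", "a2": "TX", "b0": "TX", "b1": "TB", "b2": "TB"}
        )
        d = correlation_distance(m)
        tree = ward_cluster(d)
        out = majority_cluster_assignment(tree, 2, grouping, distances=d)
        assert out["TX"] in set(tree.cut(2))

    def test_k_below_two_rejected(self, rng):
        m = two_cluster_matrix(rng)
        tree = ward_cluster(correlation_distance(m))
        with pytest.raises(ValueError):
            majority_cluster_assignment(tree, 1, pd.Series({c: "T" for c in m.columns}))
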