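"""Descriptive statistics, Pearson oracle checks and Ward clustering.

The Ward implementation is cross-checked against an independent
brute-force agglomerator that recomputes, at every step and for every
cluster pair, the within-cluster variance increase directly from the
member coordinates (no Lance–Williams recurrence)."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pterisk.core import CensoredMeasurement, Element, PlantSample
from pterisk.stats import pearson_matrix, summarize, ward_cluster


# -- independent oracles ------------------------------------------------

def brute_force_ward(X: np.ndarray):
    """Greedy Ward merges computed from raw member coordinates.

    X has one column per leaf.  Returns scipy-style merge rows
    (a, b, height, size) with height = sqrt(2 · ΔESS).
    """
    n = X.shape[1]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma, mb = clusters[a], clusters[b]
            ca = X[:, ma].mean(axis=1)
            cb = X[:, mb].mean(axis=1)
            d_ess = (len(ma) * len(mb)) / (len(ma) + len(mb)) * float(
                ((ca - cb) ** 2).sum()
            )
            if best is None or d_ess < best[0] - 1e-12:
                best = (d_ess, a, b)
        d_ess, a, b = best
        merges.append((a, b, np.sqrt(2 * d_ess), len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def pearson_oracle(x, y):
    """r from the definition: covariance over the product of SDs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


# -- summaries ----------------------------------------------------------

class TestSummarize:
    def test_basic_moments(self):
        s = summarize([1.0, 2.0, 3.0], Element.CU)
        assert (s.mean, s.sd) == (2.0, 1.0)
        assert (s.min, s.max, s.n) == (1.0, 3.0, 3)
        assert summarize([5.0, 5.0, 5.0], Element.CU).sd == 0.0

    def test_censored_values_counted_and_substituted(self):
        samples = [
            PlantSample(f"X{i}", "t", "f", "leaf", False,
                        {Element.HG: m})
            for i, m in enumerate([
                CensoredMeasurement.below_dl(Element.HG, 0.1),
                CensoredMeasurement.observed(Element.HG, 20.0),
            ])
        ]
        s = summarize(samples, Element.HG)
        # reporting units (ng/g): DL/2 = 0.05, not the mg/kg-converted value
        assert s.n_censored == 1 and s.min == pytest.approx(0.05)
        assert s.mean == pytest.approx((0.05 + 20.0) / 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize([], Element.CU)

    def test_invariants(self):
        s = summarize([3.0, 9.0, 4.5, 7.25], Element.BA)
        assert s.min <= s.mean <= s.max and s.sd >= 0


class TestPearson:
    def test_self_and_anti_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 5], "y": [-1.0, -2, -3, -5]})
        r, p = pearson_matrix(df)
        assert r.loc["x", "x"] == pytest.approx(1.0)
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert np.allclose(r.values, r.values.T)

    def test_five_point_toy_matches_oracle(self):
        x = [1.0, 4.0, 2.0, 9.0, 7.0]
        y = [2.0, 3.0, 1.5, 8.0, 5.0]
        r, p = pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        assert r.loc["x", "y"] == pytest.approx(pearson_oracle(x, y), rel=1e-12)
        assert 0 <= p.loc["x", "y"] <= 1

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1, _ = pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        r2, _ = pearson_matrix(pd.DataFrame({"x": 3.5 * x + 10, "y": 0.2 * y - 4}))
        assert r1.loc["x", "y"] == pytest.approx(r2.loc["x", "y"], rel=1e-9)

    def test_zero_variance_reported_absent(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        r, _ = pearson_matrix(df)
        assert np.isnan(r.loc["x", "y"])


class TestWard:
    def test_identical_variables_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        df = pd.DataFrame({"a": base, "b": base, "c": rng.normal(size=30) + 50})
        dendro = ward_cluster(df, standardize=False)
        a, b, dist, size = dendro.merges[0]
        assert {a, b} == {0, 1} and dist == pytest.approx(0.0) and size == 2

    def test_two_block_structure_recovered(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=60)
        v = rng.normal(size=60)
        df = pd.DataFrame({
            "a": u + 0.1 * rng.normal(size=60),
            "b": u + 0.1 * rng.normal(size=60),
            "c": v + 0.1 * rng.normal(size=60),
            "d": v + 0.1 * rng.normal(size=60),
        })
        groups = ward_cluster(df).cut(2)
        assert sorted(map(sorted, groups)) == [["a", "b"], ["c", "d"]]

    @pytest.mark.parametrize("seed,n_leaves", [(0, 3), (1, 4), (2, 5), (3, 5), (4, 5)])
    def test_matches_brute_force_on_small_instances(self, seed, n_leaves):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, n_leaves))
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(n_leaves)])
        got = ward_cluster(df, standardize=False).merges
        expected = brute_force_ward(X)
        for (a, b, d, s), (ea, eb, ed, es) in zip(got, expected):
            assert {a, b} == {ea, eb}
            assert d == pytest.approx(ed, rel=1e-9)
            assert s == es

    def test_linkage_distances_monotone(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(40, 6)),
                          columns=list("abcdef"))
        dendro = ward_cluster(df)
        dists = [d for _, _, d, _ in dendro.merges]
        assert all(x <= y + 1e-12 for x, y in zip(dists, dists[1:]))

    def test_newick_and_requirements(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.1, 2, 3.2]})
        tree = ward_cluster(df).to_newick()
        assert tree.startswith("(") and tree.endswith(";")
        with pytest.raises(ValueError):
            ward_cluster(df[["a"]])
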