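import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from bbrnet.community_profile import (
    DistanceMatrix,
    anosim,
    bray_curtis,
    bray_curtis_matrix,
    nmds,
    rarefy,
    shannon,
)


def _counts(rng, taxa=7, samples=4, low=3000, high=9000):
    return pd.DataFrame(
        rng.integers(low, high, size=(taxa, samples)),
        index=[f"t{i}" for i in range(taxa)],
        columns=[f"s{i}" for i in range(samples)],
    )


class TestRarefy:
    def test_columns_sum_to_depth(self, rng):
        out = rarefy(_counts(rng), depth=10_000, seed=1)
        assert (out.sum(axis=0) == 10_000).all()

    def test_depth_equal_to_column_sum_is_identity(self, rng):
        c = _counts(rng, samples=1)
        depth = int(c["s0"].sum())
        out = rarefy(c, depth=depth, seed=0)
        pd.testing.assert_series_equal(out["s0"], c["s0"], check_dtype=False)

    def test_fixed_seed_reproducible(self, rng):
        c = _counts(rng)
        a = rarefy(c, 5000, seed=42)
        bb = rarefy(c, 5000, seed=42)
        pd.testing.assert_frame_equal(a, bb)

    def test_shallow_sample_dropped_with_warning(self, rng):
        c = _counts(rng)
        c["shallow"] = [1] * 7
        with pytest.warns(UserWarning, match="shallow"):
            out = rarefy(c, 5000, seed=0)
        assert "shallow" not in out.columns

    def test_never_exceeds_original_counts(self, rng):
        c = _counts(rng)
        out = rarefy(c, 5000, seed=3)
        assert (out.to_numpy() <= c.to_numpy()).all()


class TestShannon:
    def test_single_taxon_zero(self):
        assert shannon([10, 0, 0]) == 0.0

    def test_four_equal_taxa_base2(self):
        assert shannon([5, 5, 5, 5], base=2) == pytest.approx(2.0)

    def test_bounded_by_log_richness(self, rng):
        for _ in range(20):
            c = rng.integers(0, 50, size=10)
            if c.sum() == 0:
                continue
            k = (c > 0).sum()
            if k == 0:
                continue
            assert shannon(c) <= np.log(k) + 1e-12

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon([0, 0])

    def test_matches_scipy_entropy(self, rng):
        c = rng.integers(1, 100, size=8)
        assert shannon(c) == pytest.approx(sps.entropy(c / c.sum()))


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 0, 0], [0, 2, 3], 1.0),
            ([2, 2], [1, 3], 0.25),
        ],
    )
    def test_hand_values(self, x, y, expected):
        assert bray_curtis(x, y) == pytest.approx(expected)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 5, size=6)
            y = rng.uniform(0, 5, size=6)
            assert bray_curtis(x, y) == pytest.approx(scipy_braycurtis(x, y))

    def test_both_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0, 0], [0, 0])

    def test_matrix_is_valid_distance_matrix(self, rng):
        dm = bray_curtis_matrix(_counts(rng))
        assert dm.values.max() <= 1.0
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)


class TestNMDS:
    def test_euclidean_representable_distances_reach_low_stress(self):
        pts = np.arange(6, dtype=float)[:, None]
        d = np.abs(pts - pts.T)
        dm = DistanceMatrix(d, [f"s{i}" for i in range(6)])
        res = nmds(dm, k=2, seed=0)
        assert res.stress < 0.01

    def test_stress_monotone_in_k(self, rng):
        pts = rng.normal(size=(7, 5))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(7)])
        s2 = nmds(dm, k=2, seed=0, n_restarts=5).stress
        s6 = nmds(dm, k=6, seed=0, n_restarts=5).stress
        assert s6 <= s2 + 1e-9

    def test_stress_history_non_increasing(self, rng):
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(8)])
        res = nmds(dm, k=2, seed=1, n_restarts=3)
        assert all(np.diff(res.stress_history) <= 1e-9)

    def test_too_few_samples_raises(self):
        dm = DistanceMatrix(np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="k\\+1"):
            nmds(dm, k=2, seed=0)


def _oracle_anosim(d, labels):
    """Independent full-enumeration ANOSIM (scipy ranks + itertools)."""
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    ranked = sps.rankdata(d[iu])
    m = ranked.size

    def r_of(lab):
        same = lab[iu[0]] == lab[iu[1]]
        return (ranked[~same].mean() - ranked[same].mean()) / (m / 2)

    r_obs = r_of(np.asarray(labels))
    seen, hits, total = set(), 0, 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        if r_of(np.array(perm)) >= r_obs - 1e-12:
            hits += 1
        total += 1
    return r_obs, hits / total


class TestAnosim:
    def test_separated_clusters_r_one(self):
        x = np.array([0.0, 0, 0, 10, 10, 10])
        d = np.abs(x[:, None] - x[None, :]) + 0.5 * (1 - np.eye(6))
        dm = DistanceMatrix(d, list("abcdef"))
        r, p = anosim(dm, ["g1"] * 3 + ["g2"] * 3, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(2 / 20)  # labeling and its mirror

    def test_exchangeable_labels_r_near_zero(self, rng):
        rs = []
        for _ in range(50):
            pts = rng.normal(size=(8, 3))
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            dm = DistanceMatrix(d, [f"s{i}" for i in range(8)])
            r, _ = anosim(dm, ["a"] * 4 + ["b"] * 4, seed=rng)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1

    @pytest.mark.parametrize("trial", range(6))
    def test_exact_p_matches_enumeration_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(6)])
        labels = ["a"] * 3 + ["b"] * 3
        r, p = anosim(dm, labels, seed=0)
        r_or, p_or = _oracle_anosim(d, np.array(labels))
        assert r == pytest.approx(r_or)
        assert p == pytest.approx(p_or)

    def test_matches_scikit_bio_statistic(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        pts = rng.normal(size=(10, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(10)]
        labels = ["a"] * 5 + ["b"] * 5
        r, _ = anosim(DistanceMatrix(d, ids), labels, seed=0)
        ref = sk_anosim(skbio.DistanceMatrix(d, ids), grouping=labels,
                        permutations=99)
        assert r == pytest.approx(ref["test statistic"])

    def test_permutation_p_superuniform_under_null(self, rng):
        """Label-exchangeable null: P(p <= a) <= a (+ binomial slack)."""
        ps = []
        for _ in range(400):
            pts = rng.normal(size=(8, 2))
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            dm = DistanceMatrix(d, [f"s{i}" for i in range(8)])
            _, p = anosim(dm, ["a"] * 4 + ["b"] * 4, seed=rng)
            ps.append(p)
        ps = np.array(ps)
        for alpha in (0.05, 0.1, 0.25):
            rate = (ps <= alpha).mean()
            slack = 3 * np.sqrt(alpha * (1 - alpha) / len(ps))
            assert rate <= alpha + slack

    def test_group_of_size_one_raises(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), list("abc"))
        with pytest.raises(ValueError, match="size 1"):
            anosim(dm, ["a", "a", "b"], seed=0)
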