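import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bbrnet.core_tables import FeatureAnnotation, FeatureTable, SampleMetadata
from bbrnet.correlation_difference import (
    diff_pvalues_permutation_batch,
    diff_test_fisher,
    diff_test_permutation,
    difference_network,
    difference_table,
    fisher_z,
)
from bbrnet.correlation_network import all_pairs


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_hand_value(self):
        assert fisher_z(0.9) == pytest.approx(0.5 * math.log(1.9 / 0.1), rel=1e-6)

    def test_odd_symmetry(self, rng):
        for r in rng.uniform(-0.99, 0.99, size=10):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r))

    def test_unit_rho_clamped_not_infinite(self):
        assert np.isfinite(fisher_z(1.0))

    def test_beyond_unit_raises(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)


class TestDiffTestFisher:
    def test_equal_correlations_p_one(self):
        _, p = diff_test_fisher(0.5, 10, 0.5, 10)
        assert p == pytest.approx(1.0)

    def test_hand_value(self):
        stat, p = diff_test_fisher(0.9, 6, 0.0, 6)
        assert stat == pytest.approx(1.803, abs=1e-3)
        assert p == pytest.approx(0.0714, abs=1e-3)

    def test_swapping_groups_negates_stat_preserves_p(self):
        s1, p1 = diff_test_fisher(0.8, 8, -0.2, 10)
        s2, p2 = diff_test_fisher(-0.2, 10, 0.8, 8)
        assert s1 == pytest.approx(-s2)
        assert p1 == pytest.approx(p2)

    def test_small_n_raises(self):
        with pytest.raises(ValueError, match="n > 3"):
            diff_test_fisher(0.5, 3, 0.2, 10)


def _oracle_perm_diff(x1, y1, x2, y2):
    """Independent enumeration with scipy Spearman, constants -> rho 0."""

    def rho(a, bb):
        if np.all(a == a[0]) or np.all(bb == bb[0]):
            return 0.0
        return sps.spearmanr(a, bb).statistic

    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    n1, n = len(x1), len(x)
    obs = abs(rho(x1, y1) - rho(x2, y2))
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        d = abs(rho(x[mask], y[mask]) - rho(x[~mask], y[~mask]))
        if d >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestDiffTestPermutation:
    def test_identical_groups_p_one(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        assert diff_test_permutation(x, y, x, y) == 1.0

    @pytest.mark.parametrize("trial", range(6))
    def test_enumerated_p_matches_oracle(self, trial):
        rng = np.random.default_rng(trial)
        if trial % 2:
            data = rng.integers(0, 3, size=(4, 4)).astype(float)
        else:
            data = rng.normal(size=(4, 4))
        p = diff_test_permutation(*data)
        assert p == pytest.approx(_oracle_perm_diff(*data))

    def test_batch_agrees_with_scalar(self, rng):
        X = rng.normal(size=(4, 30, 6))
        batch = diff_pvalues_permutation_batch(X[0], X[1], X[2], X[3])
        for i in range(10):
            scalar = diff_test_permutation(X[0][i], X[1][i], X[2][i], X[3][i])
            assert batch[i] == pytest.approx(scalar)

    def test_planted_strong_difference_shifts_p_down(self, rng):
        """Strong coupling (rho ~ 0.95) in one group only pulls the p
        distribution far below the exchangeable null's (median 0.5).

        The enumerated test stays conservative at n = 6+6 — even a
        near-perfect planted difference rarely reaches p < 0.05 — so the
        check is on the stochastic ordering, not a fixed significance.
        """
        planted, null = [], []
        for _ in range(40):
            x1 = rng.normal(size=6)
            y1 = x1 + 0.25 * rng.normal(size=6)  # tightly coupled
            x2 = rng.normal(size=6)
            y2 = rng.normal(size=6)  # independent
            planted.append(diff_test_permutation(x1, y1, x2, y2))
            null.append(
                diff_test_permutation(
                    rng.normal(size=6), rng.normal(size=6),
                    rng.normal(size=6), rng.normal(size=6),
                )
            )
        assert np.median(planted) < 0.25
        assert np.median(planted) < np.median(null) / 2

    def test_small_group_raises(self, rng):
        with pytest.raises(ValueError, match="n >= 4"):
            diff_test_permutation(
                rng.normal(size=3), rng.normal(size=3),
                rng.normal(size=6), rng.normal(size=6),
            )


def _combined_table(rng, n_features=6, perfect_pair=False):
    ids = [f"f{i}" for i in range(n_features)]
    values = pd.DataFrame(
        rng.uniform(0, 5, size=(12, n_features)),
        index=[f"B{i}" for i in range(6)] + [f"C{i}" for i in range(6)],
        columns=ids,
    )
    if perfect_pair:  # monotone f0 -> f1 within the berberine samples
        values.iloc[:6, 0] = np.arange(6, dtype=float)
        values.iloc[:6, 1] = np.arange(6, dtype=float) * 2 + 1
    feats = [FeatureAnnotation(i, "bile_acid", "cecum") for i in ids]
    meta = [SampleMetadata(f"B{i}", "berberine", "M") for i in range(6)] + [
        SampleMetadata(f"C{i}", "control", "F") for i in range(6)
    ]
    return FeatureTable(values, feats, meta)


class TestDifferenceNetwork:
    def test_identical_record_sets_empty_network(self, rng):
        t = _combined_table(rng)
        rec = all_pairs(t, "control")
        g = difference_network(rec, rec, alpha=0.5, table=t)
        assert g.number_of_edges() == 0

    def test_alpha_one_keeps_every_testable_pair(self, rng):
        t = _combined_table(rng)
        rec_c = all_pairs(t, "control")
        rec_t = all_pairs(t, "berberine")
        g = difference_network(rec_c, rec_t, alpha=1.0, table=t)
        assert g.number_of_edges() == len(rec_c)

    def test_mismatched_universes_raise(self, rng):
        t = _combined_table(rng)
        rec_c = all_pairs(t, "control")
        rec_t = all_pairs(t, "berberine").iloc[:-2]
        with pytest.raises(ValueError, match="universes differ"):
            difference_table(rec_c, rec_t)

    def test_unit_rho_routes_to_permutation(self, rng):
        t = _combined_table(rng, perfect_pair=True)
        rec_c = all_pairs(t, "control")
        rec_t = all_pairs(t, "berberine")
        diffs = difference_table(rec_c, rec_t, method="fisher_z", table=t)
        row = diffs.set_index(["feature_i", "feature_j"]).loc[("f0", "f1")]
        assert row["rho_treatment"] == pytest.approx(1.0)
        assert row["method"] == "permutation"
        others = diffs[diffs["method"] == "fisher_z"]
        assert len(others) > 0  # everything else takes the closed form

    def test_edge_attributes_carry_both_rhos(self, rng):
        t = _combined_table(rng)
        rec_c = all_pairs(t, "control")
        rec_t = all_pairs(t, "berberine")
        g = difference_network(rec_c, rec_t, alpha=1.0, table=t,
                               annotations=t.features)
        u, v, d = next(iter(g.edges(data=True)))
        assert {"rho_control", "rho_treatment", "delta", "p"} <= set(d)
        assert d["delta"] == pytest.approx(d["rho_treatment"] - d["rho_control"])

    def test_delta_bounded(self, rng):
        t = _combined_table(rng)
        diffs = difference_table(
            all_pairs(t, "control"), all_pairs(t, "berberine"), table=t
        )
        assert (diffs["delta"].abs() <= 2.0).all()
        assert (diffs["p"] > 0).all()
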