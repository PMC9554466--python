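"""Matrix regression, forward selection, VPA, hierarchical partitioning."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from mycassembly.distances import DistanceMatrix
from mycassembly.mrm import (unfold, refold, mrm_fit, forward_select,
                             vpa_two_sets, hierarchical_partition)


def dm_from_condensed(vec, labels):
    return DistanceMatrix(squareform(np.asarray(vec, float), checks=False),
                          labels)


def random_dm(n, rng, labels=None):
    vec = rng.random(n * (n - 1) // 2)
    return dm_from_condensed(vec, labels or [f"s{i}" for i in range(n)])


@pytest.fixture
def labels12():
    return [f"s{i}" for i in range(12)]


class TestUnfold:
    def test_order_and_length(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        d = DistanceMatrix(m, ["a", "b", "c"])
        np.testing.assert_allclose(unfold(d), [1, 2, 3])

    def test_refold_inverts(self, labels12):
        rng = np.random.default_rng(0)
        d = random_dm(12, rng, labels12)
        back = refold(unfold(d), labels12)
        np.testing.assert_allclose(back.values, d.values)

    def test_pair_count(self):
        for n in (3, 5, 9):
            rng = np.random.default_rng(n)
            assert len(unfold(random_dm(n, rng))) == n * (n - 1) // 2


class TestMRMFit:
    def test_response_equal_to_predictor(self, labels12):
        rng = np.random.default_rng(1)
        x = random_dm(12, rng, labels12)
        fit = mrm_fit(x, {"x": x}, permutations=199, seed=0)
        assert fit.coefficients["x"] == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coef_p["x"] == pytest.approx(1 / 200)

    def test_coefficients_match_normal_equations(self, labels12):
        rng = np.random.default_rng(2)
        y = random_dm(12, rng, labels12)
        preds = {k: random_dm(12, rng, labels12) for k in "abc"}
        fit = mrm_fit(y, preds, permutations=0)
        X = np.column_stack([np.ones(66)] +
                            [unfold(preds[k]) for k in fit.predictor_names])
        beta = np.linalg.solve(X.T @ X, X.T @ unfold(y))
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta, atol=1e-8)

    def test_orthogonal_predictors_add_r2(self, labels12):
        rng = np.random.default_rng(3)
        n_pairs = 66
        # three mutually orthogonal, centered pair vectors: QR with a
        # leading constant column makes columns 1..3 orthogonal to it
        basis = np.column_stack([np.ones(n_pairs), rng.normal(size=(n_pairs, 3))])
        q, _ = np.linalg.qr(basis)
        a, b, noise = q[:, 1], q[:, 2], q[:, 3]
        y = a + b + noise
        ydm = dm_from_condensed(y, labels12)
        fit_a = mrm_fit(ydm, {"a": dm_from_condensed(a, labels12)}, permutations=0)
        fit_b = mrm_fit(ydm, {"b": dm_from_condensed(b, labels12)}, permutations=0)
        fit_ab = mrm_fit(ydm, {"a": dm_from_condensed(a, labels12),
                               "b": dm_from_condensed(b, labels12)}, permutations=0)
        assert fit_ab.r2 == pytest.approx(fit_a.r2 + fit_b.r2, abs=1e-10)

    def test_rank_deficient_design_rejected(self, labels12):
        rng = np.random.default_rng(4)
        a = random_dm(12, rng, labels12)
        y = random_dm(12, rng, labels12)
        with pytest.raises(ValueError, match="collinear"):
            mrm_fit(y, {"a": a, "a_copy": a}, permutations=0)


class TestForwardSelect:
    def test_true_predictor_found_among_noise(self, labels12):
        rng = np.random.default_rng(5)
        hits = 0
        runs = 20
        for i in range(runs):
            true = random_dm(12, rng, labels12)
            y_vec = 2 * unfold(true) + 0.3 * rng.normal(size=66)
            y = dm_from_condensed(y_vec, labels12)
            cands = {"true": true}
            cands.update({f"noise{j}": random_dm(12, rng, labels12)
                          for j in range(5)})
            selected, _ = forward_select(y, cands, alpha=0.05,
                                         permutations=99, seed=i)
            hits += "true" in selected
        assert hits >= runs * 0.9

    def test_all_noise_mostly_empty(self, labels12):
        rng = np.random.default_rng(6)
        empty = 0
        runs = 20
        for i in range(runs):
            y = random_dm(12, rng, labels12)
            cands = {f"noise{j}": random_dm(12, rng, labels12) for j in range(4)}
            selected, _ = forward_select(y, cands, alpha=0.05,
                                         permutations=99, seed=i)
            empty += not selected
        assert empty >= runs * 0.7

    def test_alpha_one_admits_all_in_gain_order(self, labels12):
        rng = np.random.default_rng(7)
        y = random_dm(12, rng, labels12)
        cands = {f"c{j}": random_dm(12, rng, labels12) for j in range(3)}
        selected, final = forward_select(y, cands, alpha=1.01,
                                         permutations=99, seed=0)
        assert sorted(selected) == sorted(cands)
        assert final is not None and final.r2 <= 1


class TestVPA:
    def test_identical_sets_share_everything(self, labels12):
        rng = np.random.default_rng(8)
        x = random_dm(12, rng, labels12)
        y_vec = unfold(x) + 0.2 * rng.normal(size=66)
        y = dm_from_condensed(y_vec, labels12)
        x_copy = dm_from_condensed(unfold(x), labels12)
        res = vpa_two_sets(y, {"s": x}, {"e": x_copy})
        assert res.pure_space == pytest.approx(0.0, abs=1e-10)
        assert res.pure_env == pytest.approx(0.0, abs=1e-10)
        assert res.shared == pytest.approx(res.r2_full, abs=1e-10)

    def test_additivity_identity_on_random_fixtures(self, labels12):
        rng = np.random.default_rng(9)
        for _ in range(5):
            y = random_dm(12, rng, labels12)
            res = vpa_two_sets(y,
                               {"s1": random_dm(12, rng, labels12),
                                "s2": random_dm(12, rng, labels12)},
                               {"e1": random_dm(12, rng, labels12)})
            assert res.pure_space + res.pure_env + res.shared == \
                pytest.approx(res.r2_full, abs=1e-10)
            assert res.unexplained == pytest.approx(1 - res.r2_full, abs=1e-12)


class TestHierarchicalPartition:
    def test_single_group_gets_its_r2(self, labels12):
        rng = np.random.default_rng(10)
        y = random_dm(12, rng, labels12)
        g = {"only": {"a": random_dm(12, rng, labels12)}}
        res = hierarchical_partition(y, g)
        assert res.contributions["only"] == pytest.approx(res.r2_full)

    def test_contributions_sum_to_full_r2(self, labels12):
        rng = np.random.default_rng(11)
        y = random_dm(12, rng, labels12)
        groups = {
            "g1": {"a": random_dm(12, rng, labels12)},
            "g2": {"b": random_dm(12, rng, labels12),
                   "c": random_dm(12, rng, labels12)},
            "g3": {"d": random_dm(12, rng, labels12)},
        }
        res = hierarchical_partition(y, groups)
        assert sum(res.contributions.values()) == pytest.approx(res.r2_full,
                                                                abs=1e-10)

    def test_too_many_groups_rejected(self, labels12):
        rng = np.random.default_rng(12)
        y = random_dm(12, rng, labels12)
        groups = {f"g{i}": {f"v{i}": random_dm(12, rng, labels12)}
                  for i in range(6)}
        with pytest.raises(ValueError, match="5 groups"):
            hierarchical_partition(y, groups)
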