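"""Likelihood primitives and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from mmjoint.core import (
    ItemParams,
    JointDataset,
    PersonParams,
    PopulationStructure,
    QMatrix,
    instantaneous_speed,
    joint_loglik,
    logrt_logdensity,
    mr_prob,
)


@pytest.mark.parametrize(
    "tau, q, expected",
    [
        ((0.3, -0.2, 0.1), (0, 1, 0), -0.2),   # one-hot selection
        ((0.5,), (1,), 0.5),                   # K=1: multifactor == single factor
        ((0.3, -0.2), (1, 1), 0.1),            # plain summation
    ],
)
def test_instantaneous_speed_values(tau, q, expected):
    assert instantaneous_speed(np.array(tau), np.array(q)) == pytest.approx(expected)


def test_instantaneous_speed_shape_mismatch():
    with pytest.raises(ValueError):
        instantaneous_speed(np.array([0.1, 0.2]), np.array([1, 0, 0]))


class TestMrProb:
    def test_zero_logit_is_half(self):
        assert mr_prob(np.zeros(3), 0.0, np.array([1, 0, 0])) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # logit 1.2 - 0.5 = 0.7
        p = mr_prob(np.array([1.2, 0, 0]), -0.5, np.array([1, 0, 0]))
        assert p == pytest.approx(1 / (1 + np.exp(-0.7)), abs=1e-6)
        assert p == pytest.approx(0.66819, abs=1e-5)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-8, 8), st.floats(-8, 8), st.floats(-8, 8))
    def test_logistic_symmetry(self, t1, t2, d):
        theta = np.array([t1, t2])
        q = np.array([1, 0])
        total = mr_prob(theta, d, q) + mr_prob(-theta, -d, q)
        assert total == pytest.approx(1.0, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-4, 4), st.floats(-4, 4), st.floats(0.01, 2))
    def test_strictly_increasing_in_d_and_measured_theta(self, t, d, eps):
        q = np.array([1, 0])
        base = mr_prob(np.array([t, 0.0]), d, q)
        assert mr_prob(np.array([t, 0.0]), d + eps, q) > base
        assert mr_prob(np.array([t + eps, 0.0]), d, q) > base
        # unmeasured dimension has no effect
        assert mr_prob(np.array([t, 5.0]), d, q) == pytest.approx(base)

    def test_saturation_stays_inside_unit_interval(self):
        assert 0 < mr_prob(np.array([50.0]), 50.0, np.array([1])) < 1
        assert 0 < mr_prob(np.array([-50.0]), -50.0, np.array([1])) < 1


class TestLogrtDensity:
    def test_mode_value(self):
        v = logrt_logdensity(1.0, 1.0, 0.0, 2.0)
        assert v == pytest.approx(np.log(2 / np.sqrt(2 * np.pi)), abs=1e-10)
        assert v == pytest.approx(-0.22579, abs=1e-5)

    def test_quadratic_decay(self):
        mode = logrt_logdensity(0.0, 0.0, 0.0, 2.0)
        v = logrt_logdensity(0.5, 0.0, 0.0, 2.0)
        assert v == pytest.approx(mode - 0.5 * (2 * 0.5) ** 2, abs=1e-10)
        assert v == pytest.approx(-0.72579, abs=1e-5)

    def test_normalization(self):
        total, _ = quad(lambda x: np.exp(logrt_logdensity(x, 0.7, 0.2, 1.7)), -10, 10)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_rejects_nonpositive_omega(self):
        with pytest.raises(ValueError):
            logrt_logdensity(0.0, 0.0, 0.0, np.array(-1.0))


class TestQMatrix:
    def test_rejects_multiple_loadings_per_row(self):
        with pytest.raises(ValueError, match="exactly one 1"):
            QMatrix(np.array([[1, 1], [0, 1]]))

    def test_rejects_empty_dimension(self):
        with pytest.raises(ValueError, match="at least one item"):
            QMatrix(np.array([[1, 0], [1, 0]]))

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            QMatrix(np.array([[2, 0], [0, 1]]))

    def test_dim_of_item(self):
        q = QMatrix(np.array([[1, 0], [0, 1], [0, 1]]))
        assert q.dim_of_item.tolist() == [0, 1, 1]


class TestJointDataset:
    def test_rejects_nonbinary_response(self):
        q = QMatrix(np.array([[1], [1]]))
        with pytest.raises(ValueError, match="non-binary"):
            JointDataset(np.array([[0.0, 2.0]]), np.array([[1.0, 1.0]]), q)

    def test_rejects_nonpositive_observed_time(self):
        q = QMatrix(np.array([[1], [1]]))
        with pytest.raises(ValueError, match="> 0"):
            JointDataset(np.array([[0.0, 1.0]]), np.array([[-3.0, 1.0]]), q)

    def test_missingness_is_per_matrix(self):
        q = QMatrix(np.array([[1], [1]]))
        Y = np.array([[1.0, np.nan]])
        T = np.array([[np.nan, 2.0]])
        data = JointDataset(Y, T, q)
        assert data.mask_y.tolist() == [[True, False]]
        assert data.mask_t.tolist() == [[False, True]]


class TestJointLoglik:
    def _toy(self):
        q = QMatrix(np.array([[1, 0], [0, 1]]))
        persons = PersonParams(theta=[[0.4, -0.1], [0.0, 0.3]],
                               tau=[[0.2, 0.1], [-0.3, 0.0]])
        items = ItemParams(d=[0.5, -0.2], xi=[3.9, 4.2], omega=[2.0, 1.5])
        return q, persons, items

    def test_single_bernoulli_cell(self):
        q = QMatrix(np.array([[1]]))
        data = JointDataset(np.array([[1.0]]), np.array([[np.nan]]), q)
        persons = PersonParams(theta=[[0.0]], tau=[[0.0]])
        items = ItemParams(d=[0.0], xi=[4.0], omega=[2.0])
        total, comps = joint_loglik(data, persons, items)
        assert total == pytest.approx(np.log(0.5))
        assert comps.shape == (1, 1)

    def test_masked_cell_contributes_zero(self):
        q, persons, items = self._toy()
        Y = np.array([[1.0, 0.0], [np.nan, 1.0]])
        T = np.array([[50.0, 60.0], [55.0, np.nan]])
        base, _ = joint_loglik(JointDataset(Y, T, q), persons, items)
        Y2 = Y.copy()
        Y2[1, 0] = 0.0          # masked in base; observe it in a modified copy
        with_cell, _ = joint_loglik(JointDataset(Y2, T, q), persons, items)
        assert with_cell != pytest.approx(base)
        # masking it again restores the original total regardless of the value
        Y3 = Y2.copy()
        Y3[1, 0] = np.nan
        again, _ = joint_loglik(JointDataset(Y3, T, q), persons, items)
        assert again == pytest.approx(base, abs=1e-12)

    def test_matches_termwise_oracle(self):
        q, persons, items = self._toy()
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        T = np.array([[50.0, 60.0], [55.0, 45.0]])
        data = JointDataset(Y, T, q)
        total, comps = joint_loglik(data, persons, items)
        expected = 0.0
        for n in range(2):
            for i in range(2):
                p = mr_prob(persons.theta[n], items.d[i], q.entries[i].astype(float))
                expected += Y[n, i] * np.log(p) + (1 - Y[n, i]) * np.log(1 - p)
                tt = instantaneous_speed(persons.tau[n], q.entries[i].astype(float))
                expected += logrt_logdensity(np.log(T[n, i]), items.xi[i], tt,
                                             np.array(items.omega[i]))
        assert total == pytest.approx(expected, abs=1e-10)
        assert comps.sum() == pytest.approx(expected, abs=1e-10)

    def test_all_missing_warns_and_returns_zero(self):
        q = QMatrix(np.array([[1]]))
        data = JointDataset(np.array([[np.nan]]), np.array([[np.nan]]), q)
        persons = PersonParams(theta=[[0.0]], tau=[[0.0]])
        items = ItemParams(d=[0.0], xi=[4.0], omega=[2.0])
        with pytest.warns(UserWarning, match="all cells missing"):
            total, _ = joint_loglik(data, persons, items)
        assert total == 0.0

    def test_dimension_permutation_invariance(self):
        q, persons, items = self._toy()
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        T = np.array([[50.0, 60.0], [55.0, 45.0]])
        base, _ = joint_loglik(JointDataset(Y, T, q), persons, items)
        perm = [1, 0]
        q2 = QMatrix(q.entries[:, perm])
        persons2 = PersonParams(theta=persons.theta[:, perm], tau=persons.tau[:, perm])
        permuted, _ = joint_loglik(JointDataset(Y, T, q2), persons2, items)
        assert permuted == pytest.approx(base, abs=1e-12)

    def test_k1_multifactor_reduces_to_single_factor(self):
        # with one dimension, the Q-weighted speed equals the scalar speed,
        # so the multifactor time model collapses exactly to the classic one
        rng = np.random.default_rng(0)
        tau = rng.normal(size=(5, 1))
        logt = rng.normal(4, 1, size=(5, 3))
        xi = rng.normal(4, 0.5, size=3)
        ml = logrt_logdensity(logt, xi, tau @ np.ones((1, 3)), np.full(3, 2.0))
        sl = logrt_logdensity(logt, xi, tau[:, 0][:, None], np.full(3, 2.0))
        np.testing.assert_array_equal(ml, sl)


class TestPopulationStructure:
    def test_rejects_non_pd(self):
        with pytest.raises(ValueError, match="positive definite"):
            PopulationStructure(
                sigma_person=np.array([[1.0, 2.0], [2.0, 1.0]]),
                mu_item=np.zeros(2), sigma_item=np.eye(2))

    def test_mu_person_is_zero(self):
        ps = PopulationStructure(sigma_person=np.eye(4), mu_item=np.array([0.0, 4.0]),
                                 sigma_item=np.eye(2))
        assert np.all(ps.mu_person == 0)
        assert ps.mu_person.shape == (4,)
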