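import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occtime.chain_core import StageModel, TargetSet, survival_mass
from occtime.lifetime import lifetime_distribution
from occtime.occupancy import (
    OccupancyResult,
    homogeneous_closed_forms,
    joint_occupancy_table,
    occupancy_distribution,
    occupancy_moments,
    summary_stats,
)

from oracles import brute_force_occupancy_pmf, pmf_moment, random_model


class TestJointTable:
    def test_full_target_concentrates_on_diagonal(self, geometric_model):
        """With R = S, occupancy equals age: all mass sits at a = n."""
        target = TargetSet(np.array([True]))
        table = joint_occupancy_table(geometric_model, target, eps=None, n_max=6)
        for n, p in enumerate(table.values):
            assert p[n, 0] == pytest.approx(0.5**n)
            assert np.allclose(np.delete(p, n, axis=0), 0.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mass_equals_survival(self, seed):
        rng = np.random.default_rng(seed)
        model, target = random_model(rng)
        table = joint_occupancy_table(model, target, eps=None, n_max=8)
        for n in range(len(table.values)):
            assert table.mass_at(n) == pytest.approx(survival_mass(model, n), abs=1e-12)

    def test_two_state_table_matches_path_enumeration(self, drift_chain):
        model, target = drift_chain
        table = joint_occupancy_table(model, target, eps=None, n_max=3)
        # hand enumeration of the alive paths X_0 X_1 X_2 X_3, occupancy
        # counting X_0..X_2 only
        p3 = table.values[3]
        # 1,1,1,1: three 1->1 moves, a = 3
        assert p3[3, 0] == pytest.approx(0.125)
        # 1,2,2,2: the only path ending in 2 with a single visit to stage 1
        assert p3[1, 1] == pytest.approx(0.125)
        # 1,1,2,2 is the only a=2 path ending in stage 2
        assert p3[2, 1] == pytest.approx(0.125)
        assert np.all(p3 >= 0)

    def test_memory_guard(self, geometric_model):
        with pytest.raises(MemoryError, match="occupancy_moments"):
            joint_occupancy_table(
                geometric_model, TargetSet(np.array([True])), n_max=10**6,
                cell_budget=10**6,
            )


class TestDistribution:
    def test_full_target_equals_lifetime(self, geometric_model):
        target = TargetSet(np.array([True]))
        occ = occupancy_distribution(geometric_model, target)
        life = lifetime_distribution(geometric_model)
        m = min(occ.pmf.size, life.pmf.size)
        assert np.allclose(occ.pmf[:m], life.pmf[:m], rtol=0, atol=1e-15)
        assert occ.pmf[0] == 0.0

    def test_forced_chain_point_mass(self, forced_chain):
        model, target = forced_chain
        res = occupancy_distribution(model, target)
        assert np.allclose(res.pmf, [0.0, 1.0])

    def test_drift_chain_geometric_occupancy(self, drift_chain):
        model, target = drift_chain
        res = occupancy_distribution(model, target)
        a = np.arange(1, res.pmf.size)
        assert np.allclose(res.pmf[1:], 0.5**a, atol=1e-12)
        assert res.pmf[0] == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_path_enumeration(self, seed):
        """Exact agreement with exhaustive path enumeration on tiny chains."""
        rng = np.random.default_rng(seed)
        model, target = random_model(rng, d=int(rng.integers(1, 4)))
        horizon = 6
        expected, leftover = brute_force_occupancy_pmf(model, target, horizon)
        res = occupancy_distribution(model, target, eps=None, n_max=horizon)
        got = np.zeros(horizon + 1)
        got[: res.pmf.size] = res.pmf
        assert np.allclose(got, expected, atol=1e-12)
        assert res.truncation_mass == pytest.approx(leftover, abs=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_pmf_and_truncation_conserve_mass(self, seed):
        rng = np.random.default_rng(seed)
        model, target = random_model(rng)
        res = occupancy_distribution(model, target, eps=1e-10)
        assert res.pmf.sum() + res.truncation_mass == pytest.approx(1.0, abs=1e-12)

    def test_full_target_reduces_to_lifetime_formula(self, fulmar_ordinary):
        """For R = S the pmf collapses to b(a-1)^T Phi(a-1, 0) v."""
        model, _ = fulmar_ordinary
        target = TargetSet(np.ones(4, dtype=bool))
        res = occupancy_distribution(model, target)
        x = model.v.copy()
        for a in range(1, 15):
            assert res.pmf[a] == pytest.approx(float(model.b(a - 1) @ x), abs=1e-12)
            x = model.B(a - 1) @ x


class TestMoments:
    def test_geometric_first_two_moments(self, geometric_model):
        res = occupancy_moments(geometric_model, TargetSet(np.array([True])), K=2)
        assert res.moments[1] == pytest.approx(2.0, abs=1e-9)
        assert res.moments[2] == pytest.approx(6.0, abs=1e-8)
        assert res.variance == pytest.approx(2.0, abs=1e-8)

    def test_moment_vector_recursion_unrolls(self):
        """For the 1-state chain with R = S, m_1(n) = n 0.5^n."""
        from occtime.occupancy import _bracket, occupancy_moment_step

        B = np.array([[0.5]])
        mask = np.array([1.0])
        binom = np.array([[1.0, 0.0], [1.0, 1.0]])
        m = np.array([[1.0], [0.0]])  # m_0(0) = v, m_1(0) = 0
        for n in range(1, 8):
            m = occupancy_moment_step(B, mask, m, binom)
            assert m[0, 0] == pytest.approx(0.5**n)
            assert m[1, 0] == pytest.approx(n * 0.5**n)

    def test_forced_chain_degenerate(self, forced_chain):
        model, target = forced_chain
        res = occupancy_moments(model, target, K=2)
        assert res.moments[1] == pytest.approx(1.0)
        assert res.variance == pytest.approx(0.0, abs=1e-12)

    def test_fulmar_breeding_attempts_match_fundamental_matrix(self, fulmar_ordinary):
        """E[tau_R] for breeding stages equals 1^T R (I - B)^{-1} v."""
        model, target = fulmar_ordinary
        res = occupancy_moments(model, target, K=2, eps=1e-14)
        _, expected = homogeneous_closed_forms(model.B(0), model.v, target)
        assert res.moments[1] == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_moments_consistent_with_distribution(self, seed):
        """Moment accumulation equals moments of the explicit pmf, k <= 3."""
        rng = np.random.default_rng(seed)
        model, target = random_model(rng, d=int(rng.integers(2, 5)))
        dist = occupancy_distribution(model, target, eps=1e-13)
        mom = occupancy_moments(model, target, K=3, eps=1e-13)
        for k in (1, 2, 3):
            assert mom.moments[k] == pytest.approx(
                pmf_moment(dist.pmf, k), abs=1e-8, rel=1e-8
            )

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_variance_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        model, target = random_model(rng)
        res = occupancy_moments(model, target, K=2)
        assert res.variance >= 0.0


class TestSummaryAndClosedForms:
    def test_cv_from_moments(self):
        res = OccupancyResult(moments={1: 2.0, 2: 6.0})
        mean, var, cv = summary_stats(res)
        assert (mean, var) == (2.0, 2.0)
        assert cv == pytest.approx(math.sqrt(2.0) / 2.0)

    def test_degenerate_cv_zero(self, forced_chain):
        model, target = forced_chain
        res = occupancy_moments(model, target, K=2)
        assert summary_stats(res)[2] == pytest.approx(0.0, abs=1e-7)

    def test_unreachable_target_cv_nan(self):
        # stage 2 unreachable from stage 1
        model = StageModel(np.array([[0.5, 0.0], [0.0, 0.5]]), np.array([1.0, 0.0]))
        res = occupancy_moments(model, TargetSet(np.array([False, True])), K=2)
        mean, var, cv = summary_stats(res)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(cv)

    def test_closed_form_scalar(self):
        pmf_fn, expected = homogeneous_closed_forms(
            np.array([[0.5]]), np.array([1.0]), TargetSet(np.array([True]))
        )
        assert expected == pytest.approx(2.0)
        assert pmf_fn(2) == pytest.approx(0.25)

    def test_closed_form_singular_when_no_death(self):
        B = np.array([[0.3, 0.6], [0.7, 0.4]])  # column stochastic: immortal
        with pytest.raises(np.linalg.LinAlgError):
            homogeneous_closed_forms(B, np.array([1.0, 0.0]), TargetSet(np.array([True, False])))
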