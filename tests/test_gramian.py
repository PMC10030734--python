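"""Empirical Gramians against analytic oracles, and the variance
dimension used to bound electrode counts."""

import numpy as np
import pytest
import scipy.linalg

from neuroctrl.gramian_analysis import (
    ClosedLoopAssociationSystem,
    GramianResult,
    LinearDiscreteSystem,
    empirical_controllability_gramian,
    empirical_observability_gramian,
    variance_dimension,
)


def random_stable_triple(rng, n, m=1, p=1):
    A = rng.standard_normal((n, n))
    A = A - (np.max(np.linalg.eigvals(A).real) + 0.5) * np.eye(n)
    return A, rng.standard_normal((n, m)), rng.standard_normal((p, n))


class TestScalarClosedForm:
    """xdot = -x + u, y = x: both Gramians equal int exp(-2t) dt = 1/2."""

    def test_controllability(self):
        sys_ = LinearDiscreteSystem.from_continuous([[-1.0]], [[1.0]], [[1.0]], 0.01)
        w = empirical_controllability_gramian(sys_, horizon=500, dt=0.01)
        assert w.gramian[0, 0] == pytest.approx(0.5, rel=0.01)

    def test_observability(self):
        sys_ = LinearDiscreteSystem.from_continuous([[-1.0]], [[1.0]], [[1.0]], 0.01)
        w = empirical_observability_gramian(sys_, horizon=500, dt=0.01)
        assert w.gramian[0, 0] == pytest.approx(0.5, rel=0.01)


class TestLyapunovOracle:
    @pytest.mark.parametrize("trial", range(3))
    def test_matches_lyapunov_solution(self, trial):
        rng = np.random.default_rng(10 + trial)
        n = int(rng.integers(2, 7))
        A, B, C = random_stable_triple(rng, n, m=int(rng.integers(1, 3)),
                                       p=int(rng.integers(1, 3)))
        Wc_true = scipy.linalg.solve_continuous_lyapunov(A, -B @ B.T)
        Wo_true = scipy.linalg.solve_continuous_lyapunov(A.T, -C.T @ C)
        dt = 0.005
        sys_ = LinearDiscreteSystem.from_continuous(A, B, C, dt)
        horizon = int(24 / dt)
        wc = empirical_controllability_gramian(sys_, horizon=horizon, dt=dt)
        wo = empirical_observability_gramian(sys_, horizon=horizon, dt=dt)
        assert np.linalg.norm(wc.gramian - Wc_true) / np.linalg.norm(Wc_true) < 1e-2
        assert np.linalg.norm(wo.gramian - Wo_true) / np.linalg.norm(Wo_true) < 1e-2


class TestStructuralProperties:
    def test_unreachable_state_gives_zero_block(self):
        # second state decoupled from the input and from the first state
        sys_ = LinearDiscreteSystem.from_continuous(
            [[-1.0, 0.0], [0.0, -2.0]], [[1.0], [0.0]], np.eye(2), 0.01)
        w = empirical_controllability_gramian(sys_, horizon=800, dt=0.01)
        assert abs(w.gramian[1, 1]) < 1e-8 and abs(w.gramian[0, 1]) < 1e-8

    def test_unobserved_state_gives_zero_block(self):
        sys_ = LinearDiscreteSystem.from_continuous(
            [[-1.0, 0.0], [0.0, -2.0]], np.eye(2)[:, :1], [[1.0, 0.0]], 0.01)
        w = empirical_observability_gramian(sys_, horizon=800, dt=0.01)
        assert abs(w.gramian[1, 1]) < 1e-8

    def test_symmetry_and_psd(self):
        rng = np.random.default_rng(2)
        A, B, C = random_stable_triple(rng, 4, 2, 2)
        sys_ = LinearDiscreteSystem.from_continuous(A, B, C, 0.01)
        w = empirical_controllability_gramian(sys_, horizon=1000, dt=0.01)
        assert (w.gramian == w.gramian.T).all()
        assert w.eigenvalues.min() > -1e-10

    def test_impulse_scale_invariance_on_linear_system(self):
        """Doubling the impulse amplitude leaves the normalized Gramian of
        a linear system unchanged (quadratic form in the response)."""
        rng = np.random.default_rng(3)
        A, B, C = random_stable_triple(rng, 3)
        sys_ = LinearDiscreteSystem.from_continuous(A, B, C, 0.01)
        w1 = empirical_controllability_gramian(sys_, impulse_scales=(1.0,),
                                               horizon=600, dt=0.01)
        w2 = empirical_controllability_gramian(sys_, impulse_scales=(2.0,),
                                               horizon=600, dt=0.01)
        assert np.allclose(w1.gramian, w2.gramian, atol=1e-8)


class TestVarianceDimension:
    def test_examples(self):
        assert variance_dimension(np.array([9.0, 1.0]), 0.9) == 1
        assert variance_dimension(np.array([1.0, 1.0, 1.0, 0.0]), 0.9) == 3
        assert variance_dimension(np.ones(10), 0.9) == 9

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        eig = np.sort(rng.uniform(0, 1, size=12))[::-1]
        dims = [variance_dimension(eig, t) for t in (0.3, 0.5, 0.7, 0.9, 0.99)]
        assert dims == sorted(dims)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            variance_dimension(np.zeros(4), 0.9)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            variance_dimension(np.ones(3), 1.5)


class TestClosedLoopProbing:
    def test_decoupled_association_layer_bound_equals_impulse_rank(self):
        """With zero recurrence and identity stimulation, each electrode's
        response spans its own direction: the Gramian is diagonal and the
        variance dimension equals 90% of the active channels."""
        from neuroctrl.dynamics import NoiseSpec
        from neuroctrl.environments import double_integrator_model
        from neuroctrl.rnn_controller import init_rnn

        rnn = init_rnn([10], 2, 1, seed=0)
        rnn.layers[0].A_rec[:] = 0.0
        rnn.layers[0].B_in[:] = 0.0
        rnn.readout.C_out[:] = 0.0
        model = double_integrator_model(NoiseSpec.zero(2, 1))
        sys_ = ClosedLoopAssociationSystem(rnn, model, np.eye(2), 0.1, settle=10)
        w = empirical_controllability_gramian(sys_, impulse_scales=(0.1,),
                                              horizon=20, dt=1.0)
        off_diag = w.gramian - np.diag(np.diag(w.gramian))
        assert np.abs(off_diag).max() < 1e-10
        assert w.variance_dim == 9

    def test_bound_never_exceeds_association_size(self, trained_particle_net):
        from neuroctrl.dynamics import NoiseSpec
        from neuroctrl.environments import double_integrator_model
        from neuroctrl.gramian_analysis import electrode_lower_bound

        model = double_integrator_model(NoiseSpec.zero(2, 1))
        bc, bo = electrode_lower_bound(trained_particle_net, model, np.eye(2), 0.1,
                                       horizon=30)
        n = trained_particle_net.n_association
        assert 1 <= bc <= n and 1 <= bo <= n
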