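"""Bare/dressed resolvent against closed forms and the walk-sum oracle."""

import numpy as np
import pytest

from walksum import (
    FrequencyGrid,
    LocalGainParams,
    bare_resolvent,
    dressed_resolvent,
    heterogeneous_dressed_resolvent,
    local_gain,
    walk_sum_truncated,
)
from walksum.connectome import Connectome, NodePartition
from walksum.errors import ConvergenceError
from tests.conftest import random_subunity_connectome


class TestLocalGain:
    def test_unity_at_zero_frequency(self):
        assert local_gain(0.0, LocalGainParams(10.0, 0.3)) == pytest.approx(1 + 0j)

    def test_resonance_magnitude_and_phase(self):
        # at f = omega0 the gain is 1/(2 i zeta)
        val = local_gain(10.0, LocalGainParams(10.0, 0.5))
        assert abs(val) == pytest.approx(1.0)
        assert np.angle(val) == pytest.approx(-np.pi / 2)
        val = local_gain(10.0, LocalGainParams(10.0, 0.3))
        assert abs(val) == pytest.approx(1 / 0.6)

    def test_scale_invariance_in_f_over_omega0(self):
        a = local_gain(5.0, LocalGainParams(10.0, 0.2))
        b = local_gain(50.0, LocalGainParams(100.0, 0.2))
        assert a == pytest.approx(b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LocalGainParams(0.0, 0.3)
        with pytest.raises(ValueError):
            LocalGainParams(10.0, -0.1)


class TestBareResolvent:
    def test_identity_for_zero_weights(self):
        conn = Connectome(
            weights=np.zeros((3, 3)), distances=np.ones((3, 3)) - np.eye(3)
        )
        fld = bare_resolvent(conn, FrequencyGrid.default())
        assert np.allclose(fld.H, np.eye(3))

    def test_matches_explicit_inversion(self, hub48):
        grid = FrequencyGrid(f=np.array([3.0, 11.0, 40.0]))
        fld = bare_resolvent(hub48, grid)
        for k, f in enumerate(grid.f):
            z = np.exp(2j * np.pi * f * grid.T)
            expected = np.linalg.inv(np.eye(48) - z * hub48.weights)
            assert np.max(np.abs(fld.H[k] - expected)) < 1e-12

    def test_two_node_closed_form(self, two_node):
        # (I - zC)^{-1} for 2x2 with C = [[0,c],[c,0]]:
        # 1/(1 - z^2 c^2) * [[1, zc], [zc, 1]]
        grid = FrequencyGrid(f=np.array([10.0]), T=0.010)
        fld = bare_resolvent(two_node, grid)
        z = np.exp(2j * np.pi * 10.0 * 0.010)
        det = 1 - (z * 0.5) ** 2
        expected = np.array([[1, z * 0.5], [z * 0.5, 1]]) / det
        assert np.max(np.abs(fld.H[0] - expected)) < 1e-12

    def test_supercritical_raises_with_radius(self):
        conn = Connectome(
            weights=np.array([[0.0, 0.6], [0.6, 0.0]]) / 0.5,
            distances=np.array([[0.0, 1.0], [1.0, 0.0]]),
        )
        with pytest.raises(ConvergenceError, match="1.2"):
            bare_resolvent(conn, FrequencyGrid.default())

    def test_iq_recompose_exactly(self, hub48_field):
        assert np.array_equal(
            hub48_field.I + 1j * hub48_field.Q, hub48_field.H
        )

    def test_q_vanishes_when_delay_zero(self, hub48):
        fld = bare_resolvent(hub48, FrequencyGrid(f=np.array([5.0, 20.0]), T=0.0))
        assert np.max(np.abs(fld.Q)) < 1e-12

    def test_hermitian_frequency_symmetry(self, two_node):
        # H(-f) = conj(H(f)): evaluate via T -> -T which flips the phase
        f = np.array([4.0, 17.0])
        pos = bare_resolvent(two_node, FrequencyGrid(f=f, T=0.010))
        z_neg = np.exp(-2j * np.pi * f * 0.010)
        for k in range(2):
            expected = np.linalg.inv(np.eye(2) - z_neg[k] * two_node.weights)
            assert np.allclose(np.conj(pos.H[k]), expected, atol=1e-12)

    def test_offdiagonal_phase_continuous(self, two_node):
        fld = bare_resolvent(two_node, FrequencyGrid.default())
        phase = np.unwrap(np.angle(fld.H[:, 0, 1]))
        assert np.max(np.abs(np.diff(phase))) < 0.5  # no branch jumps


class TestWalkSumOracle:
    def test_k0_is_identity(self, two_node):
        assert np.array_equal(
            walk_sum_truncated(two_node, 10.0, 0.01, 0), np.eye(2)
        )

    def test_k1_first_order(self, two_node):
        z = np.exp(2j * np.pi * 10.0 * 0.01)
        expected = np.eye(2) + z * two_node.weights
        assert np.allclose(
            walk_sum_truncated(two_node, 10.0, 0.01, 1), expected
        )

    def test_geometric_tail_bound_at_radius_half(self, two_node):
        grid = FrequencyGrid(f=np.array([10.0]))
        fld = bare_resolvent(two_node, grid)
        K = 20
        approx = walk_sum_truncated(two_node, 10.0, grid.T, K)
        bound = 0.5 ** (K + 1) / (1 - 0.5)  # ~1e-6, well above roundoff
        assert np.max(np.abs(approx - fld.H[0])) <= bound

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_agreement_random_connectomes(self, seed):
        rng = np.random.default_rng(seed)
        conn = random_subunity_connectome(rng, n=rng.integers(4, 13))
        rho = conn.spectral_radius
        grid = FrequencyGrid(f=np.array([1.0, 12.5, 33.0, 45.0]))
        fld = bare_resolvent(conn, grid)
        K = min(int(np.ceil(np.log(1e-10 * (1 - rho)) / np.log(rho))), 10_000)
        for k, f in enumerate(grid.f):
            approx = walk_sum_truncated(conn, f, grid.T, K)
            tail = rho ** (K + 1) / (1 - rho)
            assert np.max(np.abs(approx - fld.H[k])) <= max(tail, 1e-10)


class TestDressedResolvent:
    def test_zero_coupling_literal_reading_gives_inverse_gain(self):
        conn = Connectome(
            weights=np.zeros((2, 2)), distances=np.array([[0.0, 1.0], [1.0, 0.0]])
        )
        p = LocalGainParams(10.0, 0.3)
        grid = FrequencyGrid(f=np.array([6.0, 10.0]))
        fld = dressed_resolvent(conn, grid, p, reading="literal")
        lv = local_gain(grid.f, p)
        for k in range(2):
            assert np.allclose(fld.H[k], np.eye(2) / lv[k])

    def test_zero_coupling_gain_outside_gives_gain(self):
        conn = Connectome(
            weights=np.zeros((2, 2)), distances=np.array([[0.0, 1.0], [1.0, 0.0]])
        )
        p = LocalGainParams(10.0, 0.3)
        grid = FrequencyGrid(f=np.array([6.0, 10.0]))
        fld = dressed_resolvent(conn, grid, p, reading="gain_outside")
        lv = local_gain(grid.f, p)
        for k in range(2):
            assert np.allclose(fld.H[k], np.eye(2) * lv[k])

    def test_overdamped_high_omega0_limit_recovers_bare(self, two_node):
        # l -> 1 over the grid when omega0 is far above it and zeta small
        grid = FrequencyGrid.default()
        p = LocalGainParams(omega0=1e5, zeta=1e-3)
        dressed = dressed_resolvent(two_node, grid, p, reading="gain_outside")
        bare = bare_resolvent(two_node, grid)
        assert np.max(np.abs(dressed.H - bare.H)) < 1e-5

    def test_matches_dressed_series_oracle(self, two_node):
        # gain-outside reading resums sum_k l^{k+1} (zC)^k
        p = LocalGainParams(10.0, 0.3)
        grid = FrequencyGrid(f=np.array([8.0]))
        fld = dressed_resolvent(two_node, grid, p, reading="gain_outside")
        lv = complex(local_gain(8.0, p))
        z = np.exp(2j * np.pi * 8.0 * grid.T)
        acc = np.zeros((2, 2), dtype=complex)
        term = lv * np.eye(2, dtype=complex)
        for _ in range(400):
            acc += term
            term = term @ (lv * z * two_node.weights)
        assert np.max(np.abs(fld.H[0] - acc)) < 1e-10

    def test_literal_reading_is_scaled_bare(self, two_node):
        p = LocalGainParams(9.0, 0.4)
        grid = FrequencyGrid(f=np.array([3.0, 12.0]))
        dressed = dressed_resolvent(two_node, grid, p, reading="literal")
        bare = bare_resolvent(two_node, grid)
        lv = local_gain(grid.f, p)
        assert np.allclose(dressed.H, bare.H / lv[:, None, None])

    def test_nonconvergent_gain_warns(self, two_node):
        # |l| * rho >= 1 near resonance with tiny damping
        with pytest.warns(RuntimeWarning, match="not absolutely convergent"):
            dressed_resolvent(
                two_node,
                FrequencyGrid.default(),
                LocalGainParams(10.0, 0.05),
                reading="gain_outside",
            )


class TestHeterogeneousDressing:
    def test_shared_params_reduce_to_homogeneous(self, hub48):
        p = LocalGainParams(8.0, 0.3)
        part = NodePartition(
            group_of=np.arange(48) % 3, thresholds=np.array([0.0, 0.0])
        )
        grid = FrequencyGrid(f=np.array([5.0, 11.0]))
        het = heterogeneous_dressed_resolvent(
            hub48, grid, part, {0: p, 1: p, 2: p}, reading="gain_outside"
        )
        hom = dressed_resolvent(hub48, grid, p, reading="gain_outside")
        assert np.max(np.abs(het.H - hom.H)) < 1e-10

    def test_three_node_hand_computation(self):
        # single-node groups: H = (L - L z C)^{-1} assembled by hand
        w = np.array([[0, 0.2, 0.1], [0.2, 0, 0.3], [0.1, 0.3, 0]])
        conn = Connectome(weights=w, distances=np.ones((3, 3)) - np.eye(3))
        part = NodePartition(group_of=np.array([0, 1, 2]), thresholds=np.zeros(2))
        params = {
            0: LocalGainParams(7.5, 0.20),
            1: LocalGainParams(6.5, 0.15),
            2: LocalGainParams(6.0, 0.15),
        }
        grid = FrequencyGrid(f=np.array([9.0]))
        fld = heterogeneous_dressed_resolvent(
            conn, grid, part, params, reading="literal"
        )
        lvec = np.array([complex(local_gain(9.0, params[g])) for g in range(3)])
        z = np.exp(2j * np.pi * 9.0 * grid.T)
        A = np.diag(lvec) @ (np.eye(3) - z * w)
        assert np.max(np.abs(fld.H[0] - np.linalg.inv(A))) < 1e-12

    def test_paper_style_group_values_run(self, hub48):
        from walksum import partition_by_degree

        part = partition_by_degree(hub48, n_groups=3)
        params = {
            0: LocalGainParams(7.5, 0.20),
            1: LocalGainParams(6.5, 0.15),
            2: LocalGainParams(6.0, 0.15),
        }
        fld = heterogeneous_dressed_resolvent(
            hub48, FrequencyGrid.default(), part, params, reading="gain_outside"
        )
        assert np.all(np.isfinite(fld.H))

    def test_missing_group_params_rejected(self, hub48):
        from walksum import partition_by_degree

        part = partition_by_degree(hub48, n_groups=3)
        with pytest.raises(ValueError, match="missing"):
            heterogeneous_dressed_resolvent(
                hub48,
                FrequencyGrid.default(),
                part,
                {0: LocalGainParams(8.0, 0.3)},
            )
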