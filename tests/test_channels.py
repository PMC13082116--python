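"""Distance binning, channel correlations, crossover and the C1–C5 battery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from walksum import (
    BandScheme,
    bare_resolvent,
    channel_distance_rho,
    channel_divergence,
    channel_rho_curves,
    compare_group_profiles,
    distance_profile,
    evaluate_predictions,
    q_crossover,
    salience,
)
from walksum.channels import bin_by_distance, upper_triangle
from walksum.connectome import Connectome
from walksum.errors import BandCoverageError, BinningError
from walksum.resolvent import FrequencyGrid


def brute_force_spearman(x, y):
    """Independent midrank-and-Pearson oracle for Spearman's rho."""

    def midranks(a):
        order = np.argsort(a, kind="stable")
        ranks = np.empty(len(a), dtype=float)
        i = 0
        sorted_a = a[order]
        while i < len(a):
            j = i
            while j + 1 < len(a) and sorted_a[j + 1] == sorted_a[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float("nan") if denom == 0 else float((rx * ry).sum() / denom)


class TestBinByDistance:
    def test_constant_field_every_bin_holds_constant(self):
        d = np.array([5.0, 20.0, 35.0, 60.0, 80.0])
        means, counts, edges, nexc = bin_by_distance(np.full(5, 3.3), d, n_bins=4)
        assert nexc == 0
        assert counts.sum() == 5
        finite = np.isfinite(means)
        assert np.allclose(means[finite], 3.3)

    def test_half_open_bins_hand_case(self):
        # distances 10, 50, 90 with 2 equal-width bins over [10, 90]:
        # [10, 50) holds only d=10; [50, 90] holds 50 and 90
        d = np.array([10.0, 50.0, 90.0])
        v = np.array([1.0, 2.0, 4.0])
        means, counts, edges, _ = bin_by_distance(v, d, n_bins=2)
        np.testing.assert_allclose(edges, [10.0, 50.0, 90.0])
        np.testing.assert_allclose(counts, [1, 2])
        np.testing.assert_allclose(means, [1.0, 3.0])

    def test_counts_cover_upper_triangle(self, hub48, hub48_field):
        prof = distance_profile(hub48_field, hub48.distances, n_bins=20)
        assert prof.counts.sum() + prof.n_excluded == 48 * 47 // 2

    def test_zero_distance_pairs_excluded_and_counted(self):
        d = np.array([0.0, 10.0, 20.0, 30.0])
        v = np.ones(4)
        _, counts, _, nexc = bin_by_distance(v, d, n_bins=2)
        assert nexc == 1
        assert counts.sum() == 3

    def test_degenerate_binning_rejected(self):
        with pytest.raises(BinningError):
            bin_by_distance(np.ones(3), np.full(3, 7.0), n_bins=4)
        with pytest.raises(BinningError):
            bin_by_distance(np.ones(3), np.array([1.0, 2.0, 3.0]), n_bins=1)


class TestSpearmanMachinery:
    @settings(max_examples=50, deadline=None, derandomize=True,
              database=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=-5, max_value=5),
                st.integers(min_value=1, max_value=50),
            ),
            min_size=4,
            max_size=50,
        )
    )
    def test_agrees_with_brute_force_midrank_oracle(self, pairs):
        vals = np.array([p[0] for p in pairs], dtype=float)
        dists = np.array([p[1] for p in pairs], dtype=float)
        expected = brute_force_spearman(vals, dists)
        got = stats.spearmanr(vals, dists).statistic
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_five_pair_tie_hand_example(self):
        vals = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        d = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        assert stats.spearmanr(vals, d).statistic == pytest.approx(
            brute_force_spearman(vals, d)
        )

    def test_monotone_values_give_unit_rho(self, hub48_field, hub48):
        # replace the field values by the distances themselves at one freq
        class Fake:
            grid = hub48_field.grid
            I = np.broadcast_to(  # noqa: E741
                hub48.distances, hub48_field.I.shape
            )
            Q = np.broadcast_to(hub48.distances, hub48_field.I.shape)

        assert channel_distance_rho(
            Fake(), hub48.distances, "I", 10.0
        ) == pytest.approx(1.0)

    def test_constant_values_give_nan(self, hub48):
        class Fake:
            grid = FrequencyGrid(f=np.array([10.0]))
            I = np.ones((1, 48, 48))  # noqa: E741
            Q = np.ones((1, 48, 48))

        assert np.isnan(channel_distance_rho(Fake(), hub48.distances, "I", 10.0))

    def test_min_distance_excludes_pairs(self, hub48, hub48_field):
        full = channel_distance_rho(hub48_field, hub48.distances, "Q", 10.0)
        thresh = channel_distance_rho(
            hub48_field, hub48.distances, "Q", 10.0, min_distance=60.0
        )
        assert full != thresh  # different pair sets

    def test_curves_match_per_frequency_calls(self, hub48, hub48_field):
        rho_i, rho_q = channel_rho_curves(hub48_field, hub48.distances)
        for k in [0, 30, 88]:
            f = hub48_field.grid.f[k]
            assert rho_i[k] == pytest.approx(
                channel_distance_rho(hub48_field, hub48.distances, "I", f),
                abs=1e-10,
            )
            assert rho_q[k] == pytest.approx(
                channel_distance_rho(hub48_field, hub48.distances, "Q", f),
                abs=1e-10,
            )


class TestQCrossover:
    def test_interpolated_hand_case(self):
        # +0.10 at 12.5 Hz, -0.15 at 13.0 Hz -> 12.5 + 0.5*(0.10/0.25)
        freqs = np.array([12.0, 12.5, 13.0])
        rho = np.array([0.2, 0.10, -0.15])
        assert q_crossover(freqs, rho) == pytest.approx(12.70)

    def test_all_positive_absent(self):
        assert q_crossover(np.array([1.0, 2.0]), np.array([0.3, 0.1])) is None

    def test_exact_zero_at_grid_point(self):
        freqs = np.array([10.0, 10.5, 11.0])
        rho = np.array([0.2, 0.0, -0.1])
        assert q_crossover(freqs, rho) == pytest.approx(10.5)

    def test_first_crossing_wins(self):
        freqs = np.arange(1.0, 6.0)
        rho = np.array([0.5, -0.5, 0.5, -0.5, 0.5])
        assert q_crossover(freqs, rho) == pytest.approx(1.5)


class TestChannelDivergence:
    def test_equal_curves_give_zero_and_first_gridpoint(self):
        f = np.array([1.0, 2.0, 3.0])
        rho = np.array([0.1, -0.2, 0.4])
        d, omega_c = channel_divergence(f, rho, rho)
        assert not d.any()
        assert omega_c == 1.0

    def test_unique_minimum_located(self):
        f = np.array([10.0, 10.5, 11.0])
        d, omega_c = channel_divergence(
            f, np.array([0.0, 0.0, 0.0]), np.array([-0.1, -0.5, -0.2])
        )
        assert omega_c == 10.5

    def test_invariant_to_common_offset(self):
        f = np.arange(1.0, 5.0)
        ri = np.array([0.1, 0.2, 0.0, -0.1])
        rq = np.array([0.3, -0.2, 0.1, 0.2])
        d1, w1 = channel_divergence(f, ri, rq)
        d2, w2 = channel_divergence(f, ri + 0.3, rq + 0.3)
        np.testing.assert_allclose(d1, d2)
        assert w1 == w2


class TestSalience:
    def test_zero_weight_connectome_zero_salience(self):
        conn = Connectome(
            weights=np.zeros((4, 4)), distances=np.ones((4, 4)) - np.eye(4)
        )
        fld = bare_resolvent(conn, FrequencyGrid.default())
        assert np.max(np.abs(salience(fld))) < 1e-20

    def test_quadratic_scaling(self, ring24_field):
        s = salience(ring24_field)

        class Scaled:
            I = 3.0 * ring24_field.I  # noqa: E741
            Q = 3.0 * ring24_field.Q

        np.testing.assert_allclose(salience(Scaled()), 9.0 * s)

    def test_matches_brute_force_variance(self, ring24_field):
        s = salience(ring24_field)
        k = 17
        iv = upper_triangle(ring24_field.I[k])
        qv = upper_triangle(ring24_field.Q[k])
        expected = np.var(iv) + np.var(qv)
        assert s[k] == pytest.approx(expected, rel=1e-12)


class TestPredictionBattery:
    def test_report_well_formed_on_hub_fixture(self, hub48, hub48_field):
        rep = evaluate_predictions(
            hub48_field, hub48.distances, n_perm=200, perm_seed=0
        )
        assert set(rep.verdicts) == {"c1", "c2", "c3", "c4", "c5"}
        assert rep.divergence == pytest.approx(rep.rho_q - rep.rho_i, nan_ok=True)
        assert rep.omega_c_hz in rep.freqs
        d = rep.to_dict()
        assert d["predictions"]["c1"]["p_permutation"] is not None
        import json

        json.dumps(d)  # fully serialisable

    def test_zero_weight_connectome_fails_c1_gracefully(self):
        conn = Connectome(
            weights=np.zeros((6, 6)),
            distances=np.abs(
                np.subtract.outer(np.arange(6.0), np.arange(6.0))
            )
            * 20.0,
        )
        fld = bare_resolvent(conn, FrequencyGrid.default())
        rep = evaluate_predictions(fld, conn.distances, n_perm=10)
        assert rep.verdicts["c1"] is False
        assert rep.q_crossover_hz is None

    def test_missing_alpha_coverage_rejected(self, hub48):
        fld = bare_resolvent(hub48, FrequencyGrid(f=np.arange(20.0, 45.5, 0.5)))
        with pytest.raises(BandCoverageError):
            evaluate_predictions(fld, hub48.distances)

    def test_crossover_in_band_on_default_fixture(self, hub48, hub48_field):
        rep = evaluate_predictions(hub48_field, hub48.distances, n_perm=50)
        assert rep.q_crossover_hz is not None
        assert 1.0 < rep.q_crossover_hz < 45.0


class TestGroupProfileComparison:
    def test_identical_profiles_unit_rho(self, hub48, hub48_field):
        prof = distance_profile(hub48_field, hub48.distances)
        out = compare_group_profiles(prof, prof)
        for name, _, _ in BandScheme.canonical():
            assert out[name] == pytest.approx(1.0)

    def test_reversed_bins_of_monotone_profile_give_minus_one(
        self, hub48, hub48_field
    ):
        import copy

        prof = distance_profile(hub48_field, hub48.distances)
        mono = copy.deepcopy(prof)
        mono.mean_i = np.tile(
            np.arange(prof.n_bins, dtype=float), (prof.freqs.size, 1)
        )
        rev = copy.deepcopy(mono)
        rev.mean_i = rev.mean_i[:, ::-1]
        out = compare_group_profiles(mono, rev)
        assert out["alpha"] == pytest.approx(-1.0)

    def test_incompatible_binning_rejected(self, hub48, hub48_field):
        a = distance_profile(hub48_field, hub48.distances, n_bins=20)
        b = distance_profile(hub48_field, hub48.distances, n_bins=10)
        with pytest.raises(BinningError):
            compare_group_profiles(a, b)
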