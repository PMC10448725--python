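"""Multiple-time-origin correlation estimators against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helfand.correlation import (
    SamplingPlan,
    cross_displacement_series,
    dipole_displacement_series,
    mean_square_displacement,
    onsager_matrix,
    self_terms_dipole_series,
)

from conftest import (
    brute_cross,
    brute_dipole_msd,
    brute_msd,
    make_trajectory,
    random_walk_trajectory,
)

LINEAR = SamplingPlan(origin_stride=1, lag_grid="linear")


class TestSamplingPlan:
    def test_blocked_grid_is_logarithmic(self):
        traj = make_trajectory(np.zeros((2001, 2, 3)), n_cations=1,
                               n_anions=1)
        lags = SamplingPlan().lag_frames(traj)
        assert lags[0] == 1 and lags.max() <= 1000
        assert set(lags[:9]) == set(range(1, 10))
        assert 900 in lags and 950 not in lags

    def test_max_lag_beyond_duration_rejected(self):
        traj = make_trajectory(np.zeros((11, 2, 3)), n_cations=1, n_anions=1)
        plan = SamplingPlan(max_lag=5.0)  # duration is 1 ps at dt=0.1
        with pytest.raises(ValueError, match="duration"):
            plan.lag_frames(traj)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SamplingPlan(origin_stride=0)
        with pytest.raises(ValueError):
            SamplingPlan(lag_grid="log")


class TestMeanSquareDisplacement:
    def test_static_positions_give_zero(self):
        traj = make_trajectory(np.ones((30, 4, 3)), n_cations=2, n_anions=2)
        series = mean_square_displacement(traj, "cation", LINEAR)
        np.testing.assert_array_equal(series.values, 0.0)

    def test_ballistic_single_particle_grows_quadratically(self):
        # +1 nm per frame along x: MSD at lag k frames is k^2 nm^2
        pos = np.zeros((12, 1, 3))
        pos[:, 0, 0] = np.arange(12.0)
        traj = make_trajectory(pos, n_cations=1, n_anions=0, dt=1.0)
        series = mean_square_displacement(traj, "cation", LINEAR)
        np.testing.assert_allclose(series.values, series.lags**2, rtol=1e-12)

    def test_matches_brute_force_all_origins(self):
        rng = np.random.default_rng(10)
        traj = random_walk_trajectory(rng, 50, 3, 2)
        series = mean_square_displacement(traj, "cation", LINEAR)
        lags_frames = np.arange(1, series.lags.size)
        ref = brute_msd(traj.positions, lags_frames, traj.role_mask("cation"))
        np.testing.assert_allclose(series.values[1:], ref, rtol=1e-12)

    def test_wrapped_input_rejected(self):
        traj = make_trajectory(np.zeros((5, 2, 3)), n_cations=1, n_anions=1,
                               wrapped=True)
        with pytest.raises(ValueError, match="unwrapped"):
            mean_square_displacement(traj, "cation", LINEAR)

    def test_empty_selection_rejected(self):
        traj = make_trajectory(np.zeros((5, 2, 3)), n_cations=1, n_anions=1)
        with pytest.raises(ValueError, match="empty"):
            mean_square_displacement(traj, "solvent", LINEAR)

    def test_origin_stride_subsamples_origins(self):
        rng = np.random.default_rng(11)
        traj = random_walk_trajectory(rng, 40, 2, 2)
        s1 = mean_square_displacement(traj, "cation", LINEAR)
        s3 = mean_square_displacement(
            traj, "cation", SamplingPlan(origin_stride=3, lag_grid="linear"))
        assert np.all(s3.origin_counts[1:] < s1.origin_counts[1:])


class TestDipoleDisplacement:
    def test_zero_charges_give_zero_series(self, charges):
        from helfand.core import ChargeAssignment

        rng = np.random.default_rng(12)
        traj = random_walk_trajectory(rng, 20, 2, 2)
        ca = ChargeAssignment(pes_set={"CAT": 0.0, "ANI": 0.0},
                              dms_set={"CAT": 0.0, "ANI": 0.0})
        series = dipole_displacement_series(traj, ca, "dms", LINEAR)
        np.testing.assert_array_equal(series.values, 0.0)

    def test_hand_computed_two_ion_case(self, charges):
        # +1e ion moves +1 nm/frame, -1e ion fixed: |dM| after k frames
        # is k e nm, so the series value is k^2 e^2 nm^2
        pos = np.zeros((10, 2, 3))
        pos[:, 0, 0] = np.arange(10.0)
        pos[:, 1, 1] = 3.0
        traj = make_trajectory(pos, n_cations=1, n_anions=1, dt=1.0)
        series = dipole_displacement_series(traj, charges, "dms", LINEAR)
        np.testing.assert_allclose(series.values, series.lags**2, rtol=1e-12)

    def test_matches_pairwise_double_loop(self, charges):
        rng = np.random.default_rng(13)
        traj = random_walk_trajectory(rng, 20, 4, 4, n_solvent=2)
        series = dipole_displacement_series(traj, charges, "dms", LINEAR)
        q = charges.charges_for(traj, "dms")
        ref = brute_dipole_msd(traj.positions, q,
                               np.arange(1, series.lags.size))
        np.testing.assert_allclose(series.values[1:], ref, rtol=1e-12)

    def test_non_neutral_set_rejected(self):
        from helfand.core import ChargeAssignment

        rng = np.random.default_rng(14)
        traj = random_walk_trajectory(rng, 10, 2, 2)
        ca = ChargeAssignment(pes_set={"CAT": 1.0, "ANI": -1.0},
                              dms_set={"CAT": 1.0, "ANI": -0.5})
        with pytest.raises(ValueError, match="electroneutral"):
            dipole_displacement_series(traj, ca, "dms", LINEAR)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(lam=st.floats(min_value=0.05, max_value=20.0,
                         allow_nan=False, allow_infinity=False))
    def test_charge_quadratic_scaling_law(self, lam):
        """Scaling every charge by lambda scales the series by lambda^2."""
        from helfand.core import ChargeAssignment

        charges = ChargeAssignment(pes_set={"CAT": 0.75, "ANI": -0.75},
                                   dms_set={"CAT": 1.0, "ANI": -1.0})
        rng = np.random.default_rng(15)
        traj = random_walk_trajectory(rng, 15, 3, 3)
        base = dipole_displacement_series(traj, charges, "dms", LINEAR)
        scaled_ca = ChargeAssignment(
            pes_set=charges.pes_set,
            dms_set={k: lam * v for k, v in charges.dms_set.items()})
        scaled = dipole_displacement_series(traj, scaled_ca, "dms", LINEAR)
        np.testing.assert_allclose(scaled.values, lam**2 * base.values,
                                   rtol=1e-9)

    def test_nonnegative_and_zero_at_lag_zero(self, charges):
        rng = np.random.default_rng(16)
        traj = random_walk_trajectory(rng, 40, 4, 4)
        series = dipole_displacement_series(traj, charges, "dms",
                                            SamplingPlan())
        assert series.values[0] == 0.0
        assert np.all(series.values >= 0.0)


class TestCrossDisplacement:
    def test_static_groups_give_zero(self):
        traj = make_trajectory(np.ones((20, 4, 3)), n_cations=2, n_anions=2)
        series = cross_displacement_series(traj, "cation", "anion", LINEAR)
        np.testing.assert_array_equal(series.values, 0.0)

    def test_hand_computed_single_particle_normalisation(self):
        # one moving cation (+1 nm/frame), one static anion; A = B = cations
        # includes the i = j self term and the 1/N = 1/2 normalisation
        pos = np.zeros((8, 2, 3))
        pos[:, 0, 0] = np.arange(8.0)
        traj = make_trajectory(pos, n_cations=1, n_anions=1, dt=1.0)
        series = cross_displacement_series(traj, "cation", "cation", LINEAR)
        np.testing.assert_allclose(series.values, series.lags**2 / 2.0,
                                   rtol=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        traj = random_walk_trajectory(rng, 25, 3, 3)
        for a, b in (("cation", "cation"), ("cation", "anion")):
            series = cross_displacement_series(traj, a, b, LINEAR)
            ref = brute_cross(traj.positions, traj.role_mask(a),
                              traj.role_mask(b), traj.n_ions,
                              np.arange(1, series.lags.size))
            np.testing.assert_allclose(series.values[1:], ref, rtol=1e-12,
                                       atol=1e-15)

    def test_dipole_series_equals_charge_weighted_cross_sum(self, charges):
        """The dipole route and the group-sum decomposition are the same
        quantity: MSDD = sum_AB z_A z_B N C_AB at every lag."""
        rng = np.random.default_rng(18)
        traj = random_walk_trajectory(rng, 30, 4, 4)
        dip = dipole_displacement_series(traj, charges, "dms", LINEAR)
        n = traj.n_ions
        total = np.zeros_like(dip.values)
        for za, a in ((1.0, "cation"), (-1.0, "anion")):
            for zb, b in ((1.0, "cation"), (-1.0, "anion")):
                series = cross_displacement_series(traj, a, b, LINEAR)
                total += za * zb * n * series.values
        np.testing.assert_allclose(dip.values, total, rtol=1e-12,
                                   atol=1e-14)


class TestOnsagerMatrix:
    WINDOW = (0.1, 2.0)

    def test_static_trajectory_gives_zero_matrix(self):
        traj = make_trajectory(np.ones((30, 4, 3)), n_cations=2, n_anions=2)
        lam = onsager_matrix(traj, LINEAR, self.WINDOW)
        assert lam.lambda_pp == lam.lambda_pm == lam.lambda_mm == 0.0

    def test_cross_coefficients_identical_by_construction(self):
        rng = np.random.default_rng(19)
        traj = random_walk_trajectory(rng, 40, 3, 3)
        lam = onsager_matrix(traj, LINEAR, self.WINDOW)
        assert lam.lambda_pm == lam.lambda_mp

    def test_free_ion_diagonal_recovers_diffusivity_share(self):
        """Independent ions: Lambda_AA -> (N_A/N) D and Lambda_pm -> 0."""
        import helfand as h

        spec = h.SyntheticSpec(n_cations=200, n_anions=200, d_plus=1.0e-9,
                               d_minus=1.0e-9, box_edge=6.0, dt=0.01,
                               n_steps=20000, mode="free", seed=21)
        traj = h.simulate_free_ions(spec)
        # Brownian dynamics is diffusive at every lag, so short lags carry
        # the least time-averaging noise
        lam = onsager_matrix(traj, SamplingPlan(), (0.01, 0.5))
        d_nm2_ps = 1.0e-9 * 1e6  # m^2/s -> nm^2/ps
        expect = 0.5 * d_nm2_ps  # (N_+/N) D with N_+ = N/2
        assert lam.lambda_pp == pytest.approx(expect, rel=0.05)
        assert lam.lambda_mm == pytest.approx(expect, rel=0.05)

    def test_free_ion_cross_coefficient_ci_contains_zero(self):
        """Independent cations and anions have zero displacement
        covariance: the replicate 95% CI of Lambda_pm straddles 0."""
        import helfand as h
        from helfand.stats import combine_replicates

        values = []
        for seed in (31, 32, 33, 34, 35):
            spec = h.SyntheticSpec(n_cations=100, n_anions=100,
                                   d_plus=1.0e-9, d_minus=1.0e-9,
                                   box_edge=5.0, dt=0.01, n_steps=10000,
                                   mode="free", seed=seed)
            traj = h.simulate_free_ions(spec)
            lam = onsager_matrix(traj, SamplingPlan(), (0.01, 0.5))
            values.append(lam.lambda_pm)
        mean, sem = combine_replicates(values)
        assert abs(mean) <= 2.776 * sem  # t(0.975, 4) for 5 replicates


class TestSelfTermsSeries:
    def test_self_terms_drop_cross_correlations(self, charges):
        """On a trajectory whose + and - ions move identically, the full
        dipole series vanishes but the self-terms series does not."""
        pos = np.zeros((10, 2, 3))
        pos[:, 0, 0] = np.arange(10.0)
        pos[:, 1, 0] = np.arange(10.0)  # anion shadows the cation
        traj = make_trajectory(pos, n_cations=1, n_anions=1, dt=1.0)
        full = dipole_displacement_series(traj, charges, "dms", LINEAR)
        self_only = self_terms_dipole_series(traj, charges, "dms", LINEAR)
        np.testing.assert_allclose(full.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(self_only.values, 2.0 * self_only.lags**2,
                                   rtol=1e-12)


class TestOrderNEquivalence:
    @pytest.mark.parametrize("estimator", ["msd", "dipole", "cross"])
    def test_blocked_grid_matches_brute_force_at_shared_lags(
            self, estimator, charges):
        rng = np.random.default_rng(20)
        traj = random_walk_trajectory(rng, 100, 4, 4)
        blocked = SamplingPlan(origin_stride=1, lag_grid="order_n_blocked")
        if estimator == "msd":
            series = mean_square_displacement(traj, "anion", blocked)
            lags_frames = np.rint(series.lags[1:] / traj.dt).astype(int)
            ref = brute_msd(traj.positions, lags_frames,
                            traj.role_mask("anion"))
        elif estimator == "dipole":
            series = dipole_displacement_series(traj, charges, "pes", blocked)
            lags_frames = np.rint(series.lags[1:] / traj.dt).astype(int)
            ref = brute_dipole_msd(traj.positions,
                                   charges.charges_for(traj, "pes"),
                                   lags_frames)
        else:
            series = cross_displacement_series(traj, "cation", "anion",
                                               blocked)
            lags_frames = np.rint(series.lags[1:] / traj.dt).astype(int)
            ref = brute_cross(traj.positions, traj.role_mask("cation"),
                              traj.role_mask("anion"), traj.n_ions,
                              lags_frames)
        np.testing.assert_allclose(series.values[1:], ref, rtol=1e-12,
                                   atol=1e-15)
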