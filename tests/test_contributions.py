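"""Time-constant sensitivity coefficients, combination, and sweeps."""

import numpy as np
import pytest

from rhythmcontrib import (CombinedMeasures, ContributionSet,
                           MeasureUndefinedError, ModelParams, ProtocolError,
                           combine, contributions, perturbed_phase, sweep)


class TestPerturbedPhase:
    def test_null_perturbation_reproduces_baseline(self, default_params,
                                                   settled_default):
        from rhythmcontrib import segment
        traj, _ = settled_default
        seg = segment(traj)
        ap = seg.ap_durations[-1]
        sp = seg.sp_durations[-1]
        # delta_frac = 0 run must match the unperturbed durations
        d_ap = perturbed_phase(default_params, "s", "AP", 0.0)
        d_sp = perturbed_phase(default_params, "s", "SP", 0.0)
        assert abs(d_ap - ap) / ap < 1e-3
        assert abs(d_sp - sp) / sp < 1e-3

    def test_sole_slow_process_has_near_unit_coefficient(self):
        """Without adaptation, s alone times the active phase, so slowing
        it stretches AP by (almost) the same fraction.  The small shortfall
        is the jump/knee-passage time, which is set by the fast dynamics
        and does not stretch with tau_s."""
        p = ModelParams(theta0=0.18, g=0.0)
        cs = contributions(p)
        assert cs.Cs_AP == pytest.approx(1.0, abs=0.05)

    def test_decoupled_theta_perturbation_has_no_effect(self):
        p = ModelParams(theta0=0.18, g=0.0)
        d0 = perturbed_phase(p, "theta", "AP", 0.0)
        d1 = perturbed_phase(p, "theta", "AP", 0.04)
        assert d1 == d0  # g = 0: theta cannot influence a at all


class TestContributions:
    def test_equal_time_constants_share_active_phase_control(
            self, default_contribs):
        assert default_contribs.Cs_AP == pytest.approx(0.5, abs=0.1)
        assert default_contribs.Ctheta_AP == pytest.approx(0.5, abs=0.1)

    def test_silent_phase_is_controlled_by_adaptation(self, default_contribs):
        assert default_contribs.Cs_SP < 0.15
        assert default_contribs.Ctheta_SP > 0.8

    def test_depression_never_gains_the_silent_phase(self):
        # even with s ten times faster than theta
        cs = contributions(ModelParams(tau_s=25.0, tau_theta=250.0))
        assert cs.Cs_SP < 0.1

    def test_coefficients_in_unit_interval_and_sums_near_one(
            self, default_contribs):
        cs = default_contribs
        for c in (cs.Cs_AP, cs.Cs_SP, cs.Ctheta_AP, cs.Ctheta_SP):
            assert -0.05 <= c <= 1.05
        assert cs.sum_AP == pytest.approx(1.0, abs=0.1)
        assert cs.sum_SP == pytest.approx(1.0, abs=0.1)
        assert not cs.monotone_warning

    def test_linear_response_regime(self, default_params, default_contribs):
        cs2 = contributions(default_params, delta_frac=0.02)
        for a, b in ((cs2.Cs_AP, default_contribs.Cs_AP),
                     (cs2.Cs_SP, default_contribs.Cs_SP),
                     (cs2.Ctheta_AP, default_contribs.Ctheta_AP),
                     (cs2.Ctheta_SP, default_contribs.Ctheta_SP)):
            assert abs(a - b) < 0.02

    def test_nonrhythmic_parameters_raise(self):
        with pytest.raises(ProtocolError):
            contributions(ModelParams(theta0=0.3))


class TestCombine:
    def test_equal_coefficients_give_zero(self):
        cs = ContributionSet(Cs_AP=0.5, Cs_SP=0.2, Ctheta_AP=0.5,
                             Ctheta_SP=0.2, delta_frac=0.04)
        cb = combine(cs)
        assert cb.C_AP == 0.0 and cb.C_SP == 0.0

    def test_single_process_limit_gives_unity(self):
        cs = ContributionSet(Cs_AP=0.9, Cs_SP=0.7, Ctheta_AP=0.0,
                             Ctheta_SP=0.0, delta_frac=0.04)
        cb = combine(cs)
        assert cb.C_AP == 1.0 and cb.C_SP == 1.0

    def test_swapping_coefficients_flips_sign(self):
        cs = ContributionSet(Cs_AP=0.7, Cs_SP=0.1, Ctheta_AP=0.2,
                             Ctheta_SP=0.8, delta_frac=0.04)
        swapped = ContributionSet(Cs_AP=0.2, Cs_SP=0.8, Ctheta_AP=0.7,
                                  Ctheta_SP=0.1, delta_frac=0.04)
        assert combine(cs).C_AP == pytest.approx(-combine(swapped).C_AP)
        assert combine(cs).C_SP == pytest.approx(-combine(swapped).C_SP)

    def test_vanishing_denominator_signalled(self):
        cs = ContributionSet(Cs_AP=0.0, Cs_SP=0.5, Ctheta_AP=0.0,
                             Ctheta_SP=0.5, delta_frac=0.04)
        with pytest.raises(MeasureUndefinedError):
            combine(cs)


class TestSweep:
    def test_vanishing_adaptation_strength_hands_control_to_depression(self):
        df = sweep(ModelParams(theta0=0.12), "g",
                   [0.05, 0.5, 1.0]).to_dataframe()
        assert df["rhythmic"].all()
        # toward g = 0 both combined indices rise toward +1
        assert df["C_AP"].is_monotonic_decreasing  # sorted by increasing g
        assert df["C_SP"].is_monotonic_decreasing
        assert df["C_AP"].iloc[0] > 0.8
        assert df["C_SP"].iloc[0] > 0.4

    def test_connectivity_moves_active_phase_control_only(self):
        df = sweep(ModelParams(), "w", [0.5, 1.0, 2.0, 3.0]).to_dataframe()
        assert df["C_AP"].is_monotonic_increasing
        assert (df["C_SP"] < -0.8).all()

    def test_cell_excitability_leaves_both_indices_unchanged(self):
        df = sweep(ModelParams(), "theta0",
                   [-0.2, -0.1, 0.0, 0.1, 0.18]).to_dataframe()
        assert df["rhythmic"].all()
        assert df["C_AP"].max() - df["C_AP"].min() < 0.1
        assert df["C_SP"].max() - df["C_SP"].min() < 0.1

    def test_nonrhythmic_rows_flagged_and_retained(self):
        df = sweep(ModelParams(), "theta0", [0.0, 0.3]).to_dataframe()
        assert len(df) == 2
        assert bool(df["rhythmic"].iloc[0]) and not bool(df["rhythmic"].iloc[1])
        assert np.isnan(df["C_AP"].iloc[1])

    def test_rows_carry_full_parameter_sets(self):
        table = sweep(ModelParams(), "w", [0.5, 1.0])
        for row in table.rows:
            assert row.params.w == row.axis_value

    def test_silent_phase_index_below_active_phase_index(self):
        df = sweep(ModelParams(), "tau_ratio",
                   [0.3, 1.0, 3.0]).to_dataframe()
        assert (df["C_SP"] < df["C_AP"]).all()
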