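"""The five in-silico protocols: SERT sweep, stimulation pulse, meals,
autoreceptor homeostasis, and SSRI/agonist dosing."""

import numpy as np
import pytest

from serotonin_terminal.experiments import (
    agonist_experiment,
    homeostasis_sweep,
    meals_experiment,
    pulse_release,
    ssri_experiment,
    table4_sweep,
)
from serotonin_terminal.model import AutoreceptorConfig


@pytest.fixture(scope="module")
def sweep(params, baseline_state):
    return table4_sweep(params, state0=baseline_state)


class TestTable4Sweep:
    def test_wild_type_column(self, sweep):
        row = sweep.tables["table4"].iloc[0]
        assert row["v_tph_uM_hr"] == pytest.approx(5.57, rel=0.001)
        assert row["e5ht_nM"] == pytest.approx(0.768, rel=0.001)
        assert row["v_sert_uM_hr"] == pytest.approx(21.1, abs=0.1)

    def test_half_block_column(self, sweep):
        row = sweep.tables["table4"].iloc[1]
        assert row["f"] == 0.5
        assert row["e5ht_nM"] == pytest.approx(1.18, rel=0.01)
        assert row["v5ht_uM"] == pytest.approx(19.9, rel=0.01)

    def test_knockout_column(self, sweep):
        row = sweep.tables["table4"].iloc[-1]
        assert row["v_sert_uM_hr"] == 0.0
        assert row["v5ht_uM"] == pytest.approx(6.41, rel=0.02)
        assert row["e5ht_nM"] == pytest.approx(6.2, rel=0.02)

    def test_monotone_trends_across_fractions(self, sweep):
        t = sweep.tables["table4"]
        # as f decreases: e5ht rises, v5ht falls, synthesis falls
        assert t["e5ht_nM"].is_monotonic_increasing
        assert t["v5ht_uM"].is_monotonic_decreasing
        assert t["v_tph_uM_hr"].is_monotonic_decreasing


@pytest.fixture(scope="module")
def unblocked(params, baseline_state):
    return pulse_release(params, state0=baseline_state)


@pytest.fixture(scope="module")
def half_blocked(params, baseline_state):
    return pulse_release(params, blocked_fraction=0.5, state0=baseline_state)


class TestPulse:
    def test_peak_near_two_micromolar(self, unblocked):
        assert unblocked.summary["peak_e5ht_uM"] == pytest.approx(2.0,
                                                                  rel=0.15)

    def test_peak_occurs_at_end_of_pulse(self, unblocked):
        assert unblocked.summary["t_peak_s"] == pytest.approx(0.2, abs=0.01)

    def test_half_block_raises_peak_and_doubles_decay(self, unblocked,
                                                      half_blocked):
        assert (half_blocked.summary["peak_e5ht_uM"]
                > unblocked.summary["peak_e5ht_uM"])
        ratio = (half_blocked.summary["half_life_s"]
                 / unblocked.summary["half_life_s"])
        assert 1.5 < ratio < 2.2

    def test_decay_near_linear_while_sert_saturated(self, unblocked, params):
        # while e5ht >> Km the clearance is nearly constant, so equal time
        # steps remove nearly equal amounts
        traj = unblocked.trajectories["pulse"]
        t0 = unblocked.summary["t_peak_s"] / 3600.0 + 2.0 / 3600.0
        ts = t0 + np.linspace(0.0, 0.2, 5) / 3600.0
        vals = [traj.value_at(t, "e5ht") for t in ts]
        assert min(vals) > 10 * params.sert_km
        drops = -np.diff(vals)
        assert np.ptp(drops) / np.mean(drops) < 0.15

    def test_mass_balance_over_episode(self, params, autoreceptors,
                                       baseline_state, unblocked):
        # released − (reuptake + catabolism + removal) integrates to the
        # e5ht elevation
        from scipy.integrate import quad

        from serotonin_terminal.model import TerminalState, velocities
        traj = unblocked.trajectories["pulse"]
        t0, t1 = traj.t_span
        fire = unblocked.config["pulse_rate_per_hr"]

        def net_flux(t):
            st = TerminalState.from_array(
                np.maximum(traj.state_at(t), 0.0))
            in_pulse = (2.0 / 3600.0 <= t
                        < 2.0 / 3600.0 + unblocked.config["duration_s"] / 3600.0)
            vel = velocities(st, params, autoreceptors,
                             fire=fire if in_pulse else 1.0)
            return (vel["v_release"] - vel["v_sert"] - vel["v_catab_e"]
                    - vel["v_rem"])

        total = 0.0
        cuts = [t0, 2.0 / 3600.0, 2.2 / 3600.0, t1]
        for a, b in zip(cuts[:-1], cuts[1:]):
            total += quad(net_flux, a, b, limit=400)[0]
        elevation = traj.states[-1, 6] - traj.states[0, 6]
        assert total == pytest.approx(elevation, abs=1e-3)

    def test_no_pulse_gives_flat_trajectory(self, params, baseline_state):
        res = pulse_release(params, pulse_rate=1.0, state0=baseline_state)
        traj = res.trajectories["pulse"]
        assert np.ptp(traj.states[:, 6]) < 1e-8

    def test_deterministic_reruns(self, params, baseline_state, unblocked):
        again = pulse_release(params, state0=baseline_state)
        assert again.summary == unblocked.summary


@pytest.fixture(scope="module")
def meals_result(params, baseline_state):
    return meals_experiment(params, state0=baseline_state)


class TestMeals:
    def test_unit_peak_factor_is_flat(self, params, baseline_state):
        res = meals_experiment(params, peak_factor=1.0, state0=baseline_state)
        pct = res.tables["day_percent"]
        for col in ("trp_uM", "e5ht_nM", "v_tph_uM_hr"):
            assert np.allclose(pct[col], 100.0, atol=0.01)

    def test_trp_peaks_all_same_height(self, meals_result):
        # tryptophan returns near baseline between meals, so the three
        # peaks match (unlike tyrosine in dopaminergic terminals)
        day = meals_result.tables["day_absolute"]
        trp = day["trp_uM"].to_numpy()
        t = day["time_hr"].to_numpy()
        peaks = [trp[(t >= lo) & (t <= hi)].max()
                 for lo, hi in ((8, 12), (13, 17), (19, 23))]
        assert np.ptp(peaks) / np.mean(peaks) < 0.02

    def test_synthesis_swings_more_than_e5ht(self, meals_result):
        # autoreceptor damping: the TPH flux varies far more than
        # extracellular 5-HT
        s = meals_result.summary
        assert s["swing_pct_v_tph_uM_hr"] > 2 * s["swing_pct_e5ht_nM"]

    def test_e5ht_rises_during_meals(self, meals_result):
        pct = meals_result.tables["day_percent"]
        assert pct["e5ht_nM"].max() > 100.5
        assert pct["e5ht_nM"].idxmax() > 0


class TestHomeostasis:
    @pytest.mark.parametrize("vary", ["fire", "sert_vmax", "tph_vmax"])
    def test_autoreceptors_damp_every_input(self, vary, params,
                                            baseline_state):
        res = homeostasis_sweep(params, vary=vary, state0=baseline_state)
        assert res.summary["range_on_nM"] < res.summary["range_off_nM"]
        assert res.summary["damping_factor"] > 1.0

    def test_firing_reduction_mapping(self, params, baseline_state):
        res = homeostasis_sweep(params, vary="fire",
                                grid=[0.20, 0.58, 1.0],
                                state0=baseline_state)
        t = res.tables["sweep"]
        on = t[t.autoreceptors].set_index("scale")["e5ht_pct_baseline"]
        assert on[0.58] == pytest.approx(70.0, abs=2.0)
        assert on[0.20] == pytest.approx(30.0, abs=2.0)

    def test_unknown_variable_rejected(self, params):
        with pytest.raises(ValueError):
            homeostasis_sweep(params, vary="mat_vmax")


@pytest.fixture(scope="module")
def rises(params, baseline_state):
    out = {}
    for region in ("hippocampus", "frontal_cortex"):
        for ko in (False, True):
            res = ssri_experiment(params, region=region,
                                  autoreceptor_1b_knockout=ko,
                                  state0=baseline_state)
            out[(region, ko)] = res.summary["peak_rise_pct"]
    return out


class TestSsriAndAgonist:
    def test_all_regions_rise_after_dose(self, rises):
        assert all(v > 0 for v in rises.values())

    def test_hippocampus_rises_more_than_frontal_cortex(self, rises):
        assert rises[("hippocampus", False)] > rises[("frontal_cortex", False)]
        assert rises[("hippocampus", True)] > rises[("frontal_cortex", True)]

    def test_1b_knockout_rises_more_than_wild_type(self, rises):
        assert rises[("hippocampus", True)] > rises[("hippocampus", False)]
        assert rises[("frontal_cortex", True)] > rises[("frontal_cortex", False)]

    def test_e5ht_returns_toward_elevated_equilibrium(self, params,
                                                      baseline_state):
        res = ssri_experiment(params, region="hippocampus",
                              state0=baseline_state)
        assert res.summary["final_pct"] == pytest.approx(100.0, abs=2.0)

    @pytest.mark.parametrize("region, trough", [
        ("frontal_cortex", 30.0), ("hippocampus", 70.0)])
    def test_agonist_trough_matches_steady_mapping(self, region, trough,
                                                   params, baseline_state):
        res = agonist_experiment(params, region=region,
                                 state0=baseline_state)
        assert res.summary["trough_pct"] == pytest.approx(trough, abs=5.0)

    def test_agonist_recovers_to_baseline(self, params, baseline_state):
        res = agonist_experiment(params, region="hippocampus",
                                 state0=baseline_state)
        assert res.summary["final_pct"] == pytest.approx(100.0, abs=1.0)

    def test_config_echo_sufficient_to_rerun(self, params, baseline_state):
        a = agonist_experiment(params, region="frontal_cortex",
                               state0=baseline_state)
        b = agonist_experiment(params, region=a.config["region"],
                               washout_hr=a.config["washout_hr"],
                               dose_time=a.config["dose_time_hr"],
                               state0=baseline_state)
        assert a.summary == b.summary


class TestKnockoutConfig:
    def test_1b_knockout_pins_both_factors(self):
        cfg = AutoreceptorConfig.knockout_1b()
        assert not cfg.synthesis_feedback and not cfg.release_feedback
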