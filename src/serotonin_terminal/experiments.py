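"""Scripted in-silico experiments on the terminal model.

Each experiment is a deterministic, reproducible protocol returning an
:class:`ExperimentResult` with named tables (pandas DataFrames), trajectories,
and scalar summary metrics.  Percent changes are always computed against the
pre-perturbation equilibrated baseline of the same run, never against a
global default.

The six protocols:

* ``table4_sweep`` — steady states as the unblocked SERT fraction f drops
  from 1 (wild type) to 0 (SERT knockout), i.e. progressively higher SSRI
  doses;
* ``pulse_release`` — 0.2 s of 5000/hr firing emulating brief 100 Hz
  electrical stimulation, with optional acute SERT blockade;
* ``meals_experiment`` — 24 h of meal-driven serum tryptophan;
* ``homeostasis_sweep`` — steady extracellular 5-HT as firing rate, SERT
  expression, or TPH activity are scaled, with the autoreceptors on vs off;
* ``ssri_experiment`` — a fluoxetine-like dose with raphe firing suppression,
  wild type vs terminal-autoreceptor (5-HT1B) knockout;
* ``agonist_experiment`` — a 5-HT1A agonist modeled purely as transient
  firing suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationTargets, calibrate
from .drivers import (
    PULSE_DURATION_HR,
    Drivers,
    make_fluox_dose,
    make_meal_profile,
    make_square_pulse,
    make_suppressed_fire,
    occupancy_profile,
)
from .model import AutoreceptorConfig, KineticParameters, TerminalState
from .solvers import Trajectory, find_steady_state, half_life, integrate

__all__ = [
    "ExperimentResult",
    "table4_sweep",
    "pulse_release",
    "meals_experiment",
    "homeostasis_sweep",
    "ssri_experiment",
    "agonist_experiment",
    "REGION_F_MIN",
]

#: peak firing suppression by raphe 5-HT1A stimulation, per projection
#: region: the median raphe (→ hippocampus) drops to 58% of tonic firing,
#: the dorsal raphe (→ frontal cortex) to 20%
REGION_F_MIN = {"hippocampus": 0.58, "frontal_cortex": 0.20}

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class ExperimentResult:
    """Named output bundle of one protocol run."""

    name: str
    config: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    trajectories: dict[str, Trajectory] = field(default_factory=dict)
    summary: dict[str, float] = field(default_factory=dict)


def _baseline(p: KineticParameters | None,
              state0: TerminalState | None,
              ) -> tuple[KineticParameters, TerminalState]:
    if p is None or state0 is None:
        p_cal, s_cal = calibrate(p=p)
        return p_cal, (state0 or s_cal)
    return p, state0


# ---------------------------------------------------------------------------
# C. SERT-fraction sweep (wild type -> knockout)
# ---------------------------------------------------------------------------

def table4_sweep(p: KineticParameters | None = None,
                 cfg: AutoreceptorConfig = AutoreceptorConfig(),
                 fractions=(1.0, 0.5, 0.2, 0.1, 0.05, 0.0),
                 state0: TerminalState | None = None) -> ExperimentResult:
    """Steady states for each unblocked SERT fraction.

    The grid of fractions runs from wild type (f = 1) to full knockout
    (f = 0); each solve is seeded from the previous fraction's solution so
    the continuation never loses the stable branch.  Extracellular 5-HT is
    reported in nM, everything else in μM and μM/hr.
    """
    p, seed = _baseline(p, state0)
    rows = []
    for f in fractions:
        rep = find_steady_state(p, cfg, fluox=f, x0=seed)
        seed = rep.state
        st, vel = rep.state, rep.velocities
        rows.append({
            "f": f,
            "trp_uM": st.trp,
            "c5ht_uM": st.c5ht,
            "v5ht_uM": st.v5ht,
            "e5ht_nM": st.e5ht_nM,
            "hiaa5_uM": st.hiaa5,
            "v_tph_uM_hr": vel["v_tph"],
            "v_mat_uM_hr": vel["v_mat_net"],
            "v_sert_uM_hr": vel["v_sert"],
            "v_rem_uM_hr": vel["v_rem"],
            "v_catab_uM_hr": vel["v_catab_c"] + vel["v_catab_e"],
        })
    table = pd.DataFrame(rows)
    return ExperimentResult(
        name="table4_sweep",
        config={"fractions": list(fractions),
                "autoreceptors": [cfg.synthesis_feedback, cfg.release_feedback]},
        tables={"table4": table},
        summary={
            "e5ht_fold_increase_ko": float(
                table["e5ht_nM"].iloc[-1] / table["e5ht_nM"].iloc[0]),
        })


# ---------------------------------------------------------------------------
# B. stimulation pulse
# ---------------------------------------------------------------------------

def pulse_release(p: KineticParameters | None = None,
                  cfg: AutoreceptorConfig = AutoreceptorConfig(),
                  blocked_fraction: float = 0.0,
                  pulse_rate: float = 5000.0,
                  duration_hr: float = PULSE_DURATION_HR,
                  state0: TerminalState | None = None) -> ExperimentResult:
    """0.2-s firing pulse (1 -> 5000/hr) with optional acute SERT blockade.

    The system is pre-equilibrated at the wild-type baseline; the blockade
    is applied *acutely* at the start of the run (a bath application of
    fluoxetine on the seconds time scale does not re-equilibrate the
    vesicular store), the pulse fires 2 s later, and the trajectory is
    followed for a further 12 s.  The peak and the decay half-life of
    extracellular 5-HT are measured on the dense solver output, with the
    half-life defined on the elevation above the pre-pulse baseline.
    """
    if not 0.0 <= blocked_fraction <= 1.0:
        raise ValueError(f"blocked_fraction must lie in [0, 1], "
                         f"got {blocked_fraction}")
    p, s0 = _baseline(p, state0)
    f = 1.0 - blocked_fraction
    t_on = 2.0 / SECONDS_PER_HOUR
    t_end = t_on + duration_hr + 12.0 / SECONDS_PER_HOUR
    fire, bps = make_square_pulse(t_on=t_on, pulse=pulse_rate,
                                  duration=duration_hr)
    drv = Drivers(fire=fire, fluox=lambda t: f, btrp=lambda t: 96.0,
                  breakpoints=bps)
    traj = integrate(p, cfg, drv, s0, (0.0, t_end))
    baseline = traj.value_at(t_on, "e5ht")
    summary: dict[str, float] = {
        "baseline_e5ht_uM": baseline,
        "v5ht_depleted_fraction": float(
            1.0 - np.min(traj.states[:, 5]) / s0.v5ht),
    }
    if pulse_rate > drv.fire(0.0):
        hl = half_life(traj, "e5ht", baseline=baseline)
        summary.update({
            "peak_e5ht_uM": hl["peak"],
            "half_life_s": hl["half_life_hr"] * SECONDS_PER_HOUR,
            "t_peak_s": (hl["t_peak"] - t_on) * SECONDS_PER_HOUR,
        })
    return ExperimentResult(
        name="pulse_release",
        config={"blocked_fraction": blocked_fraction,
                "pulse_rate_per_hr": pulse_rate,
                "duration_s": duration_hr * SECONDS_PER_HOUR},
        trajectories={"pulse": traj},
        summary=summary)


# ---------------------------------------------------------------------------
# A. meals
# ---------------------------------------------------------------------------

def meals_experiment(p: KineticParameters | None = None,
                     cfg: AutoreceptorConfig = AutoreceptorConfig(),
                     peak_factor: float = 2.0,
                     meal_starts=(7.0, 12.0, 18.0),
                     state0: TerminalState | None = None) -> ExperimentResult:
    """One day of meal-driven serum tryptophan (fire = 1, no SSRI).

    The serum profile repeats with a 24 h period; the model is warmed up for
    one full day so the reported day is periodic, and every curve is
    expressed as percent of its own pre-meal (t = 0) baseline.
    """
    p, s0 = _baseline(p, state0)
    btrp, knots = make_meal_profile(peak_factor=peak_factor,
                                    meal_starts=meal_starts, n_days=2)
    drv = Drivers(fire=lambda t: 1.0, fluox=lambda t: 1.0, btrp=btrp,
                  breakpoints=knots)
    traj = integrate(p, cfg, drv, s0, (0.0, 48.0), rtol=1e-8, atol=1e-10)

    times = np.linspace(24.0, 48.0, 481)
    recs = []
    from .model import v_tph  # local to keep module surface tidy
    for t in times:
        y = traj.state_at(t)
        st = TerminalState.from_array(np.maximum(y, 0.0))
        recs.append({
            "time_hr": t - 24.0,
            "btrp_uM": drv.btrp(t),
            "trp_uM": st.trp,
            "v_tph_uM_hr": v_tph(st.trp, st.bh4, st.e5ht, p, cfg),
            "e5ht_nM": st.e5ht_nM,
            "v5ht_uM": st.v5ht,
        })
    day = pd.DataFrame(recs)
    pct = day.copy()
    for col in day.columns[1:]:
        pct[col] = 100.0 * day[col] / day[col].iloc[0]
    swings = {f"swing_pct_{c}": float(pct[c].max() - pct[c].min())
              for c in day.columns[1:]}
    return ExperimentResult(
        name="meals",
        config={"peak_factor": peak_factor, "meal_starts": list(meal_starts)},
        tables={"day_absolute": day, "day_percent": pct},
        trajectories={"meals": traj},
        summary=swings)


# ---------------------------------------------------------------------------
# D. autoreceptor homeostasis
# ---------------------------------------------------------------------------

#: activity annotations: SERT promoter genotypes and TPH2 coding variants
#: (activity relative to the common heterozygote / wild type)
POLYMORPHISM_ACTIVITY = {
    "sert_s/s": 0.5, "sert_l/l": 1.5,
    "tph_R441H": 0.19, "tph_P449R": 0.65,
}


def homeostasis_sweep(p: KineticParameters | None = None,
                      vary: str = "fire",
                      grid=None,
                      state0: TerminalState | None = None) -> ExperimentResult:
    """Steady extracellular 5-HT vs a scaled input, autoreceptors on vs off.

    ``vary`` is one of ``fire`` (tonic firing rate), ``sert_vmax`` (SERT
    expression) or ``tph_vmax`` (TPH activity); the grid scales the baseline
    value.  The summary reports the e5ht range of each curve and the damping
    factor (off-range / on-range), which exceeds 1 whenever the
    autoreceptors buffer the perturbation.
    """
    if vary not in ("fire", "sert_vmax", "tph_vmax"):
        raise ValueError(f"cannot vary {vary!r}")
    if grid is None:
        grid = np.linspace(0.5, 1.5, 11) if vary != "tph_vmax" \
            else np.linspace(0.19, 1.0, 10)
    p, s0 = _baseline(p, state0)
    base_e = find_steady_state(p, AutoreceptorConfig(), x0=s0).state.e5ht

    rows = []
    for on in (True, False):
        cfg = AutoreceptorConfig(synthesis_feedback=on, release_feedback=on)
        seed = s0
        for scale in grid:
            if vary == "fire":
                rep = find_steady_state(p, cfg, fire=scale, x0=seed)
            else:
                p_mod = p.replace(**{vary: scale * getattr(p, vary)})
                rep = find_steady_state(p_mod, cfg, x0=seed)
            seed = rep.state
            rows.append({"scale": float(scale), "autoreceptors": on,
                         "e5ht_nM": rep.state.e5ht_nM,
                         "e5ht_pct_baseline": 100.0 * rep.state.e5ht / base_e})
    table = pd.DataFrame(rows)
    on_curve = table[table.autoreceptors]["e5ht_nM"]
    off_curve = table[~table.autoreceptors]["e5ht_nM"]
    rng_on = float(on_curve.max() - on_curve.min())
    rng_off = float(off_curve.max() - off_curve.min())
    return ExperimentResult(
        name=f"homeostasis_{vary}",
        config={"vary": vary, "grid": [float(g) for g in grid],
                "annotations": POLYMORPHISM_ACTIVITY},
        tables={"sweep": table},
        summary={"range_on_nM": rng_on, "range_off_nM": rng_off,
                 "damping_factor": rng_off / rng_on})


# ---------------------------------------------------------------------------
# E. SSRI dose and 5-HT1A agonist
# ---------------------------------------------------------------------------

def ssri_experiment(p: KineticParameters | None = None,
                    region: str = "hippocampus",
                    autoreceptor_1b_knockout: bool = False,
                    dose_time: float = 1.0,
                    t_end: float = 400.0,
                    fire_washout_hr: float = 10.0,
                    state0: TerminalState | None = None) -> ExperimentResult:
    """Time course of extracellular 5-HT after a fluoxetine-like dose.

    The dose blocks terminal SERTs (washout constant 37 hr) and, by raising
    raphe extracellular 5-HT and stimulating somatodendritic 5-HT1A
    receptors, suppresses tonic firing.  The suppression follows an
    occupancy-shaped curve bottoming out at the region-specific minimum
    (58% of tonic for the hippocampus/MRN, 20% for the frontal cortex/DRN)
    and recovering with its own washout constant, default 10 hr — faster
    than the drug, reflecting desensitization of the somatic 5-HT1A
    response under sustained exposure.  (If firing recovered only on the
    drug's 37-hr timescale, the frontal-cortex extracellular 5-HT could
    never rise above baseline: at 20% firing no depth of SERT blockade
    pushes the steady state past ~90% of baseline.)  A terminal 5-HT1B
    knockout pins both terminal autoreceptor factors at 1; the firing
    suppression (a somatic 5-HT1A effect) is retained.
    """
    f_min = REGION_F_MIN[region]
    cfg = (AutoreceptorConfig.knockout_1b() if autoreceptor_1b_knockout
           else AutoreceptorConfig())
    p, s0 = _baseline(p, state0)
    # percent changes are against the equilibrated pre-dose baseline of the
    # same autoreceptor configuration (identical to the default baseline,
    # since both factors are 1 there)
    base = find_steady_state(p, cfg, x0=s0).state.e5ht

    fluox, bps = make_fluox_dose(dose_time=dose_time)
    suppression = lambda t: occupancy_profile(  # noqa: E731
        t, dose_time=dose_time, washout_hr=fire_washout_hr)
    fire = make_suppressed_fire(f_min, suppression, t_max_search=t_end)
    drv = Drivers(fire=fire, fluox=fluox, btrp=lambda t: 96.0,
                  breakpoints=bps)
    traj = integrate(p, cfg, drv, s0, (0.0, t_end), rtol=1e-8, atol=1e-10)

    times = np.linspace(0.0, t_end, 1601)
    e = np.array([traj.state_at(t)[6] for t in times])
    pct = 100.0 * e / base
    table = pd.DataFrame({"time_hr": times, "e5ht_pct_baseline": pct})
    k = int(np.argmax(pct))
    return ExperimentResult(
        name="ssri",
        config={"region": region, "f_min_fire": f_min,
                "autoreceptor_1b_knockout": autoreceptor_1b_knockout,
                "dose_time_hr": dose_time,
                "fire_washout_hr": fire_washout_hr,
                "note": ("peak percent depends on the assumed coupling of "
                         "firing suppression to the blockade profile; "
                         "orderings between regions/genotypes are robust")},
        tables={"e5ht_percent": table},
        trajectories={"ssri": traj},
        summary={"peak_rise_pct": float(pct[k] - 100.0),
                 "t_peak_hr": float(times[k]),
                 "final_pct": float(pct[-1])})


def agonist_experiment(p: KineticParameters | None = None,
                       region: str = "frontal_cortex",
                       washout_hr: float = 2.0,
                       dose_time: float = 1.0,
                       t_end: float = 24.0,
                       state0: TerminalState | None = None
                       ) -> ExperimentResult:
    """Transient firing suppression by a 5-HT1A autoreceptor agonist.

    No SERT blockade; firing is suppressed in proportion to an occupancy
    curve with a fast washout (default 2 hr) and recovers as the drug
    clears.  Extracellular 5-HT falls toward the steady-state mapping of the
    firing reduction (≈30% of baseline for the frontal cortex, ≈70% for the
    hippocampus) and then recovers, helped by the terminal autoreceptors.
    """
    f_min = REGION_F_MIN[region]
    p, s0 = _baseline(p, state0)
    cfg = AutoreceptorConfig()
    base = s0.e5ht

    occ = lambda t: occupancy_profile(t, dose_time=dose_time,  # noqa: E731
                                      washout_hr=washout_hr)
    fire = make_suppressed_fire(f_min, occ, t_max_search=t_end)
    drv = Drivers(fire=fire, fluox=lambda t: 1.0, btrp=lambda t: 96.0,
                  breakpoints=(dose_time,))
    traj = integrate(p, cfg, drv, s0, (0.0, t_end), rtol=1e-8, atol=1e-10)

    times = np.linspace(0.0, t_end, 1201)
    e = np.array([traj.state_at(t)[6] for t in times])
    pct = 100.0 * e / base
    table = pd.DataFrame({"time_hr": times, "e5ht_pct_baseline": pct})
    k = int(np.argmin(pct))
    return ExperimentResult(
        name="agonist",
        config={"region": region, "f_min_fire": f_min,
                "washout_hr": washout_hr, "dose_time_hr": dose_time},
        tables={"e5ht_percent": table},
        trajectories={"agonist": traj},
        summary={"trough_pct": float(pct[k]),
                 "t_trough_hr": float(times[k]),
                 "final_pct": float(pct[-1])})
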