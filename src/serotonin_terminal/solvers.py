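"""Steady-state solving, stiff integration with discontinuous drivers, and
trajectory metrics.

The system is stiff (clearance of extracellular serotonin runs on a
time scale of seconds while the tryptophan pool turns over in hours), so
time integration uses an implicit/stiff-capable method and is restarted at
every declared driver breakpoint — pulse edges, dose times, meal knots —
rather than trusting step-size heuristics to find sub-second events.

Because bh2 + bh4 is conserved, the full nine-dimensional right-hand side
has a singular Jacobian everywhere.  The steady-state root finder therefore
solves the reduced eight-dimensional system with the biopterin total pinned
to its value at the seed, which is also what the dynamics themselves do.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .drivers import Drivers
from .model import (
    STATE_FIELDS,
    AutoreceptorConfig,
    KineticParameters,
    TerminalState,
    rhs_array,
    velocities,
)

__all__ = [
    "SteadyStateReport",
    "Trajectory",
    "find_steady_state",
    "steady_state_by_integration",
    "steady_state_report",
    "integrate",
    "half_life",
    "finite_difference_jacobian",
]

#: convergence tolerance on the ∞-norm of the full rhs (μM/hr); far below
#: the smallest flux of interest (extracellular catabolism ≈ 0.008 μM/hr)
STEADY_TOL = 1e-8


@dataclass(frozen=True)
class SteadyStateReport:
    """A converged steady state with its velocities and diagnostics."""

    state: TerminalState
    velocities: dict[str, float]
    residual_norm: float
    converged: bool
    drivers: dict[str, float]
    balance_residuals: dict[str, float] = field(default_factory=dict)
    targets_delta: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-ready representation (concentrations μM, fluxes μM/hr)."""
        return {
            "state_uM": {k: getattr(self.state, k) for k in STATE_FIELDS},
            "e5ht_nM": self.state.e5ht_nM,
            "velocities_uM_hr": dict(self.velocities),
            "residual_norm_uM_hr": self.residual_norm,
            "converged": self.converged,
            "drivers": dict(self.drivers),
            "balance_residuals_uM_hr": dict(self.balance_residuals),
            "targets_relative_error": dict(self.targets_delta),
        }


def steady_state_report(p: KineticParameters, steady: TerminalState,
                        cfg: AutoreceptorConfig = AutoreceptorConfig(),
                        fire: float = 1.0, fluox: float = 1.0,
                        btrp: float = 96.0, targets=None) -> SteadyStateReport:
    """Assemble the report for a candidate steady state (reporting only; no
    solving).  ``targets`` may be a CalibrationTargets to get relative
    errors against the reference baseline."""
    drv = Drivers.constant(fire=fire, fluox=fluox, btrp=btrp)
    resid = rhs_array(0.0, steady.to_array(), p, drv, cfg)
    vel = velocities(steady, p, cfg, fire=fire, fluox=fluox, btrp=btrp)
    balance = {
        "synthesis_vs_decarboxylation": vel["v_tph"] - vel["v_aadc"],
        "mat_vs_release": vel["v_mat_net"] - vel["v_release"],
        "release_vs_clearance": vel["v_release"] - (
            vel["v_sert"] + vel["v_catab_e"] + vel["v_rem"]),
        "synthesis_vs_serotonin_clearance": vel["v_tph"] - (
            vel["v_catab_c"] + vel["v_catab_e"] + vel["v_rem"]),
        "uptake_vs_pool_and_synthesis": vel["v_trpin"] - (
            vel["v_pool_catab"] + vel["v_tph"]),
    }
    delta: dict[str, float] = {}
    if targets is not None:
        pairs = {
            "trp": targets.trp_star, "htp5": targets.htp5_star,
            "c5ht": targets.c5ht_star, "v5ht": targets.v5ht_star,
            "e5ht": targets.e5ht_star, "hiaa5": targets.hiaa_star,
        }
        delta = {k: getattr(steady, k) / v - 1.0 for k, v in pairs.items()}
        delta["synthesis_flux"] = vel["v_tph"] / targets.synthesis_flux - 1.0
    norm = float(np.max(np.abs(resid)))
    return SteadyStateReport(
        state=steady, velocities=vel, residual_norm=norm,
        converged=norm < STEADY_TOL,
        drivers={"fire": fire, "fluox": fluox, "btrp": btrp},
        balance_residuals=balance, targets_delta=delta)


def _reduced_residual(y8: np.ndarray, b_total: float, p: KineticParameters,
                      drv: Drivers, cfg: AutoreceptorConfig) -> np.ndarray:
    """rhs of the eight non-bh2 equations with bh2 = b_total - bh4."""
    y = np.empty(9)
    y[0] = b_total - y8[0]
    y[1:] = y8
    return rhs_array(0.0, y, p, drv, cfg)[1:]


def find_steady_state(p: KineticParameters,
                      cfg: AutoreceptorConfig = AutoreceptorConfig(),
                      fire: float = 1.0, fluox: float = 1.0,
                      btrp: float = 96.0,
                      x0: TerminalState | None = None,
                      tol: float = STEADY_TOL,
                      targets=None) -> SteadyStateReport:
    """Solve for the fixed point under constant drivers.

    A damped multivariate root find on the reduced system (biopterin total
    pinned to the seed's) is attempted from ``x0`` (default: the calibrated
    baseline); if it fails or lands on a negative component, the solver
    re-seeds from a long integration of the dynamics, which is
    unconditionally reliable here because the baseline fixed point is
    stable.
    """
    if x0 is None:
        from .calibration import calibrate  # lazy; avoids import cycle
        _, x0 = calibrate(p=p)
    drv = Drivers.constant(fire=fire, fluox=fluox, btrp=btrp)
    b_total = x0.biopterin_total
    seed = x0.to_array()[1:]

    def attempt(seed8: np.ndarray):
        sol = root(_reduced_residual, seed8,
                   args=(b_total, p, drv, cfg), method="hybr",
                   options={"xtol": 1e-13})
        y = np.empty(9)
        y[0] = b_total - sol.x[0]
        y[1:] = sol.x
        resid = np.max(np.abs(rhs_array(0.0, y, p, drv, cfg)))
        ok = resid < tol and np.all(y >= -1e-9)
        return ok, np.maximum(y, 0.0), resid

    ok, y, resid = attempt(seed)
    if not ok:
        long_run = steady_state_by_integration(
            p, cfg, fire=fire, fluox=fluox, btrp=btrp, x0=x0)
        ok, y, resid = attempt(long_run.to_array()[1:])
        if not ok:
            raise RuntimeError(
                f"steady-state solve did not converge (residual {resid:.3g} "
                f"μM/hr at fire={fire}, fluox={fluox}, btrp={btrp})")
    return steady_state_report(p, TerminalState.from_array(y), cfg=cfg,
                               fire=fire, fluox=fluox, btrp=btrp,
                               targets=targets)


def steady_state_by_integration(p: KineticParameters,
                                cfg: AutoreceptorConfig = AutoreceptorConfig(),
                                fire: float = 1.0, fluox: float = 1.0,
                                btrp: float = 96.0,
                                x0: TerminalState | None = None,
                                t_final: float = 1e4) -> TerminalState:
    """Equilibrate by integrating the dynamics to ``t_final`` hours.

    The independent cross-check for the root-found fixed point (the two
    must agree to 0.1% per variable), and the fallback seed generator for
    hard parameter corners.
    """
    if x0 is None:
        from .calibration import calibrate
        _, x0 = calibrate(p=p)
    drv = Drivers.constant(fire=fire, fluox=fluox, btrp=btrp)
    sol = solve_ivp(rhs_array, (0.0, t_final), x0.to_array(),
                    args=(p, drv, cfg), method="LSODA",
                    rtol=1e-10, atol=1e-14, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"equilibration integration failed: {sol.message}")
    return TerminalState.from_array(np.maximum(sol.y[:, -1], 0.0))


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """Time-stamped solution with dense interpolants per smooth segment."""

    times: np.ndarray                 # hours, strictly increasing
    states: np.ndarray                # (n_times, 9) in STATE_FIELDS order
    segments: tuple                   # (t0, t1, OdeSolution) per segment

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite states")

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def state_at(self, t: float) -> np.ndarray:
        """Dense evaluation at an arbitrary time inside the span."""
        t0, t1 = self.t_span
        if not t0 <= t <= t1:
            raise ValueError(f"t = {t} outside trajectory span [{t0}, {t1}]")
        starts = [seg[0] for seg in self.segments]
        i = max(bisect.bisect_right(starts, t) - 1, 0)
        return np.asarray(self.segments[i][2](t), dtype=float)

    def value_at(self, t: float, variable: str) -> float:
        return float(self.state_at(t)[STATE_FIELDS.index(variable)])

    def final_state(self) -> TerminalState:
        return TerminalState.from_array(np.maximum(self.states[-1], 0.0))

    def biopterin_drift(self) -> float:
        """Max |bh2+bh4 − initial total| along the stored points (μM)."""
        total = self.states[:, 0] + self.states[:, 1]
        return float(np.max(np.abs(total - total[0])))

    def to_dataframe(self, p: KineticParameters | None = None,
                     cfg: AutoreceptorConfig = AutoreceptorConfig(),
                     drivers: Drivers | None = None) -> pd.DataFrame:
        """Tabulate the trajectory; with ``p`` (and optionally ``drivers``)
        the per-time velocities are appended."""
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time_hr", self.times)
        if p is not None:
            flux_rows = []
            for t, row in zip(self.times, self.states):
                st = TerminalState.from_array(np.maximum(row, 0.0))
                kw = {}
                if drivers is not None:
                    kw = {"fire": drivers.fire(t), "fluox": drivers.fluox(t),
                          "btrp": drivers.btrp(t)}
                flux_rows.append(velocities(st, p, cfg, **kw))
            df = pd.concat([df, pd.DataFrame(flux_rows)], axis=1)
        return df


def integrate(p: KineticParameters, cfg: AutoreceptorConfig,
              drivers: Drivers, state0: TerminalState,
              t_span: tuple[float, float], rtol: float = 1e-8,
              atol: float = 1e-12, method: str = "LSODA") -> Trajectory:
    """Stiff integration over ``t_span`` with restarts at driver breakpoints.

    Segments shorter than 36 s (e.g. a stimulation pulse) additionally get a
    capped step size so that the event is resolved by at least ~60 accepted
    steps, making sub-second metrics independent of step-size heuristics.
    """
    t0, t1 = t_span
    if not t1 > t0:
        raise ValueError(f"empty time span {t_span}")
    cuts = sorted({t0, t1} | {b for b in drivers.breakpoints if t0 < b < t1})

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    segments = []
    y = state0.to_array()
    for a, b in zip(cuts[:-1], cuts[1:]):
        seg_len = b - a
        max_step = seg_len / 60.0 if seg_len < 0.01 else np.inf
        sol = solve_ivp(rhs_array, (a, b), y, args=(p, drivers, cfg),
                        method=method, rtol=rtol, atol=atol,
                        dense_output=True, max_step=max_step)
        if not sol.success:
            raise RuntimeError(
                f"integration failed in [{a}, {b}] hr: {sol.message}")
        keep = slice(0 if not times else 1, None)  # drop duplicated knot
        times.append(sol.t[keep])
        states.append(sol.y[:, keep].T)
        segments.append((a, b, sol.sol))
        y = sol.y[:, -1]
    return Trajectory(times=np.concatenate(times),
                      states=np.vstack(states),
                      segments=tuple(segments))


def half_life(traj: Trajectory, variable: str = "e5ht",
              baseline: float | None = None,
              n_grid: int = 4001) -> dict[str, float]:
    """Peak and decay half-life of one variable's excursion above baseline.

    The half-life is defined on the *elevation above baseline*, not the
    absolute concentration, because saturated clearance makes the decay
    near-linear rather than exponential.  Returns times in hours:
    ``t_peak``, ``peak`` (μM), ``t_half`` and ``half_life_hr``
    (= t_half − t_peak), all measured on the dense solution.
    """
    idx = STATE_FIELDS.index(variable)
    t0, t1 = traj.t_span
    if baseline is None:
        baseline = float(traj.states[0, idx])

    grid = np.linspace(t0, t1, n_grid)
    vals = np.array([traj.state_at(t)[idx] for t in grid])
    k = int(np.argmax(vals))
    peak_elev = vals[k] - baseline
    if peak_elev <= max(1e-12, 1e-6 * abs(baseline)):
        raise ValueError(f"{variable} never rises above baseline {baseline}")

    # refine the peak locally on the dense solution
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    fine = np.linspace(lo, hi, 200)
    fvals = np.array([traj.state_at(t)[idx] for t in fine])
    j = int(np.argmax(fvals))
    t_peak, peak = float(fine[j]), float(fvals[j])
    half_level = baseline + 0.5 * (peak - baseline)

    def gap(t: float) -> float:
        return traj.state_at(t)[idx] - half_level

    # first grid point after the peak below the half level brackets the root
    after = grid[grid > t_peak]
    below = after[[gap(t) < 0 for t in after]]
    if below.size == 0:
        raise ValueError(
            f"{variable} never decays to half its peak elevation")
    b = float(below[0])
    a = max(t_peak, b - (grid[1] - grid[0]))
    t_half = float(brentq(gap, a, b, xtol=1e-12))
    return {"t_peak": t_peak, "peak": peak, "t_half": t_half,
            "half_life_hr": t_half - t_peak}


def finite_difference_jacobian(p: KineticParameters, cfg: AutoreceptorConfig,
                               drivers: Drivers, state: TerminalState,
                               eps: float = 1e-7) -> np.ndarray:
    """Central-difference Jacobian of the rhs at ``state`` (9 × 9).

    Used to check local stability of fixed points: all eigenvalues except
    the structurally zero one (biopterin conservation) should have negative
    real part.
    """
    y0 = state.to_array()
    n = y0.size
    jac = np.empty((n, n))
    for j in range(n):
        h = eps * max(abs(y0[j]), 1e-6)
        up, dn = y0.copy(), y0.copy()
        up[j] += h
        dn[j] = max(dn[j] - h, 0.0)
        jac[:, j] = (rhs_array(0.0, up, p, drivers, cfg)
                     - rhs_array(0.0, dn, p, drivers, cfg)) / (up[j] - dn[j])
    return jac
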