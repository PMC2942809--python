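"""Core kinetics of the serotonergic terminal: state, parameters, rate laws,
and the right-hand side of the nine-variable ODE system.

The model tracks, in a single well-mixed terminal, the biopterin cofactor
cycle (bh2/bh4), cellular tryptophan and its exchange with a large
intracellular pool, 5-HTP, cytosolic / vesicular / extracellular serotonin,
and 5-HIAA.  All concentrations are in μM and all rates in μM/hr; time is in
hours.  Extracellular serotonin is stored internally in μM (the baseline is
0.000768 μM = 0.768 nM) and converted to nM only in reports.

Serotonin synthesis (tryptophan hydroxylase, TPH) shows weak substrate
inhibition in tryptophan and is modulated by terminal 5-HT1B autoreceptors:
a synthesis factor that falls smoothly from 1.5 toward 0.5 as extracellular
5-HT rises, and a release factor that falls piecewise-linearly from 1.5 to
0.4.  Both factors equal exactly 1 at the normal extracellular steady state,
so switching the autoreceptors off leaves the baseline steady state
unchanged — which is what makes on/off homeostasis comparisons meaningful.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .drivers import Drivers

__all__ = [
    "STATE_FIELDS",
    "TerminalState",
    "KineticParameters",
    "AutoreceptorConfig",
    "synthesis_factor",
    "release_factor",
    "v_tph",
    "v_aadc",
    "v_drr",
    "v_trpin",
    "v_mat_net",
    "v_sert",
    "clearances",
    "velocities",
    "rhs",
    "rhs_array",
]

#: state-vector ordering used everywhere (solvers, trajectories, CSV columns)
STATE_FIELDS = ("bh2", "bh4", "trp", "htp5", "c5ht", "v5ht", "e5ht",
                "hiaa5", "trp_pool")

# solver round-off may leave components a hair below zero; anything more
# negative than this is a genuine modeling/integration error
_NEG_TOL = 1e-9


@dataclass(frozen=True)
class TerminalState:
    """The nine model concentrations (μM) at one instant.

    ``htp5`` is 5-HTP, ``c5ht``/``v5ht``/``e5ht`` are cytosolic, vesicular,
    and extracellular serotonin, ``hiaa5`` is 5-HIAA, and ``trp_pool`` is
    the aggregate of all non-serotonin intracellular tryptophan sinks and
    sources.
    """

    bh2: float
    bh4: float
    trp: float
    htp5: float
    c5ht: float
    v5ht: float
    e5ht: float
    hiaa5: float
    trp_pool: float

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} is not finite: {value}")
            if value < -_NEG_TOL:
                raise ValueError(f"{name} must be >= 0, got {value}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_FIELDS])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "TerminalState":
        return cls(**dict(zip(STATE_FIELDS, map(float, y))))

    @property
    def biopterin_total(self) -> float:
        """bh2 + bh4, conserved by the dynamics."""
        return self.bh2 + self.bh4

    @property
    def e5ht_nM(self) -> float:
        """Extracellular 5-HT in nM (presentation units)."""
        return self.e5ht * 1e3


@dataclass(frozen=True)
class KineticParameters:
    """Every rate constant, Km/Vmax, autoreceptor constant, and fixed
    cofactor level of the model.  Units: μM for concentrations and Km,
    μM/hr for Vmax, /hr for first-order rate constants.

    The defaults are the resolved baseline set: literature-anchored Km
    values; Vmax values from the source physiology, with the SERT and
    tryptophan-transport entries resolved in favor of the values that
    reproduce the printed baseline fluxes (SERT Vmax 4700 μM/hr, transporter
    Km 330 / Vmax 700); and the three constants that are pinned by
    calibration rather than measurement (``mat_k_out``, ``pool_k1``,
    ``pool_k_catab``) at their calibrated values — see the calibration
    module for the flux-balance derivation.
    """

    # aromatic amino acid decarboxylase (5-HTP -> cytosolic 5-HT)
    aadc_km: float = 160.0
    aadc_vmax: float = 400.0
    # serotonin reuptake transporter
    sert_km: float = 0.17
    sert_vmax: float = 4700.0
    # dihydropteridine reductase (bh2 -> bh4, NADPH-driven, reversible)
    drr_k_bh2: float = 100.0
    drr_k_nadph: float = 75.0
    drr_vmax_f: float = 5000.0
    drr_k_bh4: float = 10.0
    drr_k_nadp: float = 75.0
    drr_vmax_b: float = 3.0
    nadph: float = 300.0
    nadp: float = 300.0
    # vesicular monoamine transporter, with linear leak back to the cytosol
    mat_km: float = 0.198
    mat_vmax: float = 3500.0
    mat_k_out: float = 115.99052542012257  # calibrated; see calibration module
    # tryptophan hydroxylase (weak substrate inhibition in trp)
    tph_k_trp: float = 40.0
    tph_k_bh4: float = 20.0
    tph_vmax: float = 400.0
    tph_ki: float = 1000.0
    # neutral amino acid transporter (serum trp -> cellular trp)
    trpin_km: float = 330.0
    trpin_vmax: float = 700.0
    # trp <-> trp-pool exchange and pool catabolism
    pool_k1: float = 13.387207712293176  # calibrated
    pool_k_minus1: float = 0.6
    pool_k_catab: float = 0.7387207712293177  # calibrated
    # catabolism (MAO + ALDH combined), 5-HIAA clearance, and removal
    catab_c_vmax: float = 1000.0
    catab_c_km: float = 95.0
    catab_e_vmax: float = 1000.0
    catab_e_km: float = 95.0
    hiaa_k_catab: float = 1.0
    k_rem: float = 400.0
    # autoreceptor constants
    auto_e5ht_star: float = 0.000768
    auto_release_break: float = 0.0023
    auto_synth_hi: float = 1.5
    auto_synth_lo: float = 0.5
    auto_release_hi: float = 1.5
    auto_release_lo: float = 0.4

    def __post_init__(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if not math.isfinite(value):
                raise ValueError(f"{name} is not finite: {value}")
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not self.auto_release_break > self.auto_e5ht_star:
            raise ValueError(
                "auto_release_break must exceed auto_e5ht_star "
                f"({self.auto_release_break} <= {self.auto_e5ht_star})")

    @classmethod
    def baseline(cls) -> "KineticParameters":
        """The resolved, calibrated default parameter set."""
        return cls()

    def replace(self, **changes) -> "KineticParameters":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class AutoreceptorConfig:
    """On/off switches for the two terminal 5-HT1B autoreceptor effects.

    When a flag is off the corresponding factor is pinned to exactly 1 for
    every extracellular 5-HT level.  A terminal 1B knockout turns both off.
    """

    synthesis_feedback: bool = True
    release_feedback: bool = True

    @classmethod
    def knockout_1b(cls) -> "AutoreceptorConfig":
        return cls(synthesis_feedback=False, release_feedback=False)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def _check_nonneg(name: str, value: float) -> float:
    if value < -_NEG_TOL:
        raise ValueError(f"{name} must be >= 0, got {value}")
    # clip solver round-off for rate evaluation only
    return value if value > 0.0 else 0.0


def synthesis_factor(e5ht: float, p: KineticParameters,
                     cfg: AutoreceptorConfig = AutoreceptorConfig()) -> float:
    """Autoreceptor modulation of synthesis: 1.5 at e5ht = 0, exactly 1 at
    the normal steady state (0.768 nM), approaching 0.5 as e5ht rises."""
    e = _check_nonneg("e5ht", e5ht)
    if not cfg.synthesis_feedback:
        return 1.0
    k2 = p.auto_e5ht_star * p.auto_e5ht_star
    return p.auto_synth_hi - e * e / (k2 + e * e)


def release_factor(e5ht: float, p: KineticParameters,
                   cfg: AutoreceptorConfig = AutoreceptorConfig()) -> float:
    """Autoreceptor modulation of vesicular release: piecewise linear from
    1.5 at e5ht = 0 through 1.0 at the normal steady state down to 0.4 at
    the upper breakpoint, constant beyond."""
    e = _check_nonneg("e5ht", e5ht)
    if not cfg.release_feedback:
        return 1.0
    if e <= p.auto_e5ht_star:
        return (p.auto_release_hi
                + (1.0 - p.auto_release_hi) * e / p.auto_e5ht_star)
    if e <= p.auto_release_break:
        frac = (e - p.auto_e5ht_star) / (p.auto_release_break - p.auto_e5ht_star)
        return 1.0 + (p.auto_release_lo - 1.0) * frac
    return p.auto_release_lo


def v_tph(trp: float, bh4: float, e5ht: float, p: KineticParameters,
          cfg: AutoreceptorConfig = AutoreceptorConfig()) -> float:
    """Tryptophan hydroxylase rate (μM/hr) with substrate inhibition in trp
    and the autoreceptor synthesis factor."""
    trp = _check_nonneg("trp", trp)
    bh4 = _check_nonneg("bh4", bh4)
    denom = (p.tph_k_trp + trp + trp * trp / p.tph_ki) * (p.tph_k_bh4 + bh4)
    return (p.tph_vmax * trp * bh4 / denom) * synthesis_factor(e5ht, p, cfg)


def v_aadc(htp5: float, p: KineticParameters) -> float:
    """Aromatic amino acid decarboxylase rate (μM/hr)."""
    htp5 = _check_nonneg("htp5", htp5)
    return p.aadc_vmax * htp5 / (p.aadc_km + htp5)


def v_drr(bh2: float, bh4: float, p: KineticParameters) -> float:
    """Net dihydropteridine reductase rate (μM/hr), bh2 -> bh4 positive.

    Bidirectional two-substrate/two-product form with NADPH and NADP held at
    fixed concentrations; can be negative when bh4 dominates."""
    bh2 = _check_nonneg("bh2", bh2)
    bh4 = _check_nonneg("bh4", bh4)
    fwd = (p.drr_vmax_f * bh2 * p.nadph
           / ((p.drr_k_bh2 + bh2) * (p.drr_k_nadph + p.nadph)))
    back = (p.drr_vmax_b * bh4 * p.nadp
            / ((p.drr_k_bh4 + bh4) * (p.drr_k_nadp + p.nadp)))
    return fwd - back


def v_trpin(btrp: float, p: KineticParameters) -> float:
    """Tryptophan transport from serum into the terminal (μM/hr)."""
    btrp = _check_nonneg("btrp", btrp)
    return p.trpin_vmax * btrp / (p.trpin_km + btrp)


def v_mat_net(c5ht: float, v5ht: float, p: KineticParameters) -> float:
    """Net vesicular monoamine transport (μM/hr), positive into vesicles:
    saturable uptake minus a linear leak back to the cytosol."""
    c5ht = _check_nonneg("c5ht", c5ht)
    v5ht = _check_nonneg("v5ht", v5ht)
    return p.mat_vmax * c5ht / (p.mat_km + c5ht) - p.mat_k_out * v5ht


def v_sert(e5ht: float, unblocked_fraction: float,
           p: KineticParameters) -> float:
    """SERT reuptake rate (μM/hr) scaled by the unblocked fraction."""
    e5ht = _check_nonneg("e5ht", e5ht)
    if not 0.0 <= unblocked_fraction <= 1.0:
        raise ValueError(
            f"unblocked_fraction must lie in [0, 1], got {unblocked_fraction}")
    return unblocked_fraction * p.sert_vmax * e5ht / (p.sert_km + e5ht)


def clearances(state: TerminalState, p: KineticParameters) -> dict[str, float]:
    """First-order and MM clearance fluxes: cytosolic and extracellular
    catabolism, removal of extracellular 5-HT, 5-HIAA clearance, and the net
    trp -> trp-pool exchange flux (positive into the pool)."""
    c5ht = _check_nonneg("c5ht", state.c5ht)
    e5ht = _check_nonneg("e5ht", state.e5ht)
    hiaa5 = _check_nonneg("hiaa5", state.hiaa5)
    trp = _check_nonneg("trp", state.trp)
    pool = _check_nonneg("trp_pool", state.trp_pool)
    return {
        "v_catab_c": p.catab_c_vmax * c5ht / (p.catab_c_km + c5ht),
        "v_catab_e": p.catab_e_vmax * e5ht / (p.catab_e_km + e5ht),
        "v_rem": p.k_rem * e5ht,
        "v_hiaa_out": p.hiaa_k_catab * hiaa5,
        "pool_flux": p.pool_k1 * trp - p.pool_k_minus1 * pool,
    }


def velocities(state: TerminalState, p: KineticParameters,
               cfg: AutoreceptorConfig = AutoreceptorConfig(),
               fire: float = 1.0, fluox: float = 1.0,
               btrp: float = 96.0) -> dict[str, float]:
    """All named reaction/transport velocities (μM/hr) at one state."""
    out = clearances(state, p)
    out["v_tph"] = v_tph(state.trp, state.bh4, state.e5ht, p, cfg)
    out["v_aadc"] = v_aadc(state.htp5, p)
    out["v_drr"] = v_drr(state.bh2, state.bh4, p)
    out["v_trpin"] = v_trpin(btrp, p)
    out["v_mat_net"] = v_mat_net(state.c5ht, state.v5ht, p)
    out["v_sert"] = fluox * v_sert(state.e5ht, 1.0, p)
    out["release_factor"] = release_factor(state.e5ht, p, cfg)
    out["synthesis_factor"] = synthesis_factor(state.e5ht, p, cfg)
    out["v_release"] = (out["release_factor"] * fire
                        * max(state.v5ht, 0.0))
    out["v_pool_catab"] = p.pool_k_catab * max(state.trp_pool, 0.0)
    return out


def rhs_array(t: float, y: np.ndarray, p: KineticParameters,
              drivers: Drivers,
              cfg: AutoreceptorConfig = AutoreceptorConfig()) -> np.ndarray:
    """Right-hand side of the nine ODEs on a raw state array.

    Negative components (solver round-off) are clipped to zero for rate
    evaluation only; the integrated state itself is never altered, so
    conservation checks stay honest.
    """
    bh2, bh4, trp, htp5, c5ht, v5ht, e5ht, hiaa5, trp_pool = (
        max(float(v), 0.0) for v in y)

    fire = drivers.fire(t)
    fluox = drivers.fluox(t)
    btrp = drivers.btrp(t)
    if not (math.isfinite(fire) and math.isfinite(fluox)
            and math.isfinite(btrp)):
        raise ValueError(f"driver undefined or non-finite at t = {t}")

    vtph = v_tph(trp, bh4, e5ht, p, cfg)
    vdrr = v_drr(bh2, bh4, p)
    vtrpin = v_trpin(btrp, p)
    vaadc = v_aadc(htp5, p)
    vmat = v_mat_net(c5ht, v5ht, p)
    vsert = fluox * v_sert(e5ht, 1.0, p)
    vrelease = release_factor(e5ht, p, cfg) * fire * v5ht
    vcatab_c = p.catab_c_vmax * c5ht / (p.catab_c_km + c5ht)
    vcatab_e = p.catab_e_vmax * e5ht / (p.catab_e_km + e5ht)
    vrem = p.k_rem * e5ht
    pool_flux = p.pool_k1 * trp - p.pool_k_minus1 * trp_pool

    dydt = np.array([
        vtph - vdrr,                                   # bh2
        vdrr - vtph,                                   # bh4
        vtrpin - vtph - pool_flux,                     # trp
        vtph - vaadc,                                  # 5htp
        vaadc - vmat + vsert - vcatab_c,               # c5ht
        vmat - vrelease,                               # v5ht
        vrelease - vsert - vcatab_e - vrem,            # e5ht
        vcatab_c + vcatab_e - p.hiaa_k_catab * hiaa5,  # 5hiaa
        pool_flux - p.pool_k_catab * trp_pool,         # trp_pool
    ])
    if not np.all(np.isfinite(dydt)):
        raise FloatingPointError(
            f"non-finite derivative at t = {t}: {dict(zip(STATE_FIELDS, dydt))}")
    return dydt


def rhs(t: float, state: TerminalState, p: KineticParameters,
        drivers: Drivers,
        cfg: AutoreceptorConfig = AutoreceptorConfig()) -> dict[str, float]:
    """Typed wrapper around :func:`rhs_array`: derivatives (μM/hr) keyed by
    state-field name."""
    dydt = rhs_array(t, state.to_array(), p, drivers, cfg)
    return dict(zip(STATE_FIELDS, map(float, dydt)))
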