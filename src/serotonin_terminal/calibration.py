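"""Calibration of the under-determined model constants.

Three groups of constants are not fixed by the source physiology and are
instead pinned so that the model's baseline steady state (fire = 1/hr, all
SERTs unblocked, serum tryptophan 96 μM) reproduces the printed reference
concentrations and fluxes:

* the biopterin pool — bh4* is the level at which the TPH flux equals the
  target synthesis flux at the target tryptophan concentration, and bh2* is
  the level at which the reductase exactly regenerates it; their sum is the
  conserved biopterin total;
* the vesicular leak ``mat_k_out`` — chosen so the net MAT flux equals the
  release flux at the cytosolic/vesicular reference concentrations;
* the tryptophan-pool constants ``pool_k1`` and ``pool_k_catab`` — chosen so
  the cellular tryptophan equation and the pool equation both vanish with
  the pool ten times larger than cellular tryptophan.

The last calibration exists because the printed exchange constants
(k1 = 6, k-1 = 0.6, k_catab = 0.2, read as first-order /hr constants) are
flux-infeasible: the maximum steady pool efflux they allow, k1·trp*, is
smaller than the influx the pool must absorb (uptake minus synthesis).
:func:`printed_pool_constants_analysis` carries that arithmetic and
:func:`calibrate` emits it as a warning rather than silently patching it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.optimize import brentq

from .model import (
    AutoreceptorConfig,
    KineticParameters,
    TerminalState,
    v_drr,
    v_sert,
    v_tph,
    v_trpin,
)

__all__ = [
    "CalibrationTargets",
    "calibrate",
    "calibrate_biopterin",
    "calibrate_mat",
    "calibrate_trp_pool",
    "flux_consistent_state",
    "printed_pool_constants_analysis",
    "baseline_model",
    "verify_flux_closure",
]

logger = logging.getLogger(__name__)

#: the exchange constants as printed in the source parameter table, read as
#: first-order rate constants (/hr); kept for the infeasibility analysis
PRINTED_POOL_K1 = 6.0
PRINTED_POOL_K_CATAB = 0.2


@dataclass(frozen=True)
class CalibrationTargets:
    """Reference baseline concentrations (μM) and fluxes (μM/hr)."""

    trp_star: float = 20.6          # cellular tryptophan
    pool_ratio: float = 10.0        # trp-pool : trp
    btrp_baseline: float = 96.0     # fasted serum tryptophan
    uptake_flux: float = 159.0      # reported brain tryptophan uptake
    synthesis_flux: float = 5.57    # TPH = AADC flux at steady state
    c5ht_star: float = 0.5          # cytosolic 5-HT
    v5ht_star: float = 21.45        # vesicular 5-HT
    e5ht_star: float = 0.000768     # extracellular 5-HT (0.768 nM)
    htp5_star: float = 2.26         # 5-HTP
    hiaa_star: float = 5.22         # 5-HIAA

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")


# ---------------------------------------------------------------------------
# the flux-forced reference state
# ---------------------------------------------------------------------------

def _e5ht_side_fluxes(p: KineticParameters,
                      targets: CalibrationTargets) -> dict[str, float]:
    """Clearance fluxes out of the extracellular compartment at e5ht*."""
    e = targets.e5ht_star
    return {
        "v_sert": v_sert(e, 1.0, p),
        "v_catab_e": p.catab_e_vmax * e / (p.catab_e_km + e),
        "v_rem": p.k_rem * e,
    }


def forced_v5ht(p: KineticParameters, targets: CalibrationTargets) -> float:
    """Vesicular 5-HT required for the extracellular equation to vanish.

    At e5ht* both autoreceptor factors equal 1, so with fire = 1/hr the
    release flux equals v5ht numerically; it must balance reuptake,
    extracellular catabolism, and removal.
    """
    f = _e5ht_side_fluxes(p, targets)
    return f["v_sert"] + f["v_catab_e"] + f["v_rem"]


def forced_c5ht(p: KineticParameters, targets: CalibrationTargets) -> float:
    """Cytosolic 5-HT forced by catabolism closure.

    The synthesis flux must leave as cytosolic catabolism plus the
    extracellular losses, so the cytosolic catabolism flux is known and the
    MM form is inverted for c5ht.
    """
    f = _e5ht_side_fluxes(p, targets)
    v_catab_c = targets.synthesis_flux - f["v_catab_e"] - f["v_rem"]
    if not 0.0 < v_catab_c < p.catab_c_vmax:
        raise ValueError(
            f"required cytosolic catabolism flux {v_catab_c:.4g} μM/hr is "
            f"outside (0, Vmax = {p.catab_c_vmax:g})")
    return p.catab_c_km * v_catab_c / (p.catab_c_vmax - v_catab_c)


def calibrate_biopterin(p: KineticParameters,
                        targets: CalibrationTargets | None = None,
                        ) -> tuple[float, float, float]:
    """Solve for (bh4*, bh2*, biopterin total).

    bh4* makes the TPH flux equal the target synthesis flux at the target
    tryptophan level and e5ht* (where the synthesis factor is exactly 1);
    bh2* makes the net reductase flux match it.  Their sum becomes the
    conserved biopterin pool used as the initial condition.
    """
    targets = targets or CalibrationTargets()
    goal = targets.synthesis_flux
    if goal == 0.0:
        return 0.0, 0.0, 0.0
    cfg = AutoreceptorConfig()  # factor is 1 at e5ht_star by construction

    def tph_gap(b4: float) -> float:
        return v_tph(targets.trp_star, b4, targets.e5ht_star, p, cfg) - goal

    hi = 1e3
    if tph_gap(hi) < 0:
        raise ValueError(
            f"no bh4 in (0, {hi:g}] μM attains a TPH flux of {goal:g} μM/hr; "
            "TPH parameters are inconsistent with the synthesis target")
    bh4_star = brentq(tph_gap, 0.0, hi, xtol=1e-14, rtol=1e-15)

    def drr_gap(b2: float) -> float:
        return v_drr(b2, bh4_star, p) - goal

    if drr_gap(hi) < 0:
        raise ValueError(
            f"no bh2 in (0, {hi:g}] μM attains a DRR flux of {goal:g} μM/hr")
    bh2_star = brentq(drr_gap, 0.0, hi, xtol=1e-14, rtol=1e-15)
    return bh4_star, bh2_star, bh4_star + bh2_star


def calibrate_mat(p: KineticParameters,
                  targets: CalibrationTargets | None = None) -> float:
    """Vesicular leak constant (/hr) closing the vesicular flux balance.

    At steady state the net MAT flux must equal the release flux, which at
    baseline equals the forced vesicular concentration numerically.
    """
    targets = targets or CalibrationTargets()
    c_star = forced_c5ht(p, targets)
    v_star = forced_v5ht(p, targets)
    if c_star <= 0.0:
        raise ValueError("cytosolic 5-HT reference must be positive")
    uptake = p.mat_vmax * c_star / (p.mat_km + c_star)
    k_out = (uptake - v_star) / v_star
    if k_out <= 0.0:
        raise ValueError(
            f"mat_vmax = {p.mat_vmax:g} μM/hr is too small: MAT uptake "
            f"{uptake:.4g} does not exceed the required release flux "
            f"{v_star:.4g}")
    return k_out


def calibrate_trp_pool(p: KineticParameters,
                       targets: CalibrationTargets | None = None,
                       ) -> tuple[float, float]:
    """(pool_k1, pool_k_catab) in /hr closing the tryptophan balance.

    With the pool at ``pool_ratio`` times the cellular tryptophan target,
    the pool catabolism constant absorbs the uptake flux not consumed by
    synthesis, and k1 then makes the exchange flux vanish together with the
    pool equation.  ``pool_k_minus1`` stays at its fixed value.
    """
    targets = targets or CalibrationTargets()
    uptake = v_trpin(targets.btrp_baseline, p)
    pool = targets.pool_ratio * targets.trp_star
    k_catab = (uptake - targets.synthesis_flux) / pool
    if k_catab <= 0.0:
        raise ValueError(
            f"uptake flux {uptake:.4g} μM/hr does not exceed the synthesis "
            f"flux {targets.synthesis_flux:g}; pool turnover infeasible")
    k1 = (p.pool_k_minus1 + k_catab) * pool / targets.trp_star
    if k1 <= 0.0:
        raise ValueError("non-positive pool exchange constant")
    return k1, k_catab


def printed_pool_constants_analysis(
        p: KineticParameters,
        targets: CalibrationTargets | None = None,
        k1_printed: float = PRINTED_POOL_K1) -> dict[str, float | bool]:
    """Flux-balance check of the printed trp-pool exchange constants.

    At steady state the pool must absorb the uptake flux minus the synthesis
    flux; the largest steady efflux from cellular tryptophan into the pool
    that a first-order k1 can sustain is k1·trp*.  The printed k1 = 6/hr
    falls well short, which is why the pool constants are calibrated.
    """
    targets = targets or CalibrationTargets()
    required = v_trpin(targets.btrp_baseline, p) - targets.synthesis_flux
    attainable = k1_printed * targets.trp_star
    return {
        "required_efflux_uM_hr": required,
        "max_efflux_uM_hr": attainable,
        "k1_printed_per_hr": k1_printed,
        "feasible": attainable >= required,
    }


def calibrate(p: KineticParameters | None = None,
              targets: CalibrationTargets | None = None,
              ) -> tuple[KineticParameters, TerminalState]:
    """Run the full calibration pipeline.

    Returns the parameter set with ``mat_k_out``, ``pool_k1`` and
    ``pool_k_catab`` replaced by their calibrated values, together with the
    flux-consistent baseline state (an exact fixed point of the dynamics).
    Idempotent: calibrating an already-calibrated set reproduces it.
    """
    p = p or KineticParameters()
    targets = targets or CalibrationTargets()

    analysis = printed_pool_constants_analysis(p, targets)
    if not analysis["feasible"]:
        logger.warning(
            "printed trp-pool constants are flux-infeasible: required pool "
            "efflux %.1f μM/hr exceeds the attainable k1*trp = %.1f μM/hr; "
            "using calibrated first-order constants instead",
            analysis["required_efflux_uM_hr"], analysis["max_efflux_uM_hr"])

    k_out = calibrate_mat(p, targets)
    k1, k_catab = calibrate_trp_pool(p, targets)
    p_cal = p.replace(mat_k_out=k_out, pool_k1=k1, pool_k_catab=k_catab)
    return p_cal, flux_consistent_state(p_cal, targets)


def flux_consistent_state(p: KineticParameters,
                          targets: CalibrationTargets | None = None,
                          ) -> TerminalState:
    """The baseline state at which all nine equations vanish.

    Assumes ``p`` already carries calibrated pool/MAT constants; the
    remaining components follow from inverting the clearance rate laws at
    the target fluxes.
    """
    targets = targets or CalibrationTargets()
    f = _e5ht_side_fluxes(p, targets)
    bh4_star, bh2_star, _ = calibrate_biopterin(p, targets)
    s = targets.synthesis_flux
    if s >= p.aadc_vmax:
        raise ValueError("synthesis flux exceeds AADC capacity")
    htp5 = p.aadc_km * s / (p.aadc_vmax - s)
    c5ht = forced_c5ht(p, targets)
    v_catab_c = p.catab_c_vmax * c5ht / (p.catab_c_km + c5ht)
    hiaa5 = (v_catab_c + f["v_catab_e"]) / p.hiaa_k_catab
    return TerminalState(
        bh2=bh2_star,
        bh4=bh4_star,
        trp=targets.trp_star,
        htp5=htp5,
        c5ht=c5ht,
        v5ht=forced_v5ht(p, targets),
        e5ht=targets.e5ht_star,
        hiaa5=hiaa5,
        trp_pool=targets.pool_ratio * targets.trp_star,
    )


def baseline_model(targets: CalibrationTargets | None = None,
                   ) -> tuple[KineticParameters, TerminalState,
                              AutoreceptorConfig]:
    """Calibrated parameters, baseline state, and default autoreceptor
    configuration — the standard starting point for every experiment."""
    p, state = calibrate(targets=targets)
    return p, state, AutoreceptorConfig()


def verify_flux_closure(p: KineticParameters, steady: TerminalState,
                        cfg: AutoreceptorConfig = AutoreceptorConfig(),
                        fire: float = 1.0, fluox: float = 1.0,
                        btrp: float = 96.0,
                        targets: CalibrationTargets | None = None):
    """Build a steady-state report with all velocities and the residuals of
    the five flux-balance identities (synthesis = decarboxylation; MAT =
    release; release = reuptake + catabolism + removal; synthesis = total
    serotonin clearance; uptake = pool catabolism + synthesis)."""
    # local import: solvers imports model, not calibration, so no cycle
    from .solvers import steady_state_report
    return steady_state_report(p, steady, cfg=cfg, fire=fire, fluox=fluox,
                               btrp=btrp, targets=targets or CalibrationTargets())
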