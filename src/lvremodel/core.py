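"""Structural functions and the right-hand side of the remodeling ODE system.

The system couples seven states:

.. math::

    dM_\\phi/dt &= M(T_\\beta)\\,\\max(1 - \\kappa, 0) - d_{M\\phi} M_\\phi \\\\
    dF/dt &= k_F F_g(T_\\beta) F (1 - \\kappa) - d_F F \\\\
    dT_\\beta/dt &= u_T(t) + k_{M\\phi T} M_\\phi + k_{FT} F - d_{T\\beta} T_\\beta \\\\
    dM_{9A}/dt &= k_{M\\phi M9} M_\\phi h(T_\\beta) - d_{M9} M_{9A}
                  - k_{on} C M_{9A} + k_{off} CM_9 \\\\
    dC/dt &= k_{FC} F_c(T_\\beta) F_c(C) F (1 - \\kappa)
             - k_{on} C M_{9A} + k_{off} CM_9 \\\\
    dCM_9/dt &= k_{on} C M_{9A} - k_{onc} CM_9 \\\\
    dCID/dt &= k_{onc} CM_9 - d_{CID} CID

where :math:`\\kappa` is the crowding fraction (structural cells decaying as
infarcted myocytes die, plus macrophages, fibroblasts and collagen each
normalised to their maximal packing density) and
:math:`h(T) = 1/(1 + T/T_{\\beta N})` is the TIMP-1-mediated inhibition of
MMP-9.  The crowding limiter :math:`(1-\\kappa)` may go negative
(over-crowding actively suppresses growth and secretion); macrophage influx
uses :math:`\\max(1-\\kappa, 0)` since immigration cannot reverse.
"""

from __future__ import annotations

import dataclasses
import math
from typing import TYPE_CHECKING

import numpy as np

from .params import ModelParameters, ModelState

if TYPE_CHECKING:  # pragma: no cover
    from .curves import InteractionCurveSet

__all__ = [
    "ModelOptions",
    "StimulusProfile",
    "InterventionSpec",
    "myocyte_crowding",
    "crowding_fraction",
    "timp_inhibition",
    "tgf_activation_input",
    "make_rhs",
    "rhs",
]


@dataclasses.dataclass(frozen=True)
class ModelOptions:
    """Configuration switches for structurally ambiguous model terms.

    complex_loss
        "konc" (default): complex decays only through catalytic turnover,
        the choice consistent with the published complex equilibrium;
        "koff+konc": dissociation also drains the complex.
    inhibition_site
        "secretion" (default): h(T_beta) scales macrophage MMP-9 secretion;
        "association": h(T_beta) scales the MMP-9/collagen association flux.
    clip_limiter
        If True, clip (1 - crowding) at zero everywhere instead of letting
        over-crowding actively suppress growth and secretion.
    """

    complex_loss: str = "konc"
    inhibition_site: str = "secretion"
    clip_limiter: bool = False

    def __post_init__(self) -> None:
        if self.complex_loss not in ("konc", "koff+konc"):
            raise ValueError(f"unknown complex_loss {self.complex_loss!r}")
        if self.inhibition_site not in ("secretion", "association"):
            raise ValueError(f"unknown inhibition_site {self.inhibition_site!r}")


@dataclasses.dataclass(frozen=True)
class StimulusProfile:
    """Exogenous TGF-beta1 activation pulse after infarction.

    A smooth unimodal pulse that attains ``amplitude`` (pg/uL/day) exactly
    at ``peak_day`` and is negligible well before day 30.  The default
    log-normal shape with ``width`` = 0.33 log-days is below 0.1% of its
    peak by day 7 (for a day-2 peak), mimicking the reported return of the
    TGF-beta1 expression profile to normal after day 7; the width is part
    of the one-time calibration of the default study conditions.
    """

    amplitude: float
    peak_day: float = 2.0
    shape: str = "lognormal"
    width: float = 0.33

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be >= 0")
        if self.peak_day <= 0:
            raise ValueError("peak_day must be > 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.shape not in ("lognormal", "gamma"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")

    def pulse(self, t):
        """Pulse value (pg/uL/day) at time ``t`` (days); zero for t <= 0."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        if self.amplitude > 0 and np.any(pos):
            tp = t[pos]
            if self.shape == "lognormal":
                z = np.log(tp / self.peak_day) / self.width
                out[pos] = self.amplitude * np.exp(-0.5 * z * z)
            else:  # gamma-shaped: (t/tp)^k exp(k(1 - t/tp)), peak at tp
                k = (self.peak_day / self.width) ** 2
                r = tp / self.peak_day
                out[pos] = self.amplitude * np.exp(k * (np.log(r) + 1.0 - r))
        return out if out.ndim else float(out)


@dataclasses.dataclass(frozen=True)
class InterventionSpec:
    """Exogenous forcing of free MMP-9.

    ``mode="clamp"`` holds the free-MMP-9 coordinate at ``level`` (pg/uL)
    from ``start_day`` onward: its derivative is zeroed while binding fluxes
    to collagen are still computed from the clamped value.
    """

    mode: str = "none"
    level: float = 0.0
    start_day: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "clamp"):
            raise ValueError(f"unknown intervention mode {self.mode!r}")
        if self.level < 0:
            raise ValueError("intervention level must be >= 0")
        if self.start_day < 0:
            raise ValueError("start_day must be >= 0")

    @property
    def active(self) -> bool:
        return self.mode == "clamp"


NONE_INTERVENTION = InterventionSpec()


def myocyte_crowding(t, params: ModelParameters):
    """Structural occupancy k_mem(t) of myocytes + endothelium + smooth muscle.

    k_mem(t) = frac_endo_smc + frac_myocyte * exp(-d_mc * t): infarcted
    myocytes die at rate ``d_mc`` while the vascular fraction persists.
    Monotone non-increasing from frac_endo_smc + frac_myocyte down to
    frac_endo_smc.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = params.frac_endo_smc + params.frac_myocyte * np.exp(-params.d_mc * t)
    return out if out.ndim else float(out)


def crowding_fraction(state: ModelState, t: float, params: ModelParameters) -> float:
    """Total occupancy fraction: structural cells + normalised densities.

    The growth/influx limiter used in the cell and collagen equations is
    (1 - crowding_fraction); it may transiently be negative.
    """
    return float(
        myocyte_crowding(t, params)
        + state.M_phi / params.rho_Mphi
        + state.F / params.rho_F
        + state.C / params.rho_C
    )


def timp_inhibition(T_beta, params: ModelParameters):
    """TIMP-1-mediated inhibition of MMP-9, h(T) = 1/(1 + T_beta/T_betaN)."""
    T_beta = np.asarray(T_beta, dtype=float)
    if np.any(T_beta < 0):
        raise ValueError("T_beta must be >= 0")
    out = 1.0 / (1.0 + T_beta / params.T_betaN)
    return out if out.ndim else float(out)


def tgf_activation_input(t, stimulus: StimulusProfile, params: ModelParameters):
    """Total TGF-beta1 activation u_T(t) = u_T0 + pulse(t), pg/uL/day."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = np.asarray(params.u_T0 + np.asarray(stimulus.pulse(t)))
    return out if out.ndim else float(out)


def make_rhs(
    params: ModelParameters,
    curves: "InteractionCurveSet",
    stimulus: StimulusProfile,
    options: ModelOptions = ModelOptions(),
    clamp_level: float | None = None,
    offsets: np.ndarray | None = None,
    freeze_kmem: bool = False,
):
    """Build the derivative function f(t, y) for the seven-state system.

    Parameters
    ----------
    clamp_level
        If not None, free MMP-9 is held at this value: its derivative is
        zero and all fluxes use the clamped concentration.
    offsets
        Optional constant per-equation source/sink vector (length 7), used
        by the balanced-baseline mode to make a reference state an exact
        fixed point of the zero-stimulus system.
    freeze_kmem
        Evaluate the structural crowding term at t=0 (healthy tissue: no
        myocyte death), used by the balanced-baseline mode.
    """
    kon, koff, konc = params.kinetics_per_day()
    p = params
    opt = options
    off = None if offsets is None else np.asarray(offsets, dtype=float)

    migration = curves.migration
    growth = curves.growth
    sec_tgf = curves.secretion_tgf
    sec_col = curves.secretion_collagen

    kmem0 = p.frac_endo_smc + p.frac_myocyte

    def f(t: float, y: np.ndarray) -> np.ndarray:
        # guard against tiny solver undershoots below zero
        Mphi, F, Tb, M9A, C, CM9, CID = np.maximum(y, 0.0)
        if clamp_level is not None:
            M9A = clamp_level

        if freeze_kmem:
            kmem = kmem0
        else:
            kmem = p.frac_endo_smc + p.frac_myocyte * math.exp(-p.d_mc * t)
        crowd = kmem + Mphi / p.rho_Mphi + F / p.rho_F + C / p.rho_C
        lim = 1.0 - crowd
        if opt.clip_limiter and lim < 0.0:
            lim = 0.0
        lim_in = max(lim, 0.0)  # influx cannot reverse

        h = 1.0 / (1.0 + Tb / p.T_betaN)
        uT = p.u_T0 + stimulus.pulse(t)

        if opt.inhibition_site == "secretion":
            secretion = p.k_MphiM9 * Mphi * h
            assoc = kon * C * M9A
        else:
            secretion = p.k_MphiM9 * Mphi
            assoc = kon * C * M9A * h
        unbind = koff * CM9

        dMphi = migration(Tb) * lim_in - p.d_Mphi * Mphi
        dF = p.k_F * growth(Tb) * F * lim - p.d_F * F
        dTb = uT + p.k_MphiT * Mphi + p.k_FT * F - p.d_Tbeta * Tb
        dM9A = secretion - p.d_M9 * M9A - assoc + unbind
        dC = p.k_FC * sec_tgf(Tb) * sec_col(C) * F * lim - assoc + unbind
        if opt.complex_loss == "konc":
            dCM9 = assoc - konc * CM9
        else:
            dCM9 = assoc - (koff + konc) * CM9
        dCID = konc * CM9 - p.d_CID * CID

        dy = np.array([dMphi, dF, dTb, dM9A, dC, dCM9, dCID])
        if off is not None:
            dy = dy + off
        if clamp_level is not None:
            dy[3] = 0.0
        return dy

    return f


def rhs(
    t: float,
    state: ModelState,
    params: ModelParameters,
    stimulus: StimulusProfile,
    intervention: InterventionSpec,
    curves: "InteractionCurveSet",
    options: ModelOptions = ModelOptions(),
) -> ModelState:
    """Evaluate the per-day derivative of the full system at one point.

    Raises if any state component is meaningfully negative (beyond 1e-9 of
    its scale); tiny solver undershoots are tolerated and clipped.
    """
    y = state.as_array()
    scale = np.array([5.0, 20.0, 0.21, 7.1, 839.5, 447.6, 1.0])
    if np.any(y < -1e-9 * scale):
        raise ValueError(f"negative state component beyond tolerance at t={t}: {state}")
    clamp = intervention.level if (intervention.active and t >= intervention.start_day) else None
    f = make_rhs(params, curves, stimulus, options, clamp_level=clamp)
    return ModelState.from_array(f(t, y))
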