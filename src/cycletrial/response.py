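"""Effective-dose drug interaction, Hill responses and response metrics.

The two-drug pharmacodynamic layer couples fulvestrant (F) and palbociclib
(P) to the single treatment-sensitive rate of the cell-cycle chain, the
G1→S exit rate. The interaction follows a Bliss extension in which each
drug acts at an *effective* concentration rescaled by its partner,

    d_F,eff = d_F / (1 + a_FP · d_P / C_P),        d_P,eff = d_P,

(the P-on-F interaction parameter a_FP is free; the reciprocal a_PF is
fixed to zero, a standard one-parameter reduction). Negative a_FP means
synergy (the partner inflates the effective dose), positive antagonism.
Each effective dose enters a Hill response E(d) = e_inf + (1−e_inf) /
(1 + (d/C)^h), and the treated G1→S rate is the Bliss product

    λ(d_F, d_P) = λ_ctrl · E_F(d_F,eff) · E_P(d_P).

Metrics: the G1–S TR50 (dose halving the G1→S rate relative to control),
the operational day-5 count IC50, and the normalized growth-rate
inhibition GR = 2^(k/k_ctrl) − 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "InteractionParams",
    "effective_dose",
    "hill_response",
    "g1s_rate",
    "tr50",
    "ic50_from_counts",
    "gr_value",
    "response_surface",
    "DENOM_FLOOR",
]

logger = logging.getLogger(__name__)

_clamp_warned = False

#: Lower clamp on the effective-dose denominator 1 + a·d_other/C_other.
#: With a < 0 the denominator crosses zero at large partner dose; the clamp
#: keeps effective doses finite and monotone over the whole orthant.
DENOM_FLOOR = 0.05


@dataclass(frozen=True)
class InteractionParams:
    """Joint dose-response parameters of the fulvestrant+palbociclib pair.

    Half-max doses ``C_F``/``C_P`` are in nmol/L; Hill slopes are
    dimensionless; ``a_FP`` is the fulvestrant-on-palbociclib interaction
    term (a_PF is identically zero); ``lambda_ctrl`` is the untreated G1→S
    exit rate in 1/day; ``e_inf_*`` are residual response floors in [0, 1)
    (the response at infinite dose is lambda_ctrl·e_inf).
    """

    C_F: float
    C_P: float
    h_F: float
    h_P: float
    a_FP: float
    lambda_ctrl: float
    e_inf_F: float = 0.0
    e_inf_P: float = 0.0

    def __post_init__(self) -> None:
        for name in ("C_F", "C_P", "h_F", "h_P", "lambda_ctrl"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in ("e_inf_F", "e_inf_P"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {v!r}")
        if not np.isfinite(self.a_FP):
            raise ValueError("a_FP must be finite")

    def with_scaled_C_P(self, factor: float) -> "InteractionParams":
        """Resistance variant: half-max palbociclib dose scaled by ``factor``."""
        return replace(self, C_P=self.C_P * factor)


def effective_dose(d_own, d_other, a: float, C_other: float):
    """Effective concentration of a drug given its partner's level.

    d_eff = d_own / max(1 + a·d_other/C_other, DENOM_FLOOR). Synergy
    (a < 0) inflates, antagonism (a > 0) deflates the effective dose.
    Accepts scalars or arrays.
    """
    d_own = np.asarray(d_own, dtype=float)
    d_other = np.asarray(d_other, dtype=float)
    if (d_own < 0).any() or (d_other < 0).any():
        raise ValueError("doses must be non-negative")
    denom = 1.0 + a * d_other / C_other
    n_clamped = int(np.sum(denom < DENOM_FLOOR))
    if n_clamped:
        # warn loudly once; routine clamping in deep-synergy sweeps goes to DEBUG
        global _clamp_warned
        level = logging.DEBUG if _clamp_warned else logging.WARNING
        _clamp_warned = True
        logger.log(
            level, "effective_dose: clamped %d denominator value(s) at %.2f",
            n_clamped, DENOM_FLOOR,
        )
    out = d_own / np.maximum(denom, DENOM_FLOOR)
    return out if out.ndim else float(out)


def hill_response(d_eff, C: float, h: float, e_inf: float = 0.0):
    """Decreasing Hill curve E(d) = e_inf + (1−e_inf)/(1 + (d/C)^h).

    E(0) = 1 and E(∞) = e_inf; C is the half-response dose when e_inf = 0.
    """
    d_eff = np.asarray(d_eff, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = (d_eff / C) ** h  # inf at extreme dose/slope -> E = e_inf
    out = e_inf + (1.0 - e_inf) / (1.0 + ratio)
    return out if out.ndim else float(out)


def g1s_rate(d_F, d_P, p: InteractionParams):
    """Treated G1→S exit rate λ(d_F, d_P) in 1/day (Bliss product form).

    Fulvestrant acts at its effective dose (rescaled by palbociclib through
    a_FP); palbociclib acts at its actual dose since a_PF = 0.
    """
    d_f_eff = effective_dose(d_F, d_P, p.a_FP, p.C_P)
    e_f = hill_response(d_f_eff, p.C_F, p.h_F, p.e_inf_F)
    e_p = hill_response(np.asarray(d_P, dtype=float), p.C_P, p.h_P, p.e_inf_P)
    out = p.lambda_ctrl * e_f * e_p
    return out if np.ndim(out) else float(out)


def tr50(p: InteractionParams, drug: str, d_partner: float = 0.0):
    """G1–S TR50: dose at which λ(d)/λ(0,0) crosses 1/2.

    ``drug`` selects the varied axis ("F" or "P"); the partner is held at
    ``d_partner``. Solved by bracketing bisection (brentq) to 1e-10
    relative. Returns None when the half-response is unattainable (e.g.
    response floors keep the normalized rate above 1/2).
    """
    if drug not in ("F", "P"):
        raise ValueError("drug must be 'F' or 'P'")
    lam0 = g1s_rate(0.0, 0.0, p)

    def ratio_minus_half(d):
        if drug == "F":
            lam = g1s_rate(d, d_partner, p)
        else:
            lam = g1s_rate(d_partner, d, p)
        return lam / lam0 - 0.5

    if ratio_minus_half(0.0) <= 0:
        return 0.0
    c_ref = p.C_F if drug == "F" else p.C_P
    hi = c_ref
    for _ in range(200):
        if ratio_minus_half(hi) < 0:
            break
        hi *= 2.0
    else:
        return None
    lo = hi / 2.0 if hi > c_ref else 0.0
    while lo > 0 and ratio_minus_half(lo) < 0:
        lo /= 2.0
    return float(brentq(ratio_minus_half, lo, hi, rtol=1e-12, maxiter=200))


def ic50_from_counts(doses, day5_counts, control_count: float):
    """Operational IC50: dose at which day-5 count is half the control.

    Monotone piecewise-linear interpolation of count/control against
    log-dose over the tested positive doses; returns the first downward
    crossing of 1/2. Extrapolation outside the tested range is refused:
    returns None ("out of range") when the curve never crosses 1/2.
    """
    doses = np.asarray(doses, dtype=float)
    counts = np.asarray(day5_counts, dtype=float)
    if doses.size != counts.size:
        raise ValueError("doses and day5_counts must align")
    if doses.size < 3 or not np.any(doses == 0):
        raise ValueError("need at least 3 dose points including dose 0")
    if control_count <= 0 or (counts <= 0).any():
        raise ValueError("counts must be positive")
    order = np.argsort(doses)
    doses, counts = doses[order], counts[order]
    pos = doses > 0
    frac = counts[pos] / control_count
    logd = np.log(doses[pos])
    for i in range(frac.size):
        if abs(frac[i] - 0.5) < 1e-12:
            return float(np.exp(logd[i]))
        if i > 0 and (frac[i - 1] - 0.5) * (frac[i] - 0.5) < 0:
            w = (0.5 - frac[i - 1]) / (frac[i] - frac[i - 1])
            return float(np.exp(logd[i - 1] + w * (logd[i] - logd[i - 1])))
    return None


def gr_value(k_treated: float, k_control: float) -> float:
    """Normalized growth-rate inhibition GR = 2^(k_treated/k_control) − 1.

    1 at no effect, 0 at complete cytostasis, negative under cytotoxicity.
    """
    if k_control <= 0:
        raise ValueError("k_control must be positive")
    return float(2.0 ** (k_treated / k_control) - 1.0)


def response_surface(p: InteractionParams, doses_F, doses_P) -> pd.DataFrame:
    """Normalized G1→S rate over the dose grid (tidy d_F × d_P table)."""
    doses_F = np.asarray(doses_F, dtype=float)
    doses_P = np.asarray(doses_P, dtype=float)
    lam0 = g1s_rate(0.0, 0.0, p)
    df, dp = np.meshgrid(doses_F, doses_P, indexing="ij")
    rate = g1s_rate(df.ravel(), dp.ravel(), p) / lam0
    return pd.DataFrame(
        {"dose_F": df.ravel(), "dose_P": dp.ravel(), "rate_ratio": np.asarray(rate)}
    )
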