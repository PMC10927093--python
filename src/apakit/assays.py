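"""Bench-side calculators: 2^-ddCt relative expression, actinomycin-D decay
fitting, and plaque-assay titers."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ddct", "DecayFit", "fit_decay", "plaque_titer"]


def ddct(ct_target_test: float, ct_ref_test: float,
         ct_target_control: float, ct_ref_control: float) -> float:
    """Relative expression by the 2^-ddCt method.

    ``2 ** -[(Ct_target - Ct_ref)_test - (Ct_target - Ct_ref)_control]``,
    assuming exact doubling per cycle.
    """
    vals = (ct_target_test, ct_ref_test, ct_target_control, ct_ref_control)
    if any(v is None or not math.isfinite(v) for v in vals):
        raise ValueError("all four Ct values must be finite")
    d = (ct_target_test - ct_ref_test) - (ct_target_control - ct_ref_control)
    return float(2.0 ** -d)


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit on the log scale."""

    k: float                 # decay constant, per hour (signed; >= 0 for decay)
    half_life: float         # ln2 / k hours; inf when k <= 0
    r_squared: float         # clipped to [0, 1]
    n_points: int


def fit_decay(times, abundances) -> DecayFit:
    """Fit ln(abundance) ~ time by OLS; k = -slope, half-life = ln2/k.

    Abundances are normalized to the first usable time point before
    fitting; non-positive abundances are excluded (reported); fewer than 3
    usable points is an error.  A rising series yields a signed negative k
    with a warning, and an infinite half-life.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and abundances must align")
    ok = y > 0
    if (~ok).any():
        warnings.warn(f"excluded {int((~ok).sum())} non-positive abundance point(s)")
    t, y = t[ok], y[ok]
    if len(t) < 3:
        raise ValueError("need >= 3 usable time points to fit decay")
    logy = np.log(y / y[0])
    if np.allclose(logy, logy[0]):
        return DecayFit(k=0.0, half_life=float("inf"), r_squared=1.0, n_points=len(t))
    fit = sps.linregress(t, logy)
    k = -float(fit.slope)
    if k < 0:
        warnings.warn("abundance rises over time; reporting signed k")
    half_life = math.log(2) / k if k > 0 else float("inf")
    r2 = float(fit.rvalue ** 2)
    return DecayFit(k=k, half_life=half_life, r_squared=min(max(r2, 0.0), 1.0),
                    n_points=len(t))


def plaque_titer(mean_plaques: float, dilution: float, volume_ml: float
                 ) -> tuple[float, bool]:
    """Plaque-forming units per mL: count / (D x V).

    ``dilution`` is the dilution factor in (0, 1] (0.01 for a 10^-2
    dilution); ``volume_ml`` the inoculum volume.  Returns (titer,
    below_detection): zero plaques give a titer of 0 flagged as below the
    detection limit.
    """
    if not (0 < dilution <= 1):
        raise ValueError("dilution factor must be in (0, 1]")
    if volume_ml <= 0:
        raise ValueError("inoculum volume must be positive")
    if mean_plaques < 0:
        raise ValueError("plaque count cannot be negative")
    if mean_plaques == 0:
        return 0.0, True
    return float(mean_plaques / (dilution * volume_ml)), False
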