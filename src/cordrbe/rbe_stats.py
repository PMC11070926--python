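"""RBE ratios with error propagation and trend summaries.

RBE is the ratio of the photon to the ion iso-effective dose at matched
fractionation.  Photon and ion experiments are independent, so the ratio
SE uses independent relative-variance propagation; the within-fit
(intercept, slope) correlation is already inside each delta-method ED50
SE.  Confidence limits are normal-propagation by default (matching the
symmetric published +-SE convention) with a Fieller-style variant
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dose_response import ED50Result

__all__ = ["RBEResult", "rbe_ratio", "let_trend", "dose_interp"]


@dataclass(frozen=True)
class RBEResult:
    let_value: float
    n_fractions: int
    rbe: float
    se: float
    cl90: tuple[float, float]
    ed50_photon: float
    ed50_ion: float

    def __post_init__(self) -> None:
        if self.rbe <= 0:
            raise ValueError("rbe must be positive")
        if abs(self.rbe - self.ed50_photon / self.ed50_ion) > 1e-9 * self.rbe:
            raise ValueError("rbe inconsistent with ED50 ratio")


def rbe_ratio(
    photon: ED50Result,
    ion: ED50Result,
    let_value: float = 0.0,
    n_fractions: int = 1,
    level: float = 0.90,
    method: str = "normal",
) -> RBEResult:
    """RBE = ED50_photon / ED50_ion with propagated SE and confidence limits.

    ``method="normal"`` (default) gives R +- z*SE; ``method="fieller"``
    gives the exact ratio-of-normals confidence set assuming
    independence of the two ED50 estimates.
    """
    if photon.ed50 <= 0 or ion.ed50 <= 0:
        raise ValueError("ED50 values must be positive")
    ratio = photon.ed50 / ion.ed50
    rel = math.sqrt((photon.se / photon.ed50) ** 2 + (ion.se / ion.ed50) ** 2)
    se = ratio * rel
    z = stats.norm.ppf(0.5 + level / 2.0)
    if method == "normal":
        cl = (ratio - z * se, ratio + z * se)
    elif method == "fieller":
        cl = _fieller_ratio(photon.ed50, photon.se, ion.ed50, ion.se, z)
    else:
        raise ValueError(f"unknown method {method!r}")
    return RBEResult(let_value=let_value, n_fractions=n_fractions, rbe=ratio,
                     se=se, cl90=cl, ed50_photon=photon.ed50, ed50_ion=ion.ed50)


def _fieller_ratio(x: float, sx: float, y: float, sy: float, z: float):
    """Fieller set for x/y with independent normal errors."""
    a = y * y - z * z * sy * sy
    b = -x * y
    c = x * x - z * z * sx * sx
    disc = b * b - a * c
    if a <= 0 or disc < 0:
        return (-math.inf, math.inf)
    root = math.sqrt(disc)
    return ((-b - root) / a, (-b + root) / a)


def let_trend(rbe_points: list[RBEResult], degree: int = 2) -> np.ndarray:
    """Inverse-variance weighted polynomial fit of RBE on LET.

    Returns coefficients highest power first (``numpy.polyval`` order).
    All points must share the fractionation schedule; >= degree+1
    distinct LET values are required.
    """
    if len({p.n_fractions for p in rbe_points}) > 1:
        raise ValueError("mixed schedules in one trend fit")
    x = np.array([p.let_value for p in rbe_points], float)
    y = np.array([p.rbe for p in rbe_points], float)
    w = np.array([1.0 / p.se if p.se > 0 else 1.0 for p in rbe_points], float)
    if len(np.unique(x)) < degree + 1:
        raise ValueError("rank-deficient design: too few distinct LET values")
    # numpy.polyfit weights multiply residuals, so w = 1/sigma
    return np.polyfit(x, y, degree, w=w)


def dose_interp(
    anchor_dose_per_fx: float,
    anchor_rbe: float,
    alpha_beta_ion: float,
    alpha_beta_photon: float,
    doses_per_fx: np.ndarray,
) -> np.ndarray:
    """RBE vs dose per fraction from the LQ iso-effect relation.

    The curve is anchored at a measured (dose-per-fraction, RBE) pair:
    iso-effect levels scale with the per-fraction BED-like quantity
    e(d) = d*(1 + d/ab).  For each requested ion fraction dose d the
    photon fraction dose d_x solves
    e_x(d_x) = k * e_i(d) with k fixed by the anchor, and RBE = d_x/d.
    As d -> 0 the curve tends to the anchored BED50 ratio (the maximum
    RBE) when anchored at the iso-effect level.
    """
    if anchor_dose_per_fx <= 0 or anchor_rbe <= 0:
        raise ValueError("anchor must be positive")
    if alpha_beta_ion <= 0 or alpha_beta_photon <= 0:
        raise ValueError("alpha/beta values must be positive")
    d = np.asarray(doses_per_fx, float)
    if np.any(d <= 0):
        raise ValueError("doses must be positive")

    def e_ion(dd):
        return dd * (1.0 + dd / alpha_beta_ion)

    def e_photon(dd):
        return dd * (1.0 + dd / alpha_beta_photon)

    dx_anchor = anchor_rbe * anchor_dose_per_fx
    k = e_photon(dx_anchor) / e_ion(anchor_dose_per_fx)
    # solve d_x (1 + d_x/ab_x) = k e_i(d):  d_x^2/ab_x + d_x - k e = 0
    ke = k * e_ion(d)
    dx = 0.5 * alpha_beta_photon * (-1.0 + np.sqrt(1.0 + 4.0 * ke / alpha_beta_photon))
    return dx / d
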