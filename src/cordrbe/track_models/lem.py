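"""Threshold-dose local-effect model, low-dose single-track approximation.

The amorphous track has a constant-dose core of radius ``r_min`` and a
1/r^2 penumbra out to ``r_max = track_coeff * E^track_exp``; the profile
is normalized so the radial integral equals 0.1602 * LET (Gy um^2).
The photon local-effect curve is LQ up to the threshold dose D_t and
continues linearly with slope s_max = alpha_x + 2 beta_x D_t beyond.
In the low-dose limit the ion alpha is the single-track lethal-event
yield divided by the single-track specific energy, and the ion beta
follows from the slope balance at the threshold dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .stopping import KEV_PER_UM_TO_GY_UM2, IonBeam

__all__ = ["PhotonLQ", "LEMParams", "radial_dose", "lem1_alpha_beta"]

QUAD_RTOL = 1e-8


@dataclass(frozen=True)
class PhotonLQ:
    """Photon LQ response with the threshold-dose linear continuation."""

    alpha_x: float  # 1/Gy
    beta_x: float  # 1/Gy^2
    d_t: float = 30.0  # Gy

    def __post_init__(self) -> None:
        if self.alpha_x < 0 or self.beta_x < 0:
            raise ValueError("alpha_x and beta_x must be >= 0")
        if self.d_t <= 0:
            raise ValueError("d_t must be positive")

    @property
    def s_max(self) -> float:
        return self.alpha_x + 2.0 * self.beta_x * self.d_t

    def lethal_events(self, dose):
        """-ln(survival) of the photon curve, linear above the threshold."""
        d = np.asarray(dose, float)
        below = self.alpha_x * d + self.beta_x * d * d
        at_t = self.alpha_x * self.d_t + self.beta_x * self.d_t ** 2
        above = at_t + self.s_max * (d - self.d_t)
        return np.where(d <= self.d_t, below, above)


@dataclass(frozen=True)
class LEMParams:
    r_min: float = 0.3  # um, inner track radius
    track_coeff: float = 0.05  # um / (MeV/u)^track_exp
    track_exp: float = 1.7
    nucleus_radius: float = 5.0  # um; placeholder, exposed in config

    def __post_init__(self) -> None:
        for name in ("r_min", "track_coeff", "track_exp", "nucleus_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def r_max(self, energy_mev_u: float) -> float:
        return self.track_coeff * energy_mev_u ** self.track_exp


def _track_lambda(beam: IonBeam, r_min: float, r_max: float) -> float:
    """Penumbra amplitude from the total-LET normalization.

    With D = lam/r_min^2 in the core and lam/r^2 in the penumbra,
    int D 2 pi r dr = pi lam (1 + 2 ln(r_max/r_min)) = 0.1602 * LET.
    """
    if r_max <= r_min:
        raise ValueError("r_max <= r_min: unsupported energy for this track model")
    total = KEV_PER_UM_TO_GY_UM2 * beam.let_value
    return total / (math.pi * (1.0 + 2.0 * math.log(r_max / r_min)))


def radial_dose(r, beam: IonBeam, params: LEMParams):
    """Local dose (Gy) at radius r (um) from the track axis."""
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    r_max = params.r_max(beam.energy)
    lam = _track_lambda(beam, params.r_min, r_max)
    with np.errstate(divide="ignore"):
        out = np.where(
            r <= params.r_min,
            lam / params.r_min ** 2,
            np.where(r <= r_max, lam / np.maximum(r, 1e-300) ** 2, 0.0),
        )
    return out if out.ndim else float(out)


def single_track_yield(
    beam: IonBeam,
    photon: PhotonLQ,
    params: LEMParams | None = None,
) -> float:
    """Radial integral of the local photon effect, int N_x(D(r)) 2 pi r dr."""
    params = params or LEMParams()
    r_min = params.r_min
    r_max = params.r_max(beam.energy)
    lam = _track_lambda(beam, r_min, r_max)

    def integrand(r: float) -> float:
        return float(photon.lethal_events(lam / (r * r))) * 2.0 * math.pi * r

    # core contributes a constant-dose disc
    core = float(photon.lethal_events(lam / r_min ** 2)) * math.pi * r_min ** 2

    # split the penumbra where the local dose crosses the threshold
    r_t = math.sqrt(lam / photon.d_t) if photon.d_t > 0 else r_min
    points = sorted({r_min, min(max(r_t, r_min), r_max), r_max})
    pen = 0.0
    for a, b in zip(points, points[1:]):
        if b > a:
            val, _ = integrate.quad(integrand, a, b, epsrel=QUAD_RTOL, limit=200)
            pen += val
    return core + pen


def lem1_alpha_beta(
    beam: IonBeam,
    photon: PhotonLQ,
    params: LEMParams | None = None,
    form: str = "poisson",
) -> tuple[float, float]:
    """Ion (alpha, beta) from the low-dose single-track approximation.

    With N_1 the mean lethal-event yield of one central traversal
    (single-track radial integral over the nucleus area A_n) and
    z_1 = 0.1602*LET/A_n the single-track specific energy:

    * ``form="poisson"`` (default): alpha_ion = (1 - exp(-N_1))/z_1,
      the per-traversal kill probability over the specific energy —
      bounded, and the source of the overkill turnover at very high
      LET where N_1 approaches 1;
    * ``form="linear"``: alpha_ion = N_1/z_1, the small-N_1 limit, in
      which A_n cancels and no turnover can occur.

    beta_ion = max(0, (s_max - alpha_ion) / (2 D_t)) from the slope
    balance at the threshold dose.
    """
    params = params or LEMParams()
    yield_integral = single_track_yield(beam, photon, params)
    area_n = math.pi * params.nucleus_radius ** 2
    z1 = KEV_PER_UM_TO_GY_UM2 * beam.let_value / area_n
    n1 = yield_integral / area_n
    if form == "linear":
        alpha_ion = n1 / z1
    elif form == "poisson":
        alpha_ion = -math.expm1(-n1) / z1
    else:
        raise ValueError(f"unknown form {form!r}")
    if alpha_ion > photon.s_max:
        raise ValueError(
            f"alpha_ion {alpha_ion:.3g} exceeds s_max {photon.s_max:.3g}; "
            "low-dose approximation invalid for this quality")
    beta_ion = max(0.0, (photon.s_max - alpha_ion) / (2.0 * photon.d_t))
    return float(alpha_ion), float(beta_ion)
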