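"""Iso-effect RBE prediction, mixed-field averaging and model comparison."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..rbe_stats import RBEResult
from .lem import PhotonLQ

__all__ = ["ModelPrediction", "predict_rbe", "mixed_field", "model_comparison"]


@dataclass(frozen=True)
class ModelPrediction:
    model_name: str  # {"LEM1", "mMKM", "external"}
    let_value: float
    n_fractions: int
    dose_per_fraction: float  # Gy, ion
    alpha_ion: float
    beta_ion: float
    rbe: float

    def __post_init__(self) -> None:
        if self.rbe <= 0:
            raise ValueError("rbe must be positive")
        if self.alpha_ion < 0:
            raise ValueError("alpha_ion must be >= 0")


def predict_rbe(
    alpha_ion: float,
    beta_ion: float,
    photon: PhotonLQ,
    dose_per_fraction: float,
    n_fractions: int = 1,
    let_value: float = 0.0,
    model_name: str = "external",
) -> ModelPrediction:
    """RBE at a given ion fraction dose from matched per-fraction effect.

    E = alpha_i d + beta_i d^2; the photon fraction dose producing the
    same effect is the positive root of beta_x d_x^2 + alpha_x d_x = E,
    and RBE = d_x / d (independent of n for equal per-fraction effect).
    """
    if dose_per_fraction <= 0:
        raise ValueError("dose_per_fraction must be positive")
    if photon.beta_x <= 0:
        raise ValueError("photon beta_x must be positive")
    if alpha_ion < 0 or beta_ion < 0:
        raise ValueError("ion LQ parameters must be >= 0")
    d = dose_per_fraction
    effect = alpha_ion * d + beta_ion * d * d
    disc = photon.alpha_x ** 2 + 4.0 * photon.beta_x * effect
    d_x = (-photon.alpha_x + math.sqrt(disc)) / (2.0 * photon.beta_x)
    return ModelPrediction(
        model_name=model_name,
        let_value=let_value,
        n_fractions=n_fractions,
        dose_per_fraction=d,
        alpha_ion=alpha_ion,
        beta_ion=beta_ion,
        rbe=d_x / d,
    )


def mixed_field(components: list[tuple[float, float, float]]) -> tuple[float, float]:
    """Dose-weighted LQ averaging over field components.

    ``components`` are (dose_weight, alpha_i, beta_i); weights must sum
    to 1.  alpha mixes linearly, sqrt(beta) mixes linearly.
    """
    if not components:
        raise ValueError("empty component list")
    w = np.array([c[0] for c in components], float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be >= 0 and sum to 1")
    alpha = np.array([c[1] for c in components], float)
    beta = np.array([c[2] for c in components], float)
    if np.any(beta < 0):
        raise ValueError("beta components must be >= 0")
    return float(w @ alpha), float((w @ np.sqrt(beta)) ** 2)


def model_comparison(
    measured: list[RBEResult],
    predicted: list[ModelPrediction],
    plateau_let: float = 26.0,
) -> pd.DataFrame:
    """Signed deviations (predicted - measured) per (LET, schedule, model).

    A prediction is flagged ``significant`` when it lies outside the
    measured 90% confidence limits.  Per model and schedule the table
    carries the plateau deviation and the mean +- SD over the remaining
    (in-SOBP) positions in the ``plateau_dev``/``sobp_mean``/``sobp_sd``
    columns (repeated on each matching row).
    """
    meas = {(m.let_value, m.n_fractions): m for m in measured}
    rows = []
    for p in predicted:
        key = (p.let_value, p.n_fractions)
        if key not in meas:
            raise KeyError(f"no measured RBE for (LET, nFx) = {key}")
        m = meas[key]
        dev = p.rbe - m.rbe
        lo, hi = m.cl90
        rows.append({
            "model": p.model_name,
            "let_value": p.let_value,
            "n_fractions": p.n_fractions,
            "rbe_measured": m.rbe,
            "rbe_predicted": p.rbe,
            "deviation": dev,
            "significant": bool(p.rbe < lo or p.rbe > hi),
        })
    df = pd.DataFrame(rows)
    for (model, nfx), sub in df.groupby(["model", "n_fractions"]):
        plateau = sub.loc[sub.let_value == plateau_let, "deviation"]
        sobp = sub.loc[sub.let_value != plateau_let, "deviation"]
        sel = (df.model == model) & (df.n_fractions == nfx)
        df.loc[sel, "plateau_dev"] = plateau.iloc[0] if len(plateau) else np.nan
        df.loc[sel, "sobp_mean"] = sobp.mean() if len(sobp) else np.nan
        df.loc[sel, "sobp_sd"] = sobp.std(ddof=1) if len(sobp) > 1 else np.nan
    return df
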