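"""Linear-quadratic BED and generalized logistic regression.

Schedules with different fraction numbers are placed on a common effect
scale through the biologically effective dose BED = D*(1 + d/(ab)) with
d = D/n.  A joint logistic law p = 1/(1+exp(-(g0 + g1*BED))) is fitted
across schedules with alpha/beta free; because alpha/beta is a positive
ratio parameter with a heavy right tail it is profiled on a log scale.
BED50 = -g0/g1 follows with delta-method SE and Fieller limits, and the
ratio of photon to ion BED50 gives the maximum RBE in the limit of
vanishing fractional dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .actuarial import DoseGroupSummary
from .dose_response import FiellerInterval, LogisticFit, fieller_cl

__all__ = [
    "LQFit",
    "BED50Result",
    "RBEmaxResult",
    "IdentifiabilityError",
    "bed",
    "fit_lq_logistic",
    "alpha_beta_from_ed50_pair",
    "bed50",
    "rbe_max",
]


class IdentifiabilityError(ValueError):
    """alpha/beta cannot be identified from the supplied design."""


@dataclass(frozen=True)
class LQFit:
    g0: float
    g1: float  # per Gy, on the BED axis
    alpha_beta: float  # Gy
    cov: np.ndarray  # 3x3 covariance of (g0, g1, alpha_beta)
    loglik: float

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be positive")


@dataclass(frozen=True)
class BED50Result:
    bed50: float
    se: float
    cl90: FiellerInterval


@dataclass(frozen=True)
class RBEmaxResult:
    rbe_max: float
    se: float
    cl90: tuple[float, float]


def bed(total_dose: float, n_fractions: int, alpha_beta: float) -> float:
    """BED = D * (1 + d/(alpha/beta)) with d = D/n; alpha_beta=inf gives D."""
    if total_dose < 0:
        raise ValueError("total_dose must be >= 0")
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be positive")
    if math.isinf(alpha_beta):
        return float(total_dose)
    d = total_dose / n_fractions
    return float(total_dose * (1.0 + d / alpha_beta))


def _neg_loglik(theta: np.ndarray, D: np.ndarray, nfx: np.ndarray,
                n: np.ndarray, r: np.ndarray) -> float:
    g0, g1, log_ab = theta
    ab = math.exp(log_ab)
    b = D * (1.0 + (D / nfx) / ab)
    eta = g0 + g1 * b
    return -float(np.sum(r * eta - n * np.logaddexp(0.0, eta)))


def _profile_fit_g(ab: float, D, nfx, n, r):
    """Newton fit of (g0, g1) at fixed alpha/beta; returns (g0, g1, loglik)."""
    from .dose_response import fit_logistic  # local import avoids cycle at module load

    b = D * (1.0 + (D / nfx) / ab)
    # reuse the 2-parameter machinery with BED as the covariate
    groups = [
        DoseGroupSummary("lq", 0.0, 1, float(bi), max(int(round(ni)), 1),
                         min(max(ri / ni if ni > 0 else 0.0, 0.0), 1.0),
                         0.0, float(ni), float(ri))
        for bi, ni, ri in zip(b, n, r)
    ]
    fit = fit_logistic(groups)
    return fit.b0, fit.b1, fit.loglik


def fit_lq_logistic(
    groups: list[DoseGroupSummary],
    ab_grid: np.ndarray | None = None,
) -> LQFit:
    """Joint logistic fit over schedules with alpha/beta free.

    Profiles the binomial log-likelihood over log(alpha/beta) on a grid,
    refines the optimum by bounded scalar minimization, and takes the
    covariance from the inverse observed information of the full
    3-parameter likelihood (transformed from the log scale).  Raises
    :class:`IdentifiabilityError` for single-schedule input or a flat
    profile.
    """
    if len({g.n_fractions for g in groups}) < 2:
        raise IdentifiabilityError("alpha/beta requires >= 2 distinct schedules")
    D = np.array([g.total_dose for g in groups], float)
    nfx = np.array([g.n_fractions for g in groups], float)
    n = np.array([g.n_eff for g in groups], float)
    r = np.array([g.r_eff for g in groups], float)

    if ab_grid is None:
        ab_grid = np.geomspace(0.5, 500.0, 61)
    profile = []
    for ab in ab_grid:
        try:
            g0, g1, ll = _profile_fit_g(ab, D, nfx, n, r)
        except Exception:
            ll = -np.inf
            g0 = g1 = np.nan
        profile.append((ll, ab, g0, g1))
    lls = np.array([p[0] for p in profile])
    if not np.any(np.isfinite(lls)):
        raise IdentifiabilityError("profile likelihood undefined everywhere")
    if np.nanmax(lls) - np.nanmin(lls[np.isfinite(lls)]) < 1e-7:
        raise IdentifiabilityError("profile likelihood flat in alpha/beta")
    k = int(np.nanargmax(lls))
    if k in (0, len(ab_grid) - 1):
        raise IdentifiabilityError(
            f"alpha/beta at grid boundary ({ab_grid[k]:.3g} Gy); design uninformative")

    # refine log(alpha/beta) between the neighbours of the grid optimum
    lo, hi = math.log(ab_grid[k - 1]), math.log(ab_grid[k + 1])

    def prof_nll(log_ab: float) -> float:
        _, _, ll = _profile_fit_g(math.exp(log_ab), D, nfx, n, r)
        return -ll

    res = optimize.minimize_scalar(prof_nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-9})
    log_ab = float(res.x)
    ab = math.exp(log_ab)
    g0, g1, ll = _profile_fit_g(ab, D, nfx, n, r)

    theta = np.array([g0, g1, log_ab])
    H = _hessian(lambda t: _neg_loglik(t, D, nfx, n, r), theta)
    try:
        cov_log = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise IdentifiabilityError("singular information matrix") from exc
    # transform log(alpha/beta) -> alpha/beta
    J = np.diag([1.0, 1.0, ab])
    cov = J @ cov_log @ J
    return LQFit(g0=float(g0), g1=float(g1), alpha_beta=ab, cov=cov, loglik=float(ll))


def _hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    k = len(x)
    steps = h * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * steps[i] * steps[j])
    return H


def alpha_beta_from_ed50_pair(ed50_1fx: float, ed50_2fx: float) -> float:
    """Closed-form alpha/beta from single- and split-dose iso-effect doses.

    Solves ED1*(1 + ED1/x) = ED2*(1 + (ED2/2)/x), i.e.
    x = (ED2^2/2 - ED1^2) / (ED1 - ED2).  Requires ED1 < ED2 < 2*ED1;
    ED2 >= 2*ED1 corresponds to the pure-alpha limit (x -> inf) or an
    incompatible pair and is rejected.
    """
    if not (0.0 < ed50_1fx < ed50_2fx):
        raise ValueError("need ed50_2fx > ed50_1fx > 0")
    if ed50_2fx >= 2.0 * ed50_1fx:
        raise ValueError("ed50_2fx >= 2*ed50_1fx: alpha/beta unbounded (pure-alpha limit)")
    x = (ed50_2fx ** 2 / 2.0 - ed50_1fx ** 2) / (ed50_1fx - ed50_2fx)
    if x <= 0:
        raise ValueError("incompatible ED50 pair (nonpositive alpha/beta)")
    return float(x)


def bed50(fit: LQFit, level: float = 0.90) -> BED50Result:
    """BED50 = -g0/g1 with delta SE (full 3x3 covariance) and Fieller CL.

    The Fieller construction runs on the (g0, g1) margin of the joint
    covariance, which already carries the alpha/beta-induced inflation
    of those coefficients.
    """
    if fit.g1 <= 0:
        raise ValueError("BED50 undefined for non-positive slope")
    est = -fit.g0 / fit.g1
    grad = np.array([-1.0 / fit.g1, fit.g0 / fit.g1 ** 2, 0.0])
    var = float(grad @ fit.cov @ grad)
    sub = LogisticFit(b0=fit.g0, b1=fit.g1, cov=fit.cov[:2, :2],
                      loglik=fit.loglik, groups_used=())
    return BED50Result(bed50=float(est), se=math.sqrt(max(var, 0.0)),
                       cl90=fieller_cl(sub, level))


def rbe_max(photon: BED50Result, ion: BED50Result, level: float = 0.90) -> RBEmaxResult:
    """Maximum RBE = photon BED50 / ion BED50, independent-ratio propagation."""
    if photon.bed50 <= 0 or ion.bed50 <= 0:
        raise ValueError("BED50 values must be positive")
    ratio = photon.bed50 / ion.bed50
    rel = math.sqrt((photon.se / photon.bed50) ** 2 + (ion.se / ion.bed50) ** 2)
    se = ratio * rel
    z = stats.norm.ppf(0.5 + level / 2.0)
    return RBEmaxResult(rbe_max=ratio, se=se, cl90=(ratio - z * se, ratio + z * se))
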