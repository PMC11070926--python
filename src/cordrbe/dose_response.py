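"""Maximum-likelihood logistic dose-response fitting and ED50 inference.

Fits p(D) = 1/(1 + exp(-(b0 + b1*D))) to actuarial response rates by
maximizing the fractional-count binomial likelihood (effective sample
sizes are non-integer), with a damped Newton iteration restarted from
moment-based initial values.  ED50 = -b0/b1 with a delta-method standard
error; 90% confidence limits by Fieller's theorem on the coefficient
covariance.  When the response pattern is completely separated (all-0
below all-1 with no intermediate group) the ML slope diverges and the
group midpoint with the 25%-of-gap fallback standard error is used
instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .actuarial import DoseGroupSummary

__all__ = [
    "LogisticFit",
    "ED50Result",
    "FiellerInterval",
    "SeparationError",
    "ConvergenceError",
    "fit_logistic",
    "ed50",
    "fieller_cl",
    "se_fallback",
    "ed50_from_groups",
    "latency_trend",
    "loglik_logistic",
]


class SeparationError(ValueError):
    """Complete separation: the ML slope is unbounded."""


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge after restarts."""


@dataclass(frozen=True)
class LogisticFit:
    b0: float
    b1: float  # per Gy
    cov: np.ndarray  # 2x2 covariance of (b0, b1)
    loglik: float
    groups_used: tuple[DoseGroupSummary, ...]

    def predict(self, dose):
        eta = self.b0 + self.b1 * np.asarray(dose, dtype=float)
        return expit(eta)


@dataclass(frozen=True)
class FiellerInterval:
    low: float
    high: float
    bounded: bool = True


@dataclass(frozen=True)
class ED50Result:
    ed50: float
    se: float
    cl90: FiellerInterval
    method: str = "delta"  # {"delta", "fallback"}


def loglik_logistic(b0: float, b1: float, doses, n_eff, r_eff) -> float:
    """Fractional-count binomial log-likelihood (up to the constant term)."""
    doses = np.asarray(doses, float)
    n = np.asarray(n_eff, float)
    r = np.asarray(r_eff, float)
    eta = b0 + b1 * doses
    # r*log p + (n-r)*log(1-p) written in the numerically stable form
    return float(np.sum(r * eta - n * np.logaddexp(0.0, eta)))


def _detect_separation(doses: np.ndarray, p: np.ndarray) -> bool:
    """True when the dose-sorted pattern is 0...0 1...1 with no fractional group."""
    if np.any((p > 0.0) & (p < 1.0)):
        return False
    order = np.argsort(doses)
    ps = p[order]
    if 0.0 not in ps or 1.0 not in ps:
        return False
    first_one = int(np.argmax(ps == 1.0))
    return bool(np.all(ps[:first_one] == 0.0) and np.all(ps[first_one:] == 1.0))


def fit_logistic(
    groups: list[DoseGroupSummary],
    max_iter: int = 200,
    grad_tol: float = 1e-8,
    covariate: str = "dose",
) -> LogisticFit:
    """ML logistic fit to per-group actuarial rates.

    ``covariate`` may be ``"dose"`` (default, the axis on which ED50 and
    the fallback rule are defined) or ``"log_dose"``.
    """
    if len({g.total_dose for g in groups}) < 2:
        raise ValueError("need >= 2 distinct dose levels")
    doses = np.array([g.total_dose for g in groups], float)
    if covariate == "log_dose":
        if np.any(doses <= 0):
            raise ValueError("log-dose covariate requires positive doses")
        x = np.log(doses)
    elif covariate == "dose":
        x = doses
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    n = np.array([g.n_eff for g in groups], float)
    r = np.array([g.r_eff for g in groups], float)
    if np.any(n < 0) or np.any(r < 0) or np.any(r > n + 1e-9):
        raise ValueError("invalid effective counts")

    if _detect_separation(x, np.where(n > 0, r / np.maximum(n, 1e-300), 0.0)):
        raise SeparationError("complete separation: all-0 doses below all-1 doses")

    X = np.column_stack([np.ones_like(x), x])

    def newton(beta: np.ndarray):
        ll = loglik_logistic(beta[0], beta[1], x, n, r)
        for _ in range(max_iter):
            eta = X @ beta
            p = expit(eta)
            grad = X.T @ (r - n * p)
            if np.linalg.norm(grad) < grad_tol:
                return beta, ll, True
            w = n * p * (1.0 - p)
            H = X.T @ (X * w[:, None])
            try:
                step = np.linalg.solve(H + 1e-12 * np.eye(2), grad)
            except np.linalg.LinAlgError:
                return beta, ll, False
            # damped update: halve until the likelihood improves
            lam = 1.0
            for _ in range(40):
                cand = beta + lam * step
                ll_new = loglik_logistic(cand[0], cand[1], x, n, r)
                if ll_new >= ll - 1e-12:
                    beta, ll = cand, ll_new
                    break
                lam *= 0.5
            else:
                return beta, ll, False
        return beta, ll, False

    # moment start: weighted linear fit of the empirical logit
    p_adj = (r + 0.5) / (n + 1.0)
    z = np.log(p_adj / (1.0 - p_adj))
    A = np.column_stack([np.ones_like(x), x])
    beta0, *_ = np.linalg.lstsq(A, z, rcond=None)
    starts = [beta0, np.array([0.0, 0.0]),
              np.array([beta0[0] * 0.5, max(beta0[1], 0.1)])]
    best = None
    for s in starts:
        beta, ll, ok = newton(np.asarray(s, float))
        if ok and (best is None or ll > best[1]):
            best = (beta, ll)
    if best is None:
        raise ConvergenceError("logistic fit did not converge from any start")
    beta, ll = best

    eta = X @ beta
    p = expit(eta)
    w = n * p * (1.0 - p)
    H = X.T @ (X * w[:, None])
    cov = np.linalg.inv(H)
    return LogisticFit(b0=float(beta[0]), b1=float(beta[1]), cov=cov,
                       loglik=ll, groups_used=tuple(groups))


def ed50(fit: LogisticFit, level: float = 0.90) -> ED50Result:
    """ED50 = -b0/b1 with delta-method SE and Fieller confidence limits."""
    if fit.b1 <= 0:
        raise ValueError("ED50 undefined for non-positive slope")
    est = -fit.b0 / fit.b1
    grad = np.array([-1.0 / fit.b1, fit.b0 / fit.b1 ** 2])
    var = float(grad @ fit.cov @ grad)
    se = math.sqrt(max(var, 0.0))
    return ED50Result(ed50=est, se=se, cl90=fieller_cl(fit, level), method="delta")


def fieller_cl(fit: LogisticFit, level: float = 0.90) -> FiellerInterval:
    """Fieller confidence limits for the ratio -b0/b1.

    Roots of (b0 + rho*b1)^2 = z^2 (v00 + 2 rho v01 + rho^2 v11).  A
    negative leading coefficient or discriminant means the set is
    unbounded; the interval is then flagged rather than fabricated.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    v00, v01, v11 = fit.cov[0, 0], fit.cov[0, 1], fit.cov[1, 1]
    a = fit.b1 ** 2 - z * z * v11
    b = fit.b0 * fit.b1 - z * z * v01
    c = fit.b0 ** 2 - z * z * v00
    disc = b * b - a * c
    if a <= 0 or disc < 0:
        return FiellerInterval(-math.inf, math.inf, bounded=False)
    root = math.sqrt(disc)
    lo = (-b - root) / a
    hi = (-b + root) / a
    return FiellerInterval(min(lo, hi), max(lo, hi), bounded=True)


def se_fallback(groups: list[DoseGroupSummary]) -> float:
    """25% of the dose gap between adjacent 0% and 100% response levels.

    Requires a dose-sorted pattern containing a direct 0 -> 1 jump.
    """
    ordered = sorted(groups, key=lambda g: g.total_dose)
    for lo, hi in zip(ordered, ordered[1:]):
        if lo.p_actuarial == 0.0 and hi.p_actuarial == 1.0:
            return 0.25 * (hi.total_dose - lo.total_dose)
    raise ValueError("no adjacent 0% and 100% response levels")


def ed50_from_groups(groups: list[DoseGroupSummary], level: float = 0.90) -> ED50Result:
    """ED50 with automatic fallback on complete separation.

    Separated patterns give the midpoint of the 0 -> 1 dose gap, the
    25%-of-gap SE and a normal-approximation interval flagged as the
    fallback method.
    """
    try:
        fit = fit_logistic(groups)
        return ed50(fit, level)
    except SeparationError:
        ordered = sorted(groups, key=lambda g: g.total_dose)
        for lo, hi in zip(ordered, ordered[1:]):
            if lo.p_actuarial == 0.0 and hi.p_actuarial == 1.0:
                mid = 0.5 * (lo.total_dose + hi.total_dose)
                se = 0.25 * (hi.total_dose - lo.total_dose)
                z = stats.norm.ppf(0.5 + level / 2.0)
                return ED50Result(ed50=mid, se=se,
                                  cl90=FiellerInterval(mid - z * se, mid + z * se),
                                  method="fallback")
        raise


def latency_trend(points: list[tuple[float, float]]) -> tuple[float, float]:
    """OLS slope of latency (days) on LET with a two-sided zero-slope test.

    Returns ``(slope, p_value)``.  Constant latencies give slope 0 and
    p = 1 rather than an undefined test statistic.
    """
    if len(points) < 3:
        raise ValueError("need >= 3 points")
    x = np.array([p[0] for p in points], float)
    y = np.array([p[1] for p in points], float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate LET values")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)
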