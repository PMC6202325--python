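"""Survival analysis from first principles.

Implements the product-limit (Kaplan-Meier) estimator with Greenwood
variance and log-log confidence intervals, the Mantel-Haenszel log-rank
test, Cox proportional-hazards regression by Newton-Raphson on the partial
likelihood (Efron tie handling by default, Breslow by flag), and the
Schoenfeld required-events formula for log-rank sample-size planning:

    d = (z_{1-alpha/2} + z_{1-beta})^2 / (p (1-p) (ln HR)^2)

with p the exposed fraction.  The required cohort size for an expected
event rate r is ceil(d / r).

These routines are self-contained on purpose; external survival packages
appear in this code base only as independent test oracles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalError",
    "KaplanMeierResult",
    "CoxResult",
    "km_estimate",
    "log_rank",
    "cox_fit",
    "required_events",
    "required_sample",
]

NOT_REACHED = float("inf")


class SurvivalError(ValueError):
    pass


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class KaplanMeierResult:
    """Product-limit estimate: step function plus median and its 95% CI.

    ``times``/``survival`` give S(t) immediately after each distinct event
    time; medians that the curve never crosses are ``inf`` ("not reached").
    """

    times: np.ndarray
    survival: np.ndarray
    std_err: np.ndarray        # Greenwood standard error of S(t)
    at_risk: np.ndarray
    events: np.ndarray
    median: float
    median_ci: tuple[float, float]

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass(frozen=True)
class CoxResult:
    covariates: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    wald_p: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    iterations: int
    monotone_likelihood: bool

    @property
    def likelihood_ratio(self) -> float:
        return 2.0 * (self.log_likelihood - self.null_log_likelihood)


def _validate(time: Sequence[float], event: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise SurvivalError("no samples")
    if time.shape != event.shape:
        raise SurvivalError("time and event must have equal length")
    if np.any(time < 0) or not np.all(np.isfinite(time)):
        raise SurvivalError("times must be finite and non-negative")
    return time, event


def km_estimate(
    time: Sequence[float], event: Sequence[bool], conf_level: float = 0.95
) -> KaplanMeierResult:
    """Kaplan-Meier product-limit estimator.

    The median is the earliest time with S(t) <= 0.5 (``inf`` if never
    reached); its CI is read off the log-log (Brookmeyer-Crowley style)
    pointwise confidence band.
    """
    time, event = _validate(time, event)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    event_times = np.unique(time[event])
    n = len(time)
    s = 1.0
    var_sum = 0.0
    times, surv, se_list, risk, dts = [], [], [], [], []
    for t in event_times:
        n_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & event))
        s *= 1.0 - d / n_risk
        if n_risk > d:
            var_sum += d / (n_risk * (n_risk - d))
        se = s * math.sqrt(var_sum) if s > 0 else 0.0
        times.append(t)
        surv.append(s)
        se_list.append(se)
        risk.append(n_risk)
        dts.append(d)

    times_a = np.array(times)
    surv_a = np.array(surv)
    se_a = np.array(se_list)

    median = _first_crossing(times_a, surv_a, 0.5)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    lo_band, hi_band = _loglog_band(surv_a, se_a, z)
    # Brookmeyer-Crowley: CI for the median from where the bands cross 0.5
    median_lo = _first_crossing(times_a, hi_band, 0.5)
    median_hi = _first_crossing(times_a, lo_band, 0.5)
    return KaplanMeierResult(
        times=times_a, survival=surv_a, std_err=se_a,
        at_risk=np.array(risk), events=np.array(dts),
        median=median, median_ci=(median_lo, median_hi),
    )


def _first_crossing(times: np.ndarray, surv: np.ndarray, level: float) -> float:
    below = surv <= level + 1e-12
    if not below.any():
        return NOT_REACHED
    return float(times[np.argmax(below)])


def _loglog_band(surv: np.ndarray, se: np.ndarray, z: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.full_like(surv, np.nan)
    hi = np.full_like(surv, np.nan)
    for i, (s, e) in enumerate(zip(surv, se)):
        if 0 < s < 1 and e > 0:
            theta = z * e / (s * abs(math.log(s)))
            lo[i] = s ** math.exp(theta)
            hi[i] = s ** math.exp(-theta)
        else:
            lo[i] = hi[i] = s
    return lo, hi


def log_rank(
    time: Sequence[float], event: Sequence[bool], group: Sequence[bool]
) -> tuple[float, float]:
    """Two-group Mantel-Haenszel log-rank test.

    Returns ``(chi_square, p)`` with 1 degree of freedom:
    U = sum over event times of (observed - expected) events in group 1,
    V the sum of hypergeometric variances, statistic U^2 / V.
    """
    time, event = _validate(time, event)
    group = np.asarray(group, dtype=bool)
    if group.all() or (~group).all():
        raise SurvivalError("log-rank needs two non-empty groups")
    if not event.any():
        raise SurvivalError("log-rank needs at least one event")
    u = 0.0
    v = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        d = int((event & (time == t)).sum())
        d1 = int((event & (time == t) & group).sum())
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0, 1.0
    stat = u * u / v
    return float(stat), float(stats.chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _cox_loglik(
    beta: np.ndarray, time: np.ndarray, event: np.ndarray, x: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, score vector and information matrix."""
    eta = x @ beta
    # clip to keep exp finite under monotone likelihood
    theta = np.exp(np.clip(eta, -500, 500))
    p = x.shape[1]
    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    order = np.argsort(-time, kind="stable")  # descending time for risk-set sums
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    nobs = len(time)
    while i < nobs:
        t = time[order[i]]
        # absorb everyone entering the risk set at this time
        j = i
        while j < nobs and time[order[j]] == t:
            k = order[j]
            s0 += theta[k]
            s1 += theta[k] * x[k]
            s2 += theta[k] * np.outer(x[k], x[k])
            j += 1
        deaths = [order[m] for m in range(i, j) if event[order[m]]]
        d = len(deaths)
        if d:
            xd = x[deaths]
            td = theta[deaths]
            sum_xd = xd.sum(axis=0)
            loglik += float((xd @ beta).sum())
            if ties == "breslow" or d == 1:
                loglik -= d * math.log(s0)
                score += sum_xd - d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
            else:  # efron
                td_sum = td.sum()
                s1_d = (td[:, None] * xd).sum(axis=0)
                s2_d = np.einsum("i,ij,ik->jk", td, xd, xd)
                score += sum_xd
                for m in range(d):
                    f = m / d
                    denom = s0 - f * td_sum
                    num1 = s1 - f * s1_d
                    num2 = s2 - f * s2_d
                    loglik -= math.log(denom)
                    score -= num1 / denom
                    info += num2 / denom - np.outer(num1 / denom, num1 / denom)
        i = j
    return loglik, score, info


def cox_fit(
    time: Sequence[float],
    event: Sequence[bool],
    covariates: np.ndarray | Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
    conf_level: float = 0.95,
) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson on the partial likelihood.

    Efron tie handling by default (``ties="breslow"`` available).
    Convergence when the max absolute score component drops below ``tol``;
    a monotone likelihood (perfect separation) is flagged and the clipped
    coefficients returned with a warning rather than an error.
    """
    time, event = _validate(time, event)
    if not event.any():
        raise SurvivalError("Cox fit needs at least one event")
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != len(time):
        x = x.T
    if x.shape[0] != len(time):
        raise SurvivalError("covariate matrix does not match sample count")
    p = x.shape[1]
    for j in range(p):
        if np.all(x[:, j] == x[0, j]):
            raise SurvivalError(f"covariate {j} is constant (non-identifiable)")
    if ties not in ("efron", "breslow"):
        raise SurvivalError(f"unknown tie method {ties!r}")
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    names = tuple(names)

    # center covariates for numerical stability; slopes are unchanged
    x_mean = x.mean(axis=0)
    xc = x - x_mean

    beta = np.zeros(p)
    null_loglik, _, _ = _cox_loglik(beta, time, event, xc, ties)
    loglik = null_loglik
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        loglik, score, info = _cox_loglik(beta, time, event, xc, ties)
        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SurvivalError("singular information matrix") from exc
        # step-halving to keep the likelihood non-decreasing
        new_beta = beta + step
        new_ll, _, _ = _cox_loglik(new_beta, time, event, xc, ties)
        halvings = 0
        while new_ll < loglik and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, _, _ = _cox_loglik(new_beta, time, event, xc, ties)
            halvings += 1
        beta = new_beta
        if np.max(np.abs(beta)) > 15:  # |HR| beyond ~3e6: separated
            monotone = True
            warnings.warn(
                "monotone partial likelihood (perfect separation); "
                "coefficients are unreliable",
                ConvergenceWarning,
                stacklevel=2,
            )
            break
        # no numerically meaningful improvement left: stop and let the
        # final score check below decide whether this counts as converged
        if abs(new_ll - loglik) < 1e-10 * (1.0 + abs(loglik)):
            break
    else:
        raise SurvivalError(f"Cox fit did not converge in {max_iter} iterations")
    if not monotone:
        _, final_score, _ = _cox_loglik(beta, time, event, xc, ties)
        if np.max(np.abs(final_score)) > 1e-4 * (1.0 + abs(loglik)):
            raise SurvivalError(
                f"Cox fit stalled with score {np.max(np.abs(final_score)):.3g}"
            )

    loglik, score, info = _cox_loglik(beta, time, event, xc, ties)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SurvivalError("singular information matrix at optimum") from exc
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    with np.errstate(over="ignore"):
        hr = np.exp(beta)
        lo = np.exp(beta - z * se)
        hi = np.exp(beta + z * se)
    wald = np.where(se > 0, 2 * stats.norm.sf(np.abs(beta) / np.where(se > 0, se, 1.0)), np.nan)
    return CoxResult(
        covariates=names, coef=beta, se=se, hazard_ratio=hr,
        ci_lower=lo, ci_upper=hi, wald_p=wald,
        log_likelihood=float(loglik), null_log_likelihood=float(null_loglik),
        iterations=it, monotone_likelihood=monotone,
    )


def cox_score_test(
    time: Sequence[float], event: Sequence[bool], covariates, ties: str = "breslow"
) -> float:
    """Score (Rao) test statistic at beta = 0; equals the log-rank statistic
    for a single binary covariate on tie-free data."""
    time, event = _validate(time, event)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != len(time):
        x = x.T
    _, score, info = _cox_loglik(np.zeros(x.shape[1]), time, event, x, ties)
    return float(score @ np.linalg.solve(info, score))


# ---------------------------------------------------------------------------
# Sample-size planning


def required_events(
    alpha: float, power: float, exposed_fraction: float, hazard_ratio: float
) -> int:
    """Schoenfeld required number of events for a two-sided log-rank test.

    d = (z_{1-alpha/2} + z_{1-beta})^2 / (p (1-p) (ln HR)^2), rounded to
    the nearest integer.
    """
    if not (0 < exposed_fraction < 1):
        raise SurvivalError("exposed fraction must be in (0, 1)")
    if hazard_ratio <= 0 or hazard_ratio == 1.0:
        raise SurvivalError("hazard ratio must be positive and != 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise SurvivalError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    p = exposed_fraction
    d = (z_a + z_b) ** 2 / (p * (1 - p) * math.log(hazard_ratio) ** 2)
    return int(math.floor(d + 0.5))  # round half-up


def required_sample(events: int, event_rate: float) -> int:
    """Cohort size needed to observe ``events`` events: ceil(events / rate)."""
    if not (0 < event_rate <= 1):
        raise SurvivalError("event rate must be in (0, 1]")
    if events <= 0:
        raise SurvivalError("events must be positive")
    return math.ceil(events / event_rate)
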