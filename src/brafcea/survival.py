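"""Parametric progression-free survival laws and the published-curve fitting stage.

Two parameterizations are used throughout and are worth stating explicitly,
because parameterization drift is the single most common way to mis-reproduce
a survival-extrapolation exercise:

* Weibull (proportional-hazards form)::

      S(t) = exp(-lam * t**kappa),      h(t) = lam * kappa * t**(kappa - 1)

  ``lam`` has units of month^-kappa; ``kappa`` is dimensionless.  This is the
  form reported by Stata's ``streg, distribution(weibull)`` and is NOT the
  scale/shape form used by ``scipy.stats.weibull_min`` or lifelines
  (``S(t) = exp(-(t/scale)**shape)``); the conversion is
  ``lam = scale**(-shape)``, ``kappa = shape``.

* Gompertz::

      S(t) = exp(-(lam/gamma) * (exp(gamma*t) - 1)),   h(t) = lam * exp(gamma*t)

  ``lam`` is the baseline hazard per month; ``gamma`` (per month) may be
  negative, in which case the hazard decays and the survival function has a
  non-zero plateau ``lim_{t->inf} S(t) = exp(lam/gamma)``.

A hazard ratio ``hr`` is applied on the cumulative-hazard scale,
``S_adj(t) = S_base(t)**hr`` (proportional hazards).

The module also provides the pipeline that turns a published Kaplan-Meier
curve plus its numbers-at-risk table into pseudo individual-patient data
(the Guyot interval algorithm) and fits a parametric family to those data by
right-censored maximum likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
from scipy import optimize

__all__ = [
    "WeibullLaw",
    "GompertzLaw",
    "ExponentialLaw",
    "HazardRatioAdjusted",
    "SurvivalLaw",
    "KMCurve",
    "PseudoIPD",
    "FitResult",
    "survival_at",
    "cycle_transition_prob",
    "reconstruct_ipd",
    "fit_parametric",
]

log = logging.getLogger(__name__)


def _check_finite(**params: float) -> None:
    for name, value in params.items():
        if not math.isfinite(value):
            raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


@dataclass(frozen=True)
class WeibullLaw:
    """Weibull law in proportional-hazards form, S(t) = exp(-lam * t**kappa)."""

    lam: float
    kappa: float

    def __post_init__(self) -> None:
        _check_finite(lam=self.lam, kappa=self.kappa)
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError(f"Weibull requires lam > 0 and kappa > 0, got {self}")

    def survival(self, t):
        t = _validate_times(t)
        return np.exp(-self.lam * np.power(t, self.kappa))

    def median(self) -> float:
        return (math.log(2.0) / self.lam) ** (1.0 / self.kappa)

    def log_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return math.log(self.lam * self.kappa) + (self.kappa - 1.0) * np.log(t)


@dataclass(frozen=True)
class ExponentialLaw:
    """Constant-hazard law, S(t) = exp(-lam * t); the kappa = 1 Weibull."""

    lam: float

    def __post_init__(self) -> None:
        _check_finite(lam=self.lam)
        if self.lam <= 0:
            raise ValueError(f"Exponential requires lam > 0, got {self}")

    def survival(self, t):
        t = _validate_times(t)
        return np.exp(-self.lam * t)

    def median(self) -> float:
        return math.log(2.0) / self.lam

    def log_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return np.full_like(t, math.log(self.lam))


@dataclass(frozen=True)
class GompertzLaw:
    """Gompertz law, S(t) = exp(-(lam/gamma) * (exp(gamma*t) - 1)).

    gamma < 0 gives a decaying hazard and a survival plateau exp(lam/gamma);
    gamma -> 0 degenerates smoothly to the exponential law (handled via expm1).
    """

    lam: float
    gamma: float

    def __post_init__(self) -> None:
        _check_finite(lam=self.lam, gamma=self.gamma)
        if self.lam <= 0:
            raise ValueError(f"Gompertz requires lam > 0, got {self}")

    def survival(self, t):
        t = _validate_times(t)
        if abs(self.gamma) < 1e-12:
            return np.exp(-self.lam * t)
        # -(lam/gamma) * expm1(gamma * t), stable for gamma of either sign
        return np.exp(-(self.lam / self.gamma) * np.expm1(self.gamma * t))

    def plateau(self) -> float:
        """lim_{t->inf} S(t); 0 unless gamma < 0."""
        if self.gamma < 0:
            return math.exp(self.lam / self.gamma)
        return 0.0

    def log_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return math.log(self.lam) + self.gamma * t


@dataclass(frozen=True)
class HazardRatioAdjusted:
    """A base law with a hazard ratio applied on the cumulative-hazard scale.

    S_adj(t) = S_base(t)**hr, so hr = 1 reproduces the base law exactly.  The
    95% CI bounds travel with the point estimate for sensitivity analyses.
    """

    base: "SurvivalLaw"
    hr: float
    hr_low: float | None = None
    hr_high: float | None = None

    def __post_init__(self) -> None:
        _check_finite(hr=self.hr)
        if self.hr <= 0:
            raise ValueError(f"hazard ratio must be > 0, got {self.hr}")

    def survival(self, t):
        return np.power(self.base.survival(t), self.hr)

    def log_hazard(self, t):
        return math.log(self.hr) + self.base.log_hazard(t)


SurvivalLaw = Union[WeibullLaw, ExponentialLaw, GompertzLaw, HazardRatioAdjusted]


def _validate_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival time must be >= 0")
    return t


def survival_at(law: SurvivalLaw, t) -> np.ndarray | float:
    """Evaluate S(t) for any supported law; scalar in, scalar out."""
    out = law.survival(t)
    return float(out) if np.ndim(out) == 0 else out


def cycle_transition_prob(law: SurvivalLaw, cycle_index, cycle_len: float = 1.0):
    """Per-cycle event probability conditional on being event-free at cycle start.

    p_k = 1 - S((k+1)*dt) / S(k*dt) with k the cycle index counted on the
    *time-in-state* clock (each treatment line runs its own clock).  Accepts a
    scalar or an array of cycle indices.  Where S(k*dt) has underflowed to
    zero the state is fully absorbed and p = 1 is returned with a warning.
    """
    k = np.asarray(cycle_index)
    if np.any(k < 0):
        raise ValueError("cycle_index must be >= 0")
    if cycle_len <= 0:
        raise ValueError("cycle_len must be > 0")
    s0 = np.asarray(law.survival(k * cycle_len), dtype=float)
    s1 = np.asarray(law.survival((k + 1) * cycle_len), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - np.where(s0 > 0, s1 / np.where(s0 > 0, s0, 1.0), 0.0)
    if np.any(s0 == 0):
        log.warning("survival underflowed to 0 at cycle start; treating state as absorbed")
        p = np.where(s0 == 0, 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.ndim(cycle_index) == 0 else p


# ---------------------------------------------------------------------------
# Published-curve stage: KM curve -> pseudo-IPD -> parametric fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KMCurve:
    """A digitized Kaplan-Meier curve with its numbers-at-risk table."""

    times: np.ndarray
    surv: np.ndarray
    risk_times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "surv", np.asarray(self.surv, dtype=float))
        object.__setattr__(self, "risk_times", np.asarray(self.risk_times, dtype=float))
        object.__setattr__(self, "n_at_risk", np.asarray(self.n_at_risk, dtype=int))
        if self.times.shape != self.surv.shape:
            raise ValueError("times and surv must have equal length")
        if self.times[0] != 0 or self.surv[0] != 1.0:
            raise ValueError("curve must start at (t=0, S=1)")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")
        if np.any(np.diff(self.surv) > 1e-12):
            raise ValueError("survival must be nonincreasing")
        if np.any((self.surv < 0) | (self.surv > 1)):
            raise ValueError("survival must lie in [0, 1]")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ValueError("numbers at risk must be nonincreasing")
        if np.any(self.n_at_risk < 0):
            raise ValueError("numbers at risk must be nonnegative")


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed individual-level (time, event) records."""

    time: np.ndarray
    event: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "event", np.asarray(self.event, dtype=int))
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


def reconstruct_ipd(km: KMCurve) -> PseudoIPD:
    """Rebuild pseudo individual-patient data from a KM curve and risk table.

    Interval-by-interval solution in the style of Guyot et al.: within each
    risk-table interval, censoring is assumed uniform, the number censored is
    solved so that the implied number at risk at the next risk-table time
    matches the published count, and event counts are chosen so the recomputed
    product-limit estimator tracks the published survival probabilities.
    """
    if len(km.risk_times) < 2:
        raise ValueError("risk table must have at least 2 entries")

    t_pub = km.times
    s_pub = km.surv
    records_t: list[float] = []
    records_e: list[int] = []

    n_risk = int(km.n_at_risk[0])
    s_model = 1.0  # running KM estimate carried across intervals

    # Risk-table intervals (risk_times[j], risk_times[j+1]]; the final interval
    # extends to the end of published follow-up, where survivors are censored.
    bounds = list(map(float, km.risk_times))
    bounds.append(max(bounds[-1], float(t_pub[-1])) + 1e-9)
    for j in range(len(km.risk_times)):
        lo, hi = bounds[j], bounds[j + 1]
        target = int(km.n_at_risk[j + 1]) if j + 1 < len(km.n_at_risk) else None
        in_iv = (t_pub > lo) & (t_pub <= hi)
        iv_times = t_pub[in_iv]
        iv_surv = s_pub[in_iv]

        ev_alloc, cens_times, s_model, n_risk = _solve_interval(
            lo, hi, n_risk, target, iv_times, iv_surv, s_model
        )
        for tt, d in ev_alloc:
            records_t.extend([tt] * d)
            records_e.extend([1] * d)
        records_t.extend(cens_times.tolist())
        records_e.extend([0] * len(cens_times))

    if n_risk > 0:  # survivors past the last published time: administrative censoring
        records_t.extend([bounds[-1]] * n_risk)
        records_e.extend([0] * n_risk)

    return PseudoIPD(
        np.asarray(records_t), np.asarray(records_e), meta={"source": "reconstruct_ipd"}
    )


def _solve_interval(lo, hi, n_start, target, iv_times, iv_surv, s_entry):
    """Solve one risk-table interval for event and censor counts.

    The number censored in the interval is iterated until the implied number
    at risk at the interval end matches the published ``target``; censor times
    are spread uniformly and interleaved with the published event times when
    counting the risk set.  ``target is None`` marks the final interval, where
    no constraint applies and residual censoring happens at end of follow-up.
    """
    nc = 0 if target is None else max(0, n_start - target)
    for _ in range(40):
        ct = (
            lo + (np.arange(1, nc + 1) - 0.5) / nc * (hi - lo)
            if nc > 0
            else np.empty(0)
        )
        n = n_start
        s_run = s_entry
        ci = 0
        ev_alloc: list[tuple[float, int]] = []
        for tt, ss in zip(iv_times, iv_surv):
            while ci < nc and ct[ci] < tt:
                n -= 1
                ci += 1
            if n <= 0 or s_run <= 0:
                break
            d = int(round(n * (1.0 - ss / s_run)))
            d = max(0, min(d, n))
            if d > 0:
                s_run *= 1.0 - d / n
                n -= d
                ev_alloc.append((float(tt), d))
        n -= nc - ci  # censors after the last event in the interval
        if target is None:
            return ev_alloc, ct, s_run, n
        diff = n - target
        if diff == 0:
            return ev_alloc, ct, s_run, target
        nc = int(max(0, min(nc + diff, n_start)))
    log.warning(
        "risk-table constraint not met exactly on (%g, %g]: implied %d vs published %d",
        lo,
        hi,
        n,
        target,
    )
    return ev_alloc, ct, s_run, target


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting under right censoring
# ---------------------------------------------------------------------------

Family = Literal["weibull", "gompertz", "exponential"]


@dataclass(frozen=True)
class FitResult:
    law: SurvivalLaw
    family: str
    log_likelihood: float
    aic: float
    n_params: int
    converged: bool
    message: str = ""


def _neg_loglik(theta: np.ndarray, family: str, t: np.ndarray, e: np.ndarray) -> float:
    # log L = sum_i [ e_i * log h(t_i) + log S(t_i) ]
    if family == "weibull":
        lam, kappa = math.exp(theta[0]), math.exp(theta[1])
        log_h = math.log(lam * kappa) + (kappa - 1.0) * np.log(t)
        log_s = -lam * np.power(t, kappa)
    elif family == "exponential":
        lam = math.exp(theta[0])
        log_h = np.full_like(t, math.log(lam))
        log_s = -lam * t
    elif family == "gompertz":
        lam, gamma = math.exp(theta[0]), theta[1]
        log_h = math.log(lam) + gamma * t
        if abs(gamma) < 1e-12:
            log_s = -lam * t
        else:
            log_s = -(lam / gamma) * np.expm1(gamma * t)
    else:  # pragma: no cover - guarded by caller
        raise ValueError(family)
    ll = float(np.sum(e * log_h + log_s))
    return -ll if math.isfinite(ll) else 1e300


def fit_parametric(ipd: PseudoIPD, family: Family) -> FitResult:
    """Fit a parametric survival family to right-censored data by ML.

    Raises ``ValueError`` for degenerate inputs (fewer than 10 records or no
    events).  Non-convergence of the optimizer is reported through the
    ``converged`` flag and message, never silently swallowed.
    """
    if family not in ("weibull", "gompertz", "exponential"):
        raise ValueError(f"unknown family {family!r}")
    if len(ipd) < 10:
        raise ValueError("need at least 10 records to fit")
    if ipd.n_events < 1:
        raise ValueError("need at least 1 event to fit")

    t = np.maximum(ipd.time, 1e-9)
    e = ipd.event.astype(float)

    # moment-style initial values: exponential rate = events / person-time
    rate0 = max(ipd.n_events / float(t.sum()), 1e-8)
    if family == "exponential":
        x0 = np.array([math.log(rate0)])
    elif family == "weibull":
        x0 = np.array([math.log(rate0), 0.0])
    else:
        x0 = np.array([math.log(rate0), 0.0])

    res = optimize.minimize(
        _neg_loglik,
        x0,
        args=(family, t, e),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-6, "maxiter": 5000},
    )
    theta = res.x
    if family == "weibull":
        law: SurvivalLaw = WeibullLaw(math.exp(theta[0]), math.exp(theta[1]))
        k = 2
    elif family == "exponential":
        law = ExponentialLaw(math.exp(theta[0]))
        k = 1
    else:
        law = GompertzLaw(math.exp(theta[0]), theta[1])
        k = 2
    ll = -res.fun
    return FitResult(
        law=law,
        family=family,
        log_likelihood=ll,
        aic=2 * k - 2 * ll,
        n_params=k,
        converged=bool(res.success),
        message=str(res.message),
    )
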