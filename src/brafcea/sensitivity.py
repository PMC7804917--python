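"""Sensitivity and uncertainty analyses around the base-case ICER.

* **One-way (tornado)**: every registered parameter with a printed range is
  set to its low and high bound in turn (all else at base) and the full model
  is rerun; entries whose ICER span exceeds $5,000/QALY make the tornado.
* **Probabilistic (PSA)**: parameters are drawn jointly and independently —
  gamma for costs, beta for probabilities and the utility, log-normal for the
  progression hazard ratio — and the model is rerun per draw (10,000 draws in
  the base configuration).  Distributions are moment-matched so the mean
  equals the base-case value and the printed (low, high) range maps to the
  2.5th/97.5th percentiles via SD = (high − low)/3.92; costs without a
  printed range use SD = 20% of the mean.  The cost-effectiveness
  acceptability curve (CEAC) uses net-monetary-benefit accounting, so draws
  with negative incremental QALYs are counted, not dropped.
* **Threshold pricing**: the incremental cost is exactly linear in the
  encorafenib and cetuximab unit prices, so the ICER surface over price
  discounts is computed in closed form from the per-component discounted
  spend of the base run.
* **Scenario**: a best-supportive-care-only variant in which progression on
  the first line leads directly to BSC (no checkpoint inhibitor or
  regorafenib lines).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PARAM_REGISTRY, Params, SAParam
from .economics import CEResult
from .strategies import BaseCaseResult, base_case

log = logging.getLogger(__name__)

__all__ = [
    "TornadoEntry",
    "PSASpec",
    "PSAResult",
    "ThresholdGrid",
    "one_way",
    "tornado",
    "run_psa",
    "threshold_analysis",
    "scenario_bsc_only",
]

TORNADO_MIN_SPAN = 5000.0  # $/QALY; smaller spans are left off the diagram


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    param_id: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def one_way(params: Params, param_id: str) -> TornadoEntry:
    """Rerun the full model at a parameter's low and high bound."""
    by_id = {sa.param_id: sa for sa in PARAM_REGISTRY}
    if param_id not in by_id:
        raise ValueError(f"unknown parameter id {param_id!r}")
    rng = params.sa_range(by_id[param_id])
    if rng is None:
        raise ValueError(f"parameter {param_id!r} has no printed range")
    icers = {}
    for bound in ("low", "high"):
        value = getattr(rng, bound)
        ce = base_case(params.with_overrides({param_id: value})).ce
        icers[bound] = ce.icer
    return TornadoEntry(
        param_id=param_id,
        low=rng.low,
        high=rng.high,
        icer_low=icers["low"],
        icer_high=icers["high"],
    )


def tornado(params: Params, min_span: float = TORNADO_MIN_SPAN) -> pd.DataFrame:
    """One-way SA over every ranged parameter, sorted by ICER span.

    Returns a table (parameter, low, high, icer_low, icer_high, span) sorted
    by descending span, keeping parameters with span > ``min_span``.
    """
    rows = []
    for sa in PARAM_REGISTRY:
        if params.sa_range(sa) is None:
            continue
        e = one_way(params, sa.param_id)
        rows.append(
            {
                "parameter": e.param_id,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "span": e.span,
            }
        )
    tab = pd.DataFrame(rows).sort_values("span", ascending=False).reset_index(drop=True)
    return tab[tab["span"] > min_span].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSASpec:
    """Monte Carlo design: number of draws, seed, and a variance scale.

    ``variance_scale`` multiplies every distribution's standard deviation
    (0 gives a degenerate PSA in which every draw is the base case — used to
    verify convergence of the PSA mean to the deterministic result).
    """

    n_draws: int = 10_000
    seed: int = 20210112
    variance_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.variance_scale < 0:
            raise ValueError("variance_scale must be >= 0")


def _sampler_moments(params: Params, sa: SAParam) -> tuple[str, float, float] | None:
    """(family, mean, sd) for one registry entry, or None if not sampled."""
    node = params.node(sa.section, sa.path)
    base = float(node["base"]) if isinstance(node, dict) else float(node)
    rng = params.sa_range(sa)
    if sa.kind == "cost":
        sd = (rng.high - rng.low) / 3.92 if rng is not None else 0.2 * base
        return ("gamma", base, sd)
    if sa.kind in ("probability", "utility"):
        if rng is None or base <= 0.0:
            return None  # degenerate (e.g. zero AE mortality): held fixed
        sd = (rng.high - rng.low) / 3.92
        cap = 0.5 * math.sqrt(base * (1.0 - base))
        if sd > cap:
            log.warning("beta sd for %s capped at %.4g (was %.4g)", sa.param_id, cap, sd)
            sd = cap
        return ("beta", base, sd)
    if sa.kind == "hazard_ratio":
        sigma = (math.log(rng.high) - math.log(rng.low)) / 3.92
        return ("lognormal", base, sigma)
    return None  # discount rate, starting age, dose caps: one-way only


def _draw(family: str, mean: float, sd: float, scale: float, rng: np.random.Generator) -> float:
    sd = sd * scale
    if sd == 0.0:
        return mean
    if family == "gamma":
        shape = (mean / sd) ** 2
        return float(rng.gamma(shape, mean / shape))
    if family == "beta":
        v = sd * sd
        nu = mean * (1.0 - mean) / v - 1.0
        a, b = mean * nu, (1.0 - mean) * nu
        return float(rng.beta(a, b))
    if family == "lognormal":
        # sd is the log-scale sigma; median pinned to the base estimate
        return float(rng.lognormal(math.log(mean), sd))
    raise ValueError(family)


@dataclass(frozen=True)
class PSAResult:
    """Draw-level PSA output with summaries."""

    draws: pd.DataFrame = field(repr=False)
    base_ce: CEResult
    wtp: float
    seed: int

    @property
    def n_negative_inc_qaly(self) -> int:
        return int((self.draws["inc_qaly"] <= 0).sum())

    def icer_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Percentile interval of the ICER over draws with a defined ratio."""
        ok = self.draws[self.draws["inc_qaly"] > 0]
        icers = ok["inc_cost"] / ok["inc_qaly"]
        lo, hi = np.quantile(icers, [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of draws where doublet has the higher net monetary benefit."""
        nmb = wtp * self.draws["inc_qaly"] - self.draws["inc_cost"]
        return float((nmb > 0).mean())

    def ceac(self, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
        if wtp_grid is None:
            wtp_grid = np.arange(0.0, 1_000_001.0, 10_000.0)
        probs = [self.prob_cost_effective(w) for w in np.asarray(wtp_grid, dtype=float)]
        return pd.DataFrame({"wtp": np.asarray(wtp_grid, dtype=float), "probability": probs})


def run_psa(params: Params, spec: PSASpec | None = None) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty through the model.

    Reproducible bit-for-bit under a fixed seed.  Returns per-draw costs and
    QALYs for both strategies plus the sampled parameter values.
    """
    spec = spec or PSASpec()
    rng = np.random.default_rng(spec.seed)
    samplers = []
    for sa in PARAM_REGISTRY:
        mom = _sampler_moments(params, sa)
        if mom is not None:
            samplers.append((sa.param_id, *mom))

    base = base_case(params)
    records = []
    for i in range(spec.n_draws):
        overrides = {
            pid: _draw(fam, mean, sd, spec.variance_scale, rng)
            for pid, fam, mean, sd in samplers
        }
        res = base_case(params.with_overrides(overrides))
        records.append(
            {
                "draw": i,
                "cost_doublet": res.ce.cost_a,
                "qaly_doublet": res.ce.qaly_a,
                "cost_standard": res.ce.cost_b,
                "qaly_standard": res.ce.qaly_b,
                "inc_cost": res.ce.inc_cost,
                "inc_qaly": res.ce.inc_qaly,
            }
        )
    draws = pd.DataFrame.from_records(records)
    return PSAResult(draws=draws, base_ce=base.ce, wtp=params.wtp, seed=spec.seed)


# ---------------------------------------------------------------------------
# Threshold pricing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdGrid:
    """ICER surface over encorafenib x cetuximab price discounts."""

    grid: pd.DataFrame = field(repr=False)  # long format
    contour: pd.DataFrame = field(repr=False)
    wtp: float
    base: BaseCaseResult = field(repr=False)

    def icer_at(self, enco_discount: float, cetux_discount: float) -> float:
        ce = self.base.ce
        enco = self.base.doublet.accrual.cost_by_component.get("encorafenib", 0.0)
        dct = self.base.doublet.accrual.cost_by_component.get("cetuximab", 0.0)
        sct = self.base.standard.accrual.cost_by_component.get("cetuximab", 0.0)
        inc = ce.inc_cost - enco_discount * enco - cetux_discount * (dct - sct)
        return inc / ce.inc_qaly


def threshold_analysis(
    params: Params, resolution: float = 0.01, wtp: float | None = None
) -> ThresholdGrid:
    """ICER over a grid of simultaneous encorafenib/cetuximab price discounts.

    The incremental cost is linear in both unit prices, so the surface is
    derived exactly from the base run's component-wise discounted drug spend.
    The contour reports, for each cetuximab discount, the encorafenib
    discount at which the ICER crosses the willingness-to-pay threshold
    (NaN when even a 100% discount cannot reach it).
    """
    wtp = float(wtp if wtp is not None else params.wtp)
    base = base_case(params)
    ce = base.ce
    enco = base.doublet.accrual.cost_by_component.get("encorafenib", 0.0)
    cet_d = base.doublet.accrual.cost_by_component.get("cetuximab", 0.0)
    cet_s = base.standard.accrual.cost_by_component.get("cetuximab", 0.0)
    d_cet = cet_d - cet_s

    steps = np.round(np.arange(0.0, 1.0 + resolution / 2, resolution), 10)
    ee, cc = np.meshgrid(steps, steps, indexing="ij")
    icer = (ce.inc_cost - ee * enco - cc * d_cet) / ce.inc_qaly
    grid = pd.DataFrame(
        {
            "enco_discount": ee.ravel(),
            "cetux_discount": cc.ravel(),
            "icer": icer.ravel(),
        }
    )
    # encorafenib discount solving ICER == wtp at each cetuximab discount
    need = (ce.inc_cost - steps * d_cet - wtp * ce.inc_qaly) / enco if enco > 0 else np.full_like(steps, np.nan)
    need = np.where((need >= 0) & (need <= 1), need, np.nan)
    contour = pd.DataFrame({"cetux_discount": steps, "enco_discount_at_wtp": need})
    return ThresholdGrid(grid=grid, contour=contour, wtp=wtp, base=base)


def scenario_bsc_only(params: Params) -> BaseCaseResult:
    """Scenario: progression on the first line leads directly to BSC."""
    return base_case(params, bsc_only=True)
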