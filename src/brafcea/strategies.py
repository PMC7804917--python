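"""Treatment-strategy assembly for relapsed BRAF V600E metastatic colorectal cancer.

Two strategies share one structure and differ only in the first-line drug:

* **doublet** — encorafenib + cetuximab; progression hazard is the fitted
  standard-chemotherapy Weibull with the trial hazard ratio (0.40) applied on
  the cumulative-hazard scale.
* **standard** — cetuximab + irinotecan-based chemotherapy (50/50 mix of
  FOLFIRI and irinotecan alone in the base case); progression follows the
  fitted Weibull directly.

At first progression, the MSI-high fraction of the cohort (8%) receives
nivolumab + ipilimumab and moves to regorafenib on progression; everyone else
goes straight to regorafenib.  Progression on regorafenib leads to a short
best-supportive-care (BSC) residence and then death.  Each line carries, on
its own clock, a time-in-state progression hazard, an adverse-event
discontinuation probability spread over the first two months (discontinuers
move to the next line), a one-time adverse-event mortality at line entry, and
background mortality from the life table competing every cycle.

The BSC residence (months) is the model's single calibrated quantity: it is
tuned so model median overall survival matches the source-trial medians
(9.3 months doublet, 5.9 months standard).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import economics
from .cohort import (
    Accrual,
    CohortTrace,
    MedianNotReached,
    PayoffSchedule,
    StateSpace,
    TunnelTransitionRule,
    accrue,
    compose_competing,
    median_survival,
    run_cohort,
)
from .config import Params
from .economics import (
    STATE_BSC,
    STATE_DEATH,
    STATE_FIRST_LINE,
    STATE_NIVO_IPI,
    STATE_REGORAFENIB,
    build_payoffs,
    compute_icer,
)
from .survival import (
    GompertzLaw,
    HazardRatioAdjusted,
    SurvivalLaw,
    WeibullLaw,
    cycle_transition_prob,
)

log = logging.getLogger(__name__)

__all__ = [
    "TreatmentLine",
    "CohortProfile",
    "LifeTable",
    "StrategySpec",
    "BaseCaseResult",
    "CalibrationResult",
    "build_strategy",
    "background_mortality",
    "combine_competing",
    "calibrate_bsc",
    "evaluate_arm",
    "base_case",
    "law_from_config",
]


@dataclass(frozen=True)
class TreatmentLine:
    """One line of therapy: its progression law and toxicity profile."""

    name: str
    pfs_law: SurvivalLaw
    p_discontinue_ae: float
    p_death_ae: float
    max_doses: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_discontinue_ae <= 1.0 or not 0.0 <= self.p_death_ae <= 1.0:
            raise ValueError(f"line {self.name!r}: AE probabilities must lie in [0, 1]")
        if self.p_discontinue_ae + self.p_death_ae > 1.0:
            raise ValueError(f"line {self.name!r}: AE probabilities sum beyond 1")


@dataclass(frozen=True)
class CohortProfile:
    """Demographics of the simulated cohort."""

    start_age: float = 61.0
    pct_male: float = 0.47
    pct_msi_h: float = 0.08
    pct_one_prior_line: float = 0.66

    def __post_init__(self) -> None:
        for name in ("pct_male", "pct_msi_h", "pct_one_prior_line"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_params(cls, params: Params) -> "CohortProfile":
        return cls(
            start_age=params.clin("start_age"),
            pct_male=float(params.clinical["pct_male"]),
            pct_msi_h=params.clin("pct_msi_h"),
            pct_one_prior_line=float(params.clinical.get("pct_one_prior_line", 0.66)),
        )


class LifeTable:
    """Annual all-cause death probability by integer age and sex."""

    def __init__(self, table: pd.DataFrame):
        t = table.sort_values("age").reset_index(drop=True)
        for col in ("age", "male", "female"):
            if col not in t.columns:
                raise ValueError(f"life table lacks column {col!r}")
        if ((t[["male", "female"]] < 0) | (t[["male", "female"]] > 1)).any().any():
            raise ValueError("life-table probabilities must lie in [0, 1]")
        self._ages = t["age"].to_numpy(dtype=int)
        self._male = t["male"].to_numpy(dtype=float)
        self._female = t["female"].to_numpy(dtype=float)
        self._warned = False

    def annual_q(self, age: float, pct_male: float) -> float:
        """Sex-mixture annual death probability at (floored) age."""
        a = int(math.floor(age))
        if a > self._ages[-1] and not self._warned:
            log.warning("age %s beyond life table; using terminal row", a)
            self._warned = True
        idx = int(np.clip(np.searchsorted(self._ages, a, side="right") - 1, 0, len(self._ages) - 1))
        return pct_male * self._male[idx] + (1.0 - pct_male) * self._female[idx]

    def monthly_background(self, start_age: float, pct_male: float, horizon: int) -> np.ndarray:
        """Per-cycle background death probabilities; the cohort ages 1/12 y per cycle."""
        ages = start_age + np.arange(horizon) / 12.0
        out = np.empty(horizon)
        for i, a in enumerate(ages):
            out[i] = background_mortality(self, a, pct_male)
        return out


def background_mortality(life_table: LifeTable, age: float, pct_male: float) -> float:
    """Monthly background death probability: 1 - (1 - q_annual)^(1/12)."""
    q = life_table.annual_q(age, pct_male)
    return 1.0 - (1.0 - q) ** (1.0 / 12.0)


def combine_competing(
    p_progress: float, p_ae_death: float, p_background: float
) -> dict[str, float]:
    """Outgoing distribution of one cycle under independent competing risks.

    Death takes 1 - (1-p_ae_death)(1-p_background); the remainder of the
    leaving mass follows the progression path; the three outputs sum to 1.
    """
    for name, p in (("p_progress", p_progress), ("p_ae_death", p_ae_death),
                    ("p_background", p_background)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    stay, move, death = compose_competing(p_progress, p_ae_death, p_background)
    return {"stay": float(stay), "progress": float(move), "death": float(death)}


def law_from_config(node: dict) -> SurvivalLaw:
    """Instantiate a survival law from a config entry (family + parameters)."""
    family = node["family"]
    if family == "weibull":
        return WeibullLaw(float(node["lam"]), float(node["kappa"]))
    if family == "gompertz":
        return GompertzLaw(float(node["lam"]), float(node["gamma"]))
    raise ValueError(f"unknown survival family {family!r}")


def tunnel_depth(law: SurvivalLaw, horizon: int, floor: int = 4) -> int:
    """Tunnel cycles to track for a law before its hazard can be clamped.

    Depth covers either essentially complete in-state absorption (in-state
    survival below 1e-14) or a flattened hazard (per-cycle change below
    1e-15), whichever comes first; occupancy beyond the returned depth is
    negligible or behaves identically, so clamping is exact to tolerance.
    """
    p = np.asarray(cycle_transition_prob(law, np.arange(horizon)))
    ksurv = np.cumprod(1.0 - p)
    absorbed = np.where(ksurv < 1e-14)[0]
    if absorbed.size:
        depth = int(absorbed[0]) + 2
    else:
        changing = np.where(np.abs(np.diff(p)) > 1e-15)[0]
        depth = int(changing[-1]) + 3 if changing.size else floor
    return int(min(max(depth, floor), horizon))


@dataclass(frozen=True)
class StrategySpec:
    """Everything needed to run one strategy through the cohort engine."""

    arm: str
    space: StateSpace
    rules: tuple[TunnelTransitionRule, ...]
    payoffs: PayoffSchedule
    profile: CohortProfile
    lines: dict[str, TreatmentLine] = field(repr=False)
    bsc_months: float = 0.5
    bsc_only: bool = False

    @property
    def initial(self) -> dict[str, float]:
        return {STATE_FIRST_LINE: 1.0}


def _line_rule(
    line: TreatmentLine,
    state: str,
    destinations: list[tuple[str, np.ndarray | float]],
    horizon: int,
) -> TunnelTransitionRule:
    """Transition rule of one treatment line on its own time-in-state clock.

    AE discontinuation is spread as two equal per-cycle probabilities over the
    first two months; AE mortality applies once at line entry (clock 0).
    """
    depth = tunnel_depth(line.pfs_law, horizon)
    p_prog = np.asarray(cycle_transition_prob(line.pfs_law, np.arange(depth)))
    p_dc = np.zeros(depth)
    p_dc[:2] = line.p_discontinue_ae / 2.0
    p_move = 1.0 - (1.0 - p_prog) * (1.0 - p_dc)
    p_die = np.zeros(depth)
    p_die[0] = line.p_death_ae
    return TunnelTransitionRule(
        from_state=state,
        p_move=p_move,
        destinations=tuple(destinations),
        p_die=p_die,
    )


def _dc_fraction(line: TreatmentLine, depth: int) -> np.ndarray:
    """Share of the leaving mass attributable to AE discontinuation, by clock."""
    p_prog = np.asarray(cycle_transition_prob(line.pfs_law, np.arange(depth)))
    p_dc = np.zeros(depth)
    p_dc[:2] = line.p_discontinue_ae / 2.0
    p_move = 1.0 - (1.0 - p_prog) * (1.0 - p_dc)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(p_move > 0, p_dc / np.where(p_move > 0, p_move, 1.0), 0.0)
    return frac


def _bsc_rule(bsc_months: float) -> TunnelTransitionRule:
    """Best-supportive-care residence as a fractional-cycle tunnel.

    A mean residence of m months is represented by deterministic death during
    tunnel cycle a (probability 1-f) or a+1 (probability f), where
    a + f = max(m - 0.5, 0); with deaths counted at cycle midpoints this
    makes the expected death time equal m months after BSC entry and varies
    continuously with m, which the median-survival calibration requires.
    """
    if bsc_months <= 0:
        raise ValueError("bsc_months must be > 0")
    m_eff = max(bsc_months - 0.5, 0.0)
    a = int(math.floor(m_eff))
    f = m_eff - a
    p_die = np.zeros(a + 2)
    p_die[a] = 1.0 - f
    p_die[a + 1] = 1.0
    return TunnelTransitionRule(
        from_state=STATE_BSC, p_move=np.zeros(a + 2), destinations=(), p_die=p_die
    )


def build_strategy(
    profile: CohortProfile,
    params: Params,
    arm: str,
    bsc_only: bool = False,
) -> StrategySpec:
    """Assemble the full state space, transition rules and payoffs of one arm.

    ``bsc_only`` drops the post-progression treatment lines (the scenario in
    which progressing patients receive best supportive care directly).  The
    two arms share every post-first-line component; only the first-line drug
    and its toxicity parameters differ.
    """
    if arm not in ("doublet", "standard"):
        raise ValueError(f"arm must be 'doublet' or 'standard', got {arm!r}")
    horizon = params.horizon
    chemo_law = law_from_config(params.clinical["survival"]["standard_chemo_pfs"])
    if arm == "doublet":
        hr_node = params.clinical["doublet_hr"]
        first_law: SurvivalLaw = HazardRatioAdjusted(
            chemo_law,
            hr=float(hr_node["base"]),
            hr_low=float(hr_node.get("low", hr_node["base"])),
            hr_high=float(hr_node.get("high", hr_node["base"])),
        )
    else:
        first_law = chemo_law

    lines = {
        STATE_FIRST_LINE: TreatmentLine(
            name=arm,
            pfs_law=first_law,
            p_discontinue_ae=params.clin("ae_discontinue", arm),
            p_death_ae=params.clin("ae_mortality", arm),
        ),
        STATE_NIVO_IPI: TreatmentLine(
            name="nivo_ipi",
            pfs_law=law_from_config(params.clinical["survival"]["nivo_ipi_pfs"]),
            p_discontinue_ae=params.clin("ae_discontinue", "nivo_ipi"),
            p_death_ae=params.clin("ae_mortality", "nivo_ipi"),
            max_doses=int(params.clin("nivo_max_doses")),
        ),
        STATE_REGORAFENIB: TreatmentLine(
            name="regorafenib",
            pfs_law=law_from_config(params.clinical["survival"]["regorafenib_pfs"]),
            p_discontinue_ae=params.clin("ae_discontinue", "regorafenib"),
            p_death_ae=params.clin("ae_mortality", "regorafenib"),
        ),
    }

    bsc_months = float(params.clinical["bsc_months"])
    dc_to_bsc = bool(params.clinical.get("ae_discontinuation_to_bsc", False))
    msi = profile.pct_msi_h

    rules: list[TunnelTransitionRule] = []
    if bsc_only:
        states = [STATE_FIRST_LINE, STATE_BSC, STATE_DEATH]
        rules.append(
            _line_rule(lines[STATE_FIRST_LINE], STATE_FIRST_LINE, [(STATE_BSC, 1.0)], horizon)
        )
    else:
        states = [STATE_FIRST_LINE, STATE_NIVO_IPI, STATE_REGORAFENIB, STATE_BSC, STATE_DEATH]
        first = lines[STATE_FIRST_LINE]
        if dc_to_bsc:
            # discontinuers go to BSC; progressors split MSI-H / regorafenib
            depth = tunnel_depth(first.pfs_law, horizon)
            dcf = _dc_fraction(first, depth)
            dests = [
                (STATE_NIVO_IPI, (1.0 - dcf) * msi),
                (STATE_REGORAFENIB, (1.0 - dcf) * (1.0 - msi)),
                (STATE_BSC, dcf),
            ]
        else:
            dests = [(STATE_NIVO_IPI, msi), (STATE_REGORAFENIB, 1.0 - msi)]
        rules.append(_line_rule(first, STATE_FIRST_LINE, dests, horizon))

        nivo = lines[STATE_NIVO_IPI]
        if dc_to_bsc:
            depth = tunnel_depth(nivo.pfs_law, horizon)
            dcf = _dc_fraction(nivo, depth)
            nivo_dests = [(STATE_REGORAFENIB, 1.0 - dcf), (STATE_BSC, dcf)]
        else:
            nivo_dests = [(STATE_REGORAFENIB, 1.0)]
        rules.append(_line_rule(nivo, STATE_NIVO_IPI, nivo_dests, horizon))
        rules.append(
            _line_rule(lines[STATE_REGORAFENIB], STATE_REGORAFENIB, [(STATE_BSC, 1.0)], horizon)
        )
    rules.append(_bsc_rule(bsc_months))

    space = StateSpace(states, absorbing=[STATE_DEATH])
    payoffs = build_payoffs(params, arm, bsc_only=bsc_only)
    return StrategySpec(
        arm=arm,
        space=space,
        rules=tuple(rules),
        payoffs=payoffs,
        profile=profile,
        lines=lines,
        bsc_months=bsc_months,
        bsc_only=bsc_only,
    )


# ---------------------------------------------------------------------------
# Running strategies and calibrating the BSC residence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmResult:
    arm: str
    accrual: Accrual
    trace: CohortTrace
    median_os: float | None


@dataclass(frozen=True)
class BaseCaseResult:
    doublet: ArmResult
    standard: ArmResult
    ce: "economics.CEResult"


def evaluate_arm(
    params: Params,
    arm: str,
    bsc_only: bool = False,
    life_table: LifeTable | None = None,
) -> ArmResult:
    """Build, run and accrue one strategy arm under the given parameters."""
    profile = CohortProfile.from_params(params)
    spec = build_strategy(profile, params, arm, bsc_only=bsc_only)
    lt = life_table if life_table is not None else LifeTable(params.life_table)
    bg = lt.monthly_background(profile.start_age, profile.pct_male, params.horizon)
    trace = run_cohort(
        spec.space,
        spec.rules,
        horizon=params.horizon,
        initial=spec.initial,
        background=bg,
        death_state=STATE_DEATH,
    )
    acc = accrue(
        trace,
        spec.payoffs,
        params.discount,
        half_cycle_correction=bool(params.clinical.get("half_cycle_correction", False)),
    )
    try:
        med = median_survival(trace)
    except MedianNotReached:
        med = None
    return ArmResult(arm=arm, accrual=acc, trace=trace, median_os=med)


def base_case(params: Params, bsc_only: bool = False) -> BaseCaseResult:
    """Run both strategies and derive the incremental cost-effectiveness ratio."""
    lt = LifeTable(params.life_table)
    dbl = evaluate_arm(params, "doublet", bsc_only=bsc_only, life_table=lt)
    std = evaluate_arm(params, "standard", bsc_only=bsc_only, life_table=lt)
    ce = compute_icer(
        (dbl.accrual.total_cost, dbl.accrual.total_qalys),
        (std.accrual.total_cost, std.accrual.total_qalys),
    )
    return BaseCaseResult(doublet=dbl, standard=std, ce=ce)


@dataclass(frozen=True)
class CalibrationResult:
    bsc_months: float
    achieved: dict[str, float]
    objective: float
    ties: tuple[float, ...]
    target_unreachable: bool
    grid: pd.DataFrame = field(repr=False)


def calibrate_bsc(
    params: Params,
    targets: dict[str, float] | None = None,
    grid: tuple[float, float, float] = (0.1, 6.0, 0.05),
) -> CalibrationResult:
    """Calibrate the BSC mean residence against trial median overall survival.

    Exhaustive grid search minimizing the summed absolute deviation of model
    median OS (both arms, one shared residence) from the targets.  Plateaus
    of the objective are resolved toward the smallest residence; all tied
    grid points are reported.
    """
    if targets is None:
        targets = {
            k: float(v) for k, v in params.clinical["os_target_months"].items()
        }
    if any(v <= 0 for v in targets.values()):
        raise ValueError("calibration targets must be positive")
    lo, hi, step = grid
    values = np.round(np.arange(lo, hi + step / 2, step), 10)
    lt = LifeTable(params.life_table)
    rows = []
    for m in values:
        p = params.with_bsc_months(float(m))
        meds = {}
        obj = 0.0
        for arm in ("doublet", "standard"):
            res = evaluate_arm(p, arm, life_table=lt)
            med = res.median_os if res.median_os is not None else float("inf")
            meds[arm] = med
            obj += abs(med - targets[arm])
        rows.append({"bsc_months": float(m), "objective": obj, **{f"median_{a}": meds[a] for a in meds}})
    tab = pd.DataFrame(rows)
    best_obj = tab["objective"].min()
    ties = tab.loc[np.isclose(tab["objective"], best_obj, atol=1e-12), "bsc_months"]
    best = float(ties.iloc[0])
    if len(ties) > 1:
        log.info("calibration objective tied at %s; choosing smallest", list(ties))
    best_row = tab[tab["bsc_months"] == best].iloc[0]
    achieved = {a: float(best_row[f"median_{a}"]) for a in targets}
    # unreachable if the fit is poor even at the optimum (e.g. absurd targets)
    unreachable = any(
        abs(achieved[a] - targets[a]) > 1.0 for a in targets
    )
    return CalibrationResult(
        bsc_months=best,
        achieved=achieved,
        objective=float(best_obj),
        ties=tuple(float(x) for x in ties),
        target_unreachable=unreachable,
        grid=tab,
    )
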