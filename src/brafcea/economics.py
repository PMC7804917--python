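"""Cost accrual per treatment line, utility payoffs, and ICER computation.

All monetary values are 2019 USD.  Intravenous agents are costed per
administered dose at the vial-rounded dose sizes of the bundled cost table;
oral agents (encorafenib, regorafenib) are flat monthly prices and carry no
administration cost.  Infusion visits are billed as: first-hour infusion code
once per visit, one additional hour for cetuximab-containing visits, an
additional-sequence code when a second drug is infused the same day, and a
preinfusion medication cost per visit.  Every month on treatment adds a
monitoring bundle (office visit, CBC, CEA, ALT, AST, lipase) plus half the
cost of a CT of the abdomen/pelvis (scans are every other month).

One-time costs: an expected adverse-event management cost at the start of
each treatment line (incidence-weighted sum over the configurable AE table)
and an end-of-life care cost on every entry to Death, whatever the cause.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import PayoffSchedule
from .config import Params

__all__ = [
    "STATE_FIRST_LINE",
    "STATE_NIVO_IPI",
    "STATE_REGORAFENIB",
    "STATE_BSC",
    "STATE_DEATH",
    "LINES",
    "CEResult",
    "monthly_line_cost",
    "line_cost_components",
    "monitoring_monthly",
    "one_time_costs",
    "build_payoffs",
    "compute_icer",
]

# Health-state labels shared across the package.
STATE_FIRST_LINE = "first_line"
STATE_NIVO_IPI = "nivo_ipi"
STATE_REGORAFENIB = "regorafenib"
STATE_BSC = "bsc"
STATE_DEATH = "death"

#: Modeled regimens accepted by :func:`monthly_line_cost`.
LINES = ("doublet", "standard", "nivo_ipi", "regorafenib", "bsc")


def monitoring_monthly(params: Params) -> float:
    """Monthly monitoring bundle: office visit + 5 labs + CT cost / 2."""
    m = params.costs["monitoring"]
    ct = params.cost("monitoring", "ct_abdomen_pelvis")
    every = float(m["ct_abdomen_pelvis"].get("every_months", 2))
    labs = sum(
        params.cost("monitoring", k) for k in ("office_visit", "cbc", "cea", "alt", "ast", "lipase")
    )
    return labs + ct / every


def _nivo_dose_arrays(params: Params) -> tuple[np.ndarray, np.ndarray]:
    """Per-month nivolumab and ipilimumab dose counts over time in state.

    Nivolumab runs every 3 weeks alongside ipilimumab for the first 4
    combination doses, then every 2 weeks alone until the dose cap; state
    occupancy may outlast dosing, in which case drug cost is zero.
    """
    combo = params.cost("dosing", "nivo_combo_doses_per_month")
    mono = params.cost("dosing", "nivo_mono_doses_per_month")
    ipi_max = float(params.clinical["ipi_max_doses"])
    nivo_max = params.clin("nivo_max_doses")
    t_combo_end = ipi_max / combo

    depth = int(math.ceil(t_combo_end + max(nivo_max - ipi_max, 0.0) / mono)) + 2
    t = np.arange(depth + 1, dtype=float)
    cum_nivo = np.minimum(
        combo * np.minimum(t, t_combo_end) + mono * np.maximum(t - t_combo_end, 0.0),
        nivo_max,
    )
    cum_ipi = np.minimum(combo * t, ipi_max)
    return np.diff(cum_nivo), np.diff(cum_ipi)


def line_cost_components(line: str, params: Params) -> dict[str, np.ndarray | float]:
    """Per-cycle cost components of one regimen, keyed by component label.

    Scalars apply at every time-in-state; arrays vary with time in state and
    hold their final value beyond their length (dose caps end in zeros).
    """
    if line not in LINES:
        raise ValueError(f"unknown treatment line {line!r}; expected one of {LINES}")
    c = params.cost
    admin_visit = c("administration", "infusion_first_hour") + c(
        "administration", "preinfusion_medication"
    )
    add_hour = c("administration", "infusion_additional_hour")
    add_seq = c("administration", "infusion_additional_sequence")
    cetux_per_mo = c("dosing", "cetuximab_doses_per_month")
    chemo_per_mo = c("dosing", "chemo_doses_per_month")

    if line == "doublet":
        return {
            "encorafenib": c("drugs", "encorafenib"),
            "cetuximab": cetux_per_mo * c("drugs", "cetuximab"),
            "administration": cetux_per_mo * (admin_visit + add_hour),
            "monitoring": monitoring_monthly(params),
        }
    if line == "standard":
        pf = params.clin("pct_folfiri")
        folfiri = c("drugs", "irinotecan") + c("drugs", "fluorouracil") + c("drugs", "folinic_acid")
        iri_only = c("drugs", "irinotecan")
        return {
            "cetuximab": cetux_per_mo * c("drugs", "cetuximab"),
            "chemo_backbone": chemo_per_mo * (pf * folfiri + (1.0 - pf) * iri_only),
            "administration": cetux_per_mo * (admin_visit + add_hour)
            + chemo_per_mo * add_seq,
            "monitoring": monitoring_monthly(params),
        }
    if line == "nivo_ipi":
        nivo_doses, ipi_doses = _nivo_dose_arrays(params)
        return {
            "nivolumab": c("drugs", "nivolumab") * nivo_doses,
            "ipilimumab": c("drugs", "ipilimumab") * ipi_doses,
            "administration": admin_visit * nivo_doses + add_seq * ipi_doses,
            "monitoring": monitoring_monthly(params),
        }
    if line == "regorafenib":
        return {
            "regorafenib": c("drugs", "regorafenib"),
            "monitoring": monitoring_monthly(params),
        }
    return {}  # best supportive care: no treatment or monitoring costs


def monthly_line_cost(line: str, cycle_in_line: int, params: Params) -> float:
    """Total cost of one regimen during a given time-in-state cycle."""
    if cycle_in_line < 0:
        raise ValueError("cycle_in_line must be >= 0")
    total = 0.0
    for comp in line_cost_components(line, params).values():
        arr = np.atleast_1d(np.asarray(comp, dtype=float))
        total += float(arr[min(cycle_in_line, arr.shape[0] - 1)])
    return total


def one_time_costs(event: str, params: Params, line: str | None = None) -> float:
    """One-time cost of an event: ``"death"`` or ``"line_start"``.

    Line starts incur the expected adverse-event management cost,
    sum(incidence x cost) over the configurable AE table for that line.
    """
    if event == "death":
        return params.cost("end_of_life")
    if event == "line_start":
        if line is None:
            raise ValueError("line_start event requires a line name")
        rows = params.ae_costs.get(line, []) or []
        return float(sum(r["incidence"] * r["cost"] for r in rows))
    raise ValueError(f"unknown one-time cost event {event!r}")


def build_payoffs(params: Params, arm: str, bsc_only: bool = False) -> PayoffSchedule:
    """Assemble the payoff schedule for one strategy arm.

    The health-state utility (0.66 in the base case) applies to every alive
    state; death carries zero utility and a one-time end-of-life cost on
    entry regardless of cause of death.
    """
    if arm not in ("doublet", "standard"):
        raise ValueError(f"arm must be 'doublet' or 'standard', got {arm!r}")
    u = params.utility
    first = line_cost_components(arm, params)
    cost_components = {STATE_FIRST_LINE: first, STATE_BSC: line_cost_components("bsc", params)}
    utility = {STATE_FIRST_LINE: u, STATE_BSC: u}
    entry = {
        STATE_FIRST_LINE: {"ae_management": one_time_costs("line_start", params, arm)},
        STATE_DEATH: {"end_of_life": one_time_costs("death", params)},
    }
    if not bsc_only:
        cost_components[STATE_NIVO_IPI] = line_cost_components("nivo_ipi", params)
        cost_components[STATE_REGORAFENIB] = line_cost_components("regorafenib", params)
        utility[STATE_NIVO_IPI] = u
        utility[STATE_REGORAFENIB] = u
        entry[STATE_NIVO_IPI] = {
            "ae_management": one_time_costs("line_start", params, "nivo_ipi")
        }
        entry[STATE_REGORAFENIB] = {
            "ae_management": one_time_costs("line_start", params, "regorafenib")
        }
    return PayoffSchedule(
        cost_components=cost_components, utility=utility, entry_cost_components=entry
    )


@dataclass(frozen=True)
class CEResult:
    """Paired cost/QALY totals and the derived incremental ratio.

    ``status`` is ``"ok"`` when the ICER is a meaningful ratio,
    ``"a_dominates"`` / ``"b_dominates"`` for dominance (ratio not reported),
    and ``"undefined"`` when incremental QALYs are numerically zero.
    """

    label_a: str
    label_b: str
    cost_a: float
    qaly_a: float
    cost_b: float
    qaly_b: float

    @property
    def inc_cost(self) -> float:
        return self.cost_a - self.cost_b

    @property
    def inc_qaly(self) -> float:
        return self.qaly_a - self.qaly_b

    @property
    def status(self) -> str:
        if abs(self.inc_qaly) < 1e-9:
            return "undefined"
        if self.inc_qaly > 0 and self.inc_cost <= 0:
            return "a_dominates"
        if self.inc_qaly < 0 and self.inc_cost >= 0:
            return "b_dominates"
        return "ok"

    @property
    def icer(self) -> float:
        """Incremental cost per QALY gained; NaN unless status == 'ok'."""
        if self.status != "ok":
            return math.nan
        return self.inc_cost / self.inc_qaly


def compute_icer(
    a: tuple[float, float],
    b: tuple[float, float],
    label_a: str = "doublet",
    label_b: str = "standard",
) -> CEResult:
    """CEResult for strategy ``a`` (cost, QALY) versus comparator ``b``."""
    return CEResult(
        label_a=label_a,
        label_b=label_b,
        cost_a=float(a[0]),
        qaly_a=float(a[1]),
        cost_b=float(b[0]),
        qaly_b=float(b[1]),
    )
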