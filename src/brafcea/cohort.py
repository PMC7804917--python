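"""Discrete-time Markov cohort engine with time-in-state (tunnel) expansion.

The engine propagates a cohort across health states in fixed-length cycles.
Every non-absorbing state carries a tunnel clock (cycles since entry) so that
transition probabilities may depend on time in state — required because the
progression hazards of the parametric survival laws are non-constant.

Within a cycle, three competing risks act on each (state, time-in-state) bin,
treated as independent:

* an in-state exit hazard ``p_move`` (progression and/or toxicity-driven
  discontinuation) routing survivors to successor states,
* an in-state death hazard ``p_die`` (e.g. treatment mortality at line entry),
* a global background death probability ``g`` shared across states, varying
  with model cycle (the cohort ages).

The composition is ``stay = (1-p_move)(1-p_die)(1-g)``; all death causes pool
into ``death = 1 - (1-p_die)(1-g)``; the remaining leaving mass
``p_move (1-p_die)(1-g)`` splits across the rule's destinations.  Stayers
advance their tunnel clock by one; entrants start at clock zero.  Beyond a
rule's declared tunnel depth the hazards are held at their last value (states
whose hazards have flattened can therefore be truncated without error).

Payoffs (per-cycle costs and utilities attached to (state, time-in-state),
plus one-time costs on state entry) are accrued at cycle start, weighted by
start-of-cycle occupancy, and discounted at ``(1+r)^(-cycle/12)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "StateSpace",
    "TunnelTransitionRule",
    "CohortTrace",
    "PayoffSchedule",
    "Accrual",
    "MedianNotReached",
    "run_cohort",
    "accrue",
    "median_survival",
    "compose_competing",
]

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class StateSpace:
    """Ordered health-state labels with the absorbing subset flagged."""

    states: tuple[str, ...]
    absorbing: frozenset[str]

    def __init__(self, states: Sequence[str], absorbing: Sequence[str]):
        object.__setattr__(self, "states", tuple(states))
        object.__setattr__(self, "absorbing", frozenset(absorbing))
        if len(set(self.states)) != len(self.states):
            raise ValueError("state labels must be unique")
        if not self.absorbing:
            raise ValueError("at least one absorbing state is required")
        unknown = self.absorbing - set(self.states)
        if unknown:
            raise ValueError(f"absorbing states not in state list: {sorted(unknown)}")

    def index(self, state: str) -> int:
        return self.states.index(state)


@dataclass(frozen=True)
class TunnelTransitionRule:
    """Outgoing behaviour of one state as arrays over time-in-state.

    ``p_move[t]`` is the probability (before competing death risks) of leaving
    the state during tunnel cycle ``t``; movers split across ``destinations``
    (label -> fraction; fractions may be scalars or arrays over time-in-state
    and must sum to 1 at every clock value).  ``p_die[t]`` is an in-state
    death hazard.  ``subject_to_background`` applies the engine-level
    per-cycle background mortality.  Arrays are clamped at their last entry
    for time-in-state beyond their length.
    """

    from_state: str
    p_move: np.ndarray
    destinations: tuple[tuple[str, np.ndarray], ...]
    p_die: np.ndarray | None = None
    subject_to_background: bool = True

    def __post_init__(self) -> None:
        pm = np.atleast_1d(np.asarray(self.p_move, dtype=float))
        pd = (
            np.zeros_like(pm)
            if self.p_die is None
            else np.atleast_1d(np.asarray(self.p_die, dtype=float))
        )
        if pd.shape != pm.shape:
            if pd.size == 1:
                pd = np.full_like(pm, pd.item())
            else:
                raise ValueError("p_die must be scalar or match p_move length")
        for name, arr in (("p_move", pm), ("p_die", pd)):
            if np.any(~np.isfinite(arr)) or np.any((arr < 0) | (arr > 1)):
                raise ValueError(
                    f"{name} for state {self.from_state!r} must lie in [0, 1]"
                )
        object.__setattr__(self, "p_move", pm)
        object.__setattr__(self, "p_die", pd)
        depth = pm.shape[0]
        dests = tuple(
            (str(s), _fit_len(np.atleast_1d(np.asarray(f, dtype=float)), depth))
            for s, f in self.destinations
        )
        if dests:
            fsum = np.sum([f for _, f in dests], axis=0)
            if any(np.any(f < 0) for _, f in dests) or np.any(np.abs(fsum - 1.0) > 1e-9):
                raise ValueError(
                    f"destination fractions for {self.from_state!r} must be "
                    f"nonnegative and sum to 1 at every time-in-state"
                )
        elif np.any(pm > 0):
            raise ValueError(
                f"state {self.from_state!r} has p_move > 0 but no destinations"
            )
        object.__setattr__(self, "destinations", dests)

    @property
    def depth(self) -> int:
        return int(self.p_move.shape[0])


def compose_competing(p_move, p_die, p_background):
    """Independent-risk composition of the three per-cycle hazards.

    Returns ``(stay, move, death)``; the three always sum to 1.
    """
    p_move = np.asarray(p_move, dtype=float)
    p_die = np.asarray(p_die, dtype=float)
    alive = (1.0 - p_die) * (1.0 - p_background)
    stay = (1.0 - p_move) * alive
    move = p_move * alive
    death = 1.0 - alive
    return stay, move, death


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-(state, time-in-state) occupancy of the cohort.

    ``occupancy`` has one row per cycle boundary (``horizon + 1`` rows) over
    the expanded state space; ``offsets`` delimit each state's tunnel block.
    ``entries[c, s]`` is the mass newly entering state ``s`` at cycle ``c``
    (row 0 holds the initial placement), used for one-time entry payoffs.
    """

    space: StateSpace
    occupancy: np.ndarray
    offsets: np.ndarray
    entries: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def depth(self, state: str) -> int:
        i = self.space.index(state)
        return int(self.offsets[i + 1] - self.offsets[i])

    def block(self, state: str) -> np.ndarray:
        """Occupancy rows restricted to one state's tunnel block."""
        i = self.space.index(state)
        return self.occupancy[:, self.offsets[i] : self.offsets[i + 1]]

    def state_totals(self) -> np.ndarray:
        """(horizon+1, n_states) occupancy summed over time-in-state."""
        return np.add.reduceat(self.occupancy, self.offsets[:-1], axis=1)

    def alive_fraction(self) -> np.ndarray:
        dead = np.zeros(self.occupancy.shape[0])
        for s in self.space.absorbing:
            dead += self.block(s).sum(axis=1)
        return 1.0 - dead

    def to_frame(self):
        """Long-format (cycle, state, occupancy) table."""
        import pandas as pd

        totals = self.state_totals()
        cycles = np.arange(totals.shape[0])
        return pd.DataFrame(
            {
                "cycle": np.repeat(cycles, len(self.space.states)),
                "state": np.tile(self.space.states, totals.shape[0]),
                "occupancy": totals.ravel(),
            }
        )


def _propagate_py(
    horizon, offsets, p_move, p_die, bg, bg_mask, route_ptr, route_dest, route_frac,
    route_off, death_idx, init,
):
    n_states = offsets.shape[0] - 1
    n_exp = offsets[-1]
    trace = np.zeros((horizon + 1, n_exp))
    entries = np.zeros((horizon + 1, n_states))
    trace[0] = init
    for s in range(n_states):
        entries[0, s] = init[offsets[s] : offsets[s + 1]].sum()
    occ = init.copy()
    for c in range(horizon):
        new = np.zeros(n_exp)
        for s in range(n_states):
            lo, hi = offsets[s], offsets[s + 1]
            depth = hi - lo
            g = bg[c] if bg_mask[s] else 0.0
            for t in range(depth):
                m = occ[lo + t]
                if m == 0.0:
                    continue
                pm = p_move[lo + t]
                pdn = p_die[lo + t]
                alive = (1.0 - pdn) * (1.0 - g)
                stay = m * (1.0 - pm) * alive
                movers = m * pm * alive
                dead = m - stay - movers
                t2 = t + 1 if t + 1 < depth else depth - 1
                new[lo + t2] += stay
                for r in range(route_ptr[s], route_ptr[s + 1]):
                    d = route_dest[r]
                    amt = movers * route_frac[route_off[r] + t]
                    new[offsets[d]] += amt
                    entries[c + 1, d] += amt
                if dead > 0.0:
                    new[offsets[death_idx]] += dead
                    entries[c + 1, death_idx] += dead
        trace[c + 1] = new
        occ = new
    return trace, entries


try:  # compiled kernel; the pure-python loop above is the reference
    from numba import njit

    _propagate_jit = njit(cache=False)(_propagate_py)
except ImportError:  # pragma: no cover
    _propagate_jit = None


def run_cohort(
    space: StateSpace,
    rules: Sequence[TunnelTransitionRule],
    horizon: int,
    initial: Mapping[str, float],
    background: np.ndarray | float = 0.0,
    death_state: str | None = None,
    max_depth: int | None = None,
    use_jit: bool = True,
) -> CohortTrace:
    """Propagate the cohort forward for ``horizon`` cycles.

    ``initial`` maps state labels to starting mass (must sum to 1; placed at
    tunnel clock 0).  ``background`` is a per-cycle death probability (scalar
    or length->horizon array) routed to ``death_state`` (default: the single
    absorbing state).  ``max_depth`` caps tunnel expansion; rules shorter than
    their state's residency simply hold their final hazard value.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    init_total = float(sum(initial.values()))
    if abs(init_total - 1.0) > _MASS_TOL:
        raise ValueError(f"initial distribution sums to {init_total}, not 1")
    unknown = set(initial) - set(space.states)
    if unknown:
        raise ValueError(f"initial distribution names unknown states: {sorted(unknown)}")

    rule_map: dict[str, TunnelTransitionRule] = {}
    for r in rules:
        if r.from_state not in space.states:
            raise ValueError(f"rule references unknown state {r.from_state!r}")
        if r.from_state in rule_map:
            raise ValueError(f"duplicate rule for state {r.from_state!r}")
        for dest, _ in r.destinations:
            if dest not in space.states:
                raise ValueError(
                    f"rule for {r.from_state!r} routes to unknown state {dest!r}"
                )
        rule_map[r.from_state] = r

    if death_state is None:
        if len(space.absorbing) != 1:
            raise ValueError("death_state must be given when several states absorb")
        death_state = next(iter(space.absorbing))

    n_states = len(space.states)
    depths = np.ones(n_states, dtype=np.int64)
    for i, s in enumerate(space.states):
        if s in space.absorbing:
            continue
        r = rule_map.get(s)
        d = r.depth if r is not None else 1
        if max_depth is not None:
            d = min(d, max_depth)
        depths[i] = max(d, 1)
    offsets = np.zeros(n_states + 1, dtype=np.int64)
    offsets[1:] = np.cumsum(depths)
    n_exp = int(offsets[-1])

    p_move = np.zeros(n_exp)
    p_die = np.zeros(n_exp)
    bg_mask = np.zeros(n_states, dtype=np.bool_)
    route_ptr = np.zeros(n_states + 1, dtype=np.int64)
    route_dest_l: list[int] = []
    route_off_l: list[int] = []
    route_frac_parts: list[np.ndarray] = []
    frac_cursor = 0
    for i, s in enumerate(space.states):
        r = rule_map.get(s)
        if r is not None and s not in space.absorbing:
            d = int(depths[i])
            p_move[offsets[i] : offsets[i] + d] = _fit_len(r.p_move, d)
            p_die[offsets[i] : offsets[i] + d] = _fit_len(r.p_die, d)
            bg_mask[i] = r.subject_to_background
            for dest, frac in r.destinations:
                route_dest_l.append(space.index(dest))
                route_off_l.append(frac_cursor)
                route_frac_parts.append(_fit_len(frac, d))
                frac_cursor += d
        elif s not in space.absorbing:
            bg_mask[i] = True  # unruled transient state still ages and can die
        route_ptr[i + 1] = len(route_dest_l)
    route_dest = np.asarray(route_dest_l, dtype=np.int64)
    route_off = np.asarray(route_off_l, dtype=np.int64)
    route_frac = (
        np.concatenate(route_frac_parts) if route_frac_parts else np.empty(0)
    )

    bg = np.broadcast_to(np.asarray(background, dtype=float), (horizon,)).copy()
    if np.any((bg < 0) | (bg > 1)):
        raise ValueError("background probabilities must lie in [0, 1]")

    init = np.zeros(n_exp)
    for s, m in initial.items():
        if m < 0:
            raise ValueError("initial masses must be nonnegative")
        init[offsets[space.index(s)]] = m

    kernel = _propagate_jit if (use_jit and _propagate_jit is not None) else _propagate_py
    trace, entries = kernel(
        int(horizon), offsets, p_move, p_die, bg, bg_mask,
        route_ptr, route_dest, route_frac, route_off,
        int(space.index(death_state)), init,
    )

    row_sums = trace.sum(axis=1)
    bad = np.where(np.abs(row_sums - 1.0) > _MASS_TOL)[0]
    if bad.size:
        raise RuntimeError(
            f"cohort mass not conserved at cycle {bad[0]}: row sum {row_sums[bad[0]]}"
        )
    return CohortTrace(space=space, occupancy=trace, offsets=offsets, entries=entries)


def _fit_len(arr: np.ndarray, d: int) -> np.ndarray:
    if arr.shape[0] >= d:
        return arr[:d]
    return np.concatenate([arr, np.full(d - arr.shape[0], arr[-1])])


# ---------------------------------------------------------------------------
# Payoff accrual
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PayoffSchedule:
    """Per-cycle and one-time payoffs attached to the state space.

    ``cost_components``: state -> component label -> cost per cycle (scalar or
    array over time-in-state, 2019 USD).  ``utility``: state -> health-state
    utility weight in [0, 1]; QALYs accrue at utility/12 per monthly cycle.
    ``entry_cost_components``: state -> component label -> one-time cost on
    entry (e.g. end-of-life care on entry to Death).
    """

    cost_components: Mapping[str, Mapping[str, np.ndarray | float]] = field(
        default_factory=dict
    )
    utility: Mapping[str, float] = field(default_factory=dict)
    entry_cost_components: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for s, comps in self.cost_components.items():
            for label, c in comps.items():
                if np.any(np.asarray(c) < 0):
                    raise ValueError(f"negative cost for {s}/{label}")
        for s, u in self.utility.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility for {s!r} must lie in [0, 1]")
        for s, comps in self.entry_cost_components.items():
            for label, c in comps.items():
                if c < 0:
                    raise ValueError(f"negative entry cost for {s}/{label}")


@dataclass(frozen=True)
class Accrual:
    """Discounted totals from one cohort run, with a cost breakdown."""

    total_cost: float
    total_qalys: float
    cost_by_component: dict[str, float]
    life_years: float


def accrue(
    trace: CohortTrace,
    payoffs: PayoffSchedule,
    annual_discount: float,
    half_cycle_correction: bool = False,
) -> Accrual:
    """Discounted total cost and QALYs of a trace under a payoff schedule.

    Cycle-``c`` payoffs are weighted by start-of-cycle occupancy and the
    discount factor ``(1+r)^(-c/12)``; one-time entry payoffs are weighted by
    newly entering mass at the entry cycle, same-cycle discounted.  With
    ``half_cycle_correction`` per-cycle payoffs weight the average of start-
    and end-of-cycle occupancy instead (entry payoffs are unaffected).
    """
    if annual_discount < 0:
        raise ValueError("annual_discount must be >= 0")
    horizon = trace.horizon
    cycles = np.arange(horizon + 1)
    disc = (1.0 + annual_discount) ** (-cycles / 12.0)

    cost_by: dict[str, float] = {}
    total_qalys = 0.0
    alive = trace.alive_fraction()
    alive_w = 0.5 * (alive[:horizon] + alive[1:]) if half_cycle_correction else alive[:horizon]
    life_years = float(np.dot(disc[:horizon], alive_w)) / 12.0

    for i, s in enumerate(trace.space.states):
        block = trace.block(s)  # (horizon+1, depth)
        # discounted occupancy per time-in-state bin, cycles 0..horizon-1
        occ_w = (
            0.5 * (block[:horizon] + block[1 : horizon + 1])
            if half_cycle_correction
            else block[:horizon]
        )
        w = disc[:horizon] @ occ_w
        comps = payoffs.cost_components.get(s, {})
        for label, c in comps.items():
            c_arr = np.atleast_1d(np.asarray(c, dtype=float))
            if c_arr.shape[0] == 1:
                amount = float(c_arr[0] * w.sum())
            else:
                amount = float(np.dot(_fit_len(c_arr, w.shape[0]), w))
            cost_by[label] = cost_by.get(label, 0.0) + amount
        u = payoffs.utility.get(s, 0.0)
        if u:
            total_qalys += u / 12.0 * float(w.sum())
        ecomps = payoffs.entry_cost_components.get(s, {})
        if ecomps:
            entry_disc = float(np.dot(disc, trace.entries[:, i]))
            for label, c in ecomps.items():
                cost_by[label] = cost_by.get(label, 0.0) + c * entry_disc

    return Accrual(
        total_cost=float(sum(cost_by.values())),
        total_qalys=float(total_qalys),
        cost_by_component=cost_by,
        life_years=life_years,
    )


class MedianNotReached(Exception):
    """Raised when the alive fraction never falls below one half."""


def median_survival(trace: CohortTrace) -> float:
    """Median survival (months) by linear interpolation of the alive curve."""
    alive = trace.alive_fraction()
    below = np.where(alive < 0.5)[0]
    if below.size == 0:
        raise MedianNotReached(
            f"alive fraction still {alive[-1]:.4f} at horizon {trace.horizon}"
        )
    j = int(below[0])
    if j == 0:
        return 0.0
    a0, a1 = alive[j - 1], alive[j]
    return (j - 1) + (a0 - 0.5) / (a0 - a1)
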