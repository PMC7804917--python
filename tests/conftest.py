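"""Shared fixtures and the independent micro-simulation oracle."""

from __future__ import annotations

import numpy as np
import pytest

from brafcea.config import load_params


@pytest.fixture(scope="session")
def params():
    """Bundled base-case parameter set (read-only; copy before mutating)."""
    return load_params()


@pytest.fixture(scope="session")
def base_result(params):
    """Base-case run of both arms, shared across tests."""
    from brafcea.strategies import base_case

    return base_case(params)


def microsimulate(space, rules, horizon, initial, background, death_state, n, seed):
    """Individual-level Monte Carlo with the same rule semantics as the engine.

    Implemented independently of the cohort engine (per-patient sampling of
    the competing risks each cycle) so it can serve as an oracle: the cohort
    trace is the expectation of this simulation.  Returns per-cycle state
    occupancy fractions with shape (horizon+1, n_states).
    """
    rng = np.random.default_rng(seed)
    states = list(space.states)
    idx = {s: i for i, s in enumerate(states)}
    rule_of = {r.from_state: r for r in rules}
    death_i = idx[death_state]

    state = np.full(n, idx[next(iter(initial))], dtype=np.int64)
    # allocate patients across the initial distribution
    labels, masses = zip(*initial.items())
    counts = np.round(np.cumsum(masses) * n).astype(int)
    start = 0
    for lab, stop in zip(labels, counts):
        state[start:stop] = idx[lab]
        start = stop
    tis = np.zeros(n, dtype=np.int64)

    counts_out = np.zeros((horizon + 1, len(states)))
    bg = np.broadcast_to(np.asarray(background, dtype=float), (horizon,))
    for c in range(horizon + 1):
        counts_out[c] = np.bincount(state, minlength=len(states)) / n
        if c == horizon:
            break
        new_state = state.copy()
        new_tis = tis + 1
        for s in states:
            i = idx[s]
            if s in space.absorbing:
                new_tis[state == i] = 0
                continue
            sel = np.where(state == i)[0]
            if sel.size == 0:
                continue
            r = rule_of.get(s)
            if r is None:
                p_move = np.zeros(sel.size)
                p_die = np.zeros(sel.size)
                dests, fracs = [], np.zeros((0, 1))
                g = bg[c]
            else:
                t_cl = np.minimum(tis[sel], r.p_move.shape[0] - 1)
                p_move = r.p_move[t_cl]
                p_die = r.p_die[t_cl]
                dests = [idx[d] for d, _ in r.destinations]
                fracs = np.stack([f[t_cl] for _, f in r.destinations]) if dests else np.zeros((0, sel.size))
                g = bg[c] if r.subject_to_background else 0.0
            u_death = rng.uniform(size=sel.size)
            u_move = rng.uniform(size=sel.size)
            u_dest = rng.uniform(size=sel.size)
            dies = u_death > (1.0 - p_die) * (1.0 - g)
            moves = (~dies) & (u_move < p_move)
            new_state[sel[dies]] = death_i
            new_tis[sel[dies]] = 0
            if dests:
                cum = np.cumsum(fracs, axis=0)
                which = (u_dest[None, :] > cum).sum(axis=0)
                which = np.minimum(which, len(dests) - 1)
                mv = sel[moves]
                new_state[mv] = np.asarray(dests)[which[moves]]
                new_tis[mv] = 0
        state, tis = new_state, new_tis
    return counts_out
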