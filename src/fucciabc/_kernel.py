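"""Numba core of the Gillespie exclusion-process simulation.

One flat event loop over the whole agent population: the total event rate
is Λ = Σ_p n_p (M_p + R_p); waiting times are Exponential(Λ); a phase
class is chosen with probability n_p (M_p + R_p)/Λ, an agent of that
class uniformly, and motility-vs-transition with probability M_p vs R_p.
This category-first selection induces exactly the per-agent Markov law
(each agent carries independent move and transition clocks).

Per-phase membership lists with swap-removal keep every event O(1).
Blocked moves and blocked divisions consume time (attempt-rate
convention); division resets the mother to red and places a red daughter
on the drawn neighbour, aborting entirely if that site is occupied or
off-lattice.
"""

import numpy as np
from numba import njit

RED = 0
YELLOW = 1
GREEN = 2

# counter slots returned by the kernel
N_EVENTS = 0
MOVE_ATTEMPTS = 1
MOVE_SUCCESSES = 2
RED_TO_YELLOW = 3
YELLOW_TO_GREEN = 4
DIVISION_ATTEMPTS = 5
DIVISION_SUCCESSES = 6
RECORD_OVERFLOW = 7


@njit(cache=True, fastmath=True)
def run_gillespie(
    occ,
    agent_site,
    agent_phase,
    n_agents,
    nbr,
    rates,
    t_start,
    t_end,
    seed,
    track_slot,
    n_tracks,
    delta,
    record_events,
    rec_cap,
):
    """Advance the configuration in place from ``t_start`` to ``t_end``.

    ``rates`` is (R_r, R_y, R_g, M_r, M_y, M_g) in h^-1.  ``track_slot``
    maps agent id -> tracked-cell slot (-1 untracked); tracking of an
    agent ends at its division.  Returns the new agent count, per-track
    per-phase path lengths, division flags, the event record arrays for
    tracked cells, and event counters.
    """
    np.random.seed(seed)
    cap = agent_site.shape[0]

    members = np.empty((3, cap), dtype=np.int32)
    count = np.zeros(3, dtype=np.int64)
    pos = np.empty(cap, dtype=np.int32)
    for a in range(n_agents):
        p = agent_phase[a]
        members[p, count[p]] = a
        pos[a] = count[p]
        count[p] += 1

    phase_dist = np.zeros((max(n_tracks, 1), 3), dtype=np.float64)
    track_divided = np.zeros(max(n_tracks, 1), dtype=np.uint8)

    rec_slot = np.empty(rec_cap, dtype=np.int32)
    rec_t = np.empty(rec_cap, dtype=np.float64)
    rec_site = np.empty(rec_cap, dtype=np.int32)
    rec_phase = np.empty(rec_cap, dtype=np.int8)
    rec_n = 0

    counters = np.zeros(8, dtype=np.int64)

    t = t_start
    while True:
        lam = 0.0
        for p in range(3):
            lam += count[p] * (rates[3 + p] + rates[p])
        if lam <= 0.0:
            t = t_end
            break
        t += np.random.exponential(1.0 / lam)
        if t >= t_end:
            t = t_end
            break
        counters[N_EVENTS] += 1

        # phase class proportional to n_p (M_p + R_p)
        u = np.random.random() * lam
        p = 0
        acc = count[0] * (rates[3] + rates[0])
        while u >= acc and p < 2:
            p += 1
            acc += count[p] * (rates[3 + p] + rates[p])

        k = int(np.random.random() * count[p])
        if k >= count[p]:
            k = int(count[p] - 1)
        aid = members[p, k]

        if np.random.random() * (rates[3 + p] + rates[p]) < rates[3 + p]:
            # movement attempt: uniform direction, abort if blocked
            counters[MOVE_ATTEMPTS] += 1
            d = int(np.random.random() * 6.0)
            if d > 5:
                d = 5
            tgt = nbr[agent_site[aid], d]
            if tgt >= 0 and occ[tgt] < 0:
                occ[agent_site[aid]] = -1
                occ[tgt] = aid
                agent_site[aid] = tgt
                counters[MOVE_SUCCESSES] += 1
                slot = track_slot[aid]
                if slot >= 0:
                    phase_dist[slot, p] += delta
                    if record_events:
                        if rec_n < rec_cap:
                            rec_slot[rec_n] = slot
                            rec_t[rec_n] = t
                            rec_site[rec_n] = tgt
                            rec_phase[rec_n] = p
                            rec_n += 1
                        else:
                            counters[RECORD_OVERFLOW] += 1
        elif p < GREEN:
            # red->yellow / yellow->green, unaffected by crowding
            q = p + 1
            kpos = pos[aid]
            last = members[p, count[p] - 1]
            members[p, kpos] = last
            pos[last] = kpos
            count[p] -= 1
            members[q, count[q]] = aid
            pos[aid] = count[q]
            count[q] += 1
            agent_phase[aid] = q
            counters[RED_TO_YELLOW if p == RED else YELLOW_TO_GREEN] += 1
            slot = track_slot[aid]
            if slot >= 0 and record_events:
                if rec_n < rec_cap:
                    rec_slot[rec_n] = slot
                    rec_t[rec_n] = t
                    rec_site[rec_n] = agent_site[aid]
                    rec_phase[rec_n] = q
                    rec_n += 1
                else:
                    counters[RECORD_OVERFLOW] += 1
        else:
            # green -> division: red daughter on drawn neighbour, mother red
            counters[DIVISION_ATTEMPTS] += 1
            d = int(np.random.random() * 6.0)
            if d > 5:
                d = 5
            tgt = nbr[agent_site[aid], d]
            if tgt >= 0 and occ[tgt] < 0:
                counters[DIVISION_SUCCESSES] += 1
                did = n_agents
                occ[tgt] = did
                agent_site[did] = tgt
                agent_phase[did] = RED
                track_slot[did] = -1
                members[RED, count[RED]] = did
                pos[did] = count[RED]
                count[RED] += 1
                n_agents += 1

                kpos = pos[aid]
                last = members[GREEN, count[GREEN] - 1]
                members[GREEN, kpos] = last
                pos[last] = kpos
                count[GREEN] -= 1
                members[RED, count[RED]] = aid
                pos[aid] = count[RED]
                count[RED] += 1
                agent_phase[aid] = RED

                slot = track_slot[aid]
                if slot >= 0:
                    track_divided[slot] = 1
                    track_slot[aid] = -1
                    if record_events:
                        if rec_n < rec_cap:
                            rec_slot[rec_n] = slot
                            rec_t[rec_n] = t
                            rec_site[rec_n] = agent_site[aid]
                            rec_phase[rec_n] = RED
                            rec_n += 1
                        else:
                            counters[RECORD_OVERFLOW] += 1

    return (
        n_agents,
        t,
        phase_dist,
        track_divided,
        rec_n,
        rec_slot[:rec_n],
        rec_t[:rec_n],
        rec_site[:rec_n],
        rec_phase[:rec_n],
        counters,
    )
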