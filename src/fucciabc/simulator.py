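"""Continuous-time stochastic simulation of FUCCI-labelled cell invasion.

Agents occupy sites of a hexagonal lattice (at most one per site) and
carry a cell-cycle phase revealed by FUCCI labelling: red (G1), yellow
(early S) and green (S/G2/M).  Each phase has a motility attempt rate
M_p and a cycle-progression rate R_p (both per hour).  Movement targets
a uniformly drawn neighbour and aborts if the site is occupied or
off-lattice; red->yellow and yellow->green transitions are unaffected by
crowding; a green agent divides at rate R_g into two red agents — the
mother stays in place, the daughter takes a uniformly drawn neighbour
site — and the whole division aborts if that site is unavailable.

Events are scheduled with the Gillespie algorithm (exponential waiting
times, rate-proportional selection).  ``simulate`` runs a compiled event
loop; ``gillespie_step`` is a plain-Python single event used for
fine-grained inspection and cross-validation of the event law.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

from . import _kernel
from .hex_lattice import (
    LatticeGeometry,
    neighbour_table,
    site_coordinates,
    xy_to_site,
)

__all__ = [
    "Phase",
    "ModelParams",
    "SimConfig",
    "SimState",
    "TrajectoryRecord",
    "SimResult",
    "init_from_positions",
    "init_random_strips",
    "gillespie_step",
    "simulate",
    "select_tracked_cells",
]

logger = logging.getLogger(__name__)


class Phase(IntEnum):
    """FUCCI cell-cycle phase: red = G1, yellow = eS, green = S/G2/M."""

    RED = 0
    YELLOW = 1
    GREEN = 2

    @classmethod
    def from_name(cls, name: str) -> "Phase":
        return cls[name.strip().upper()]

    @property
    def colour(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class ModelParams:
    """Transition and motility rates θ = (R_r, R_y, R_g, M_r, M_y, M_g), h^-1."""

    r_red: float
    r_yellow: float
    r_green: float
    m_red: float
    m_yellow: float
    m_green: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.as_array()):
            raise ValueError("all rates must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.r_red, self.r_yellow, self.r_green,
             self.m_red, self.m_yellow, self.m_green],
            dtype=np.float64,
        )

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "ModelParams":
        r_r, r_y, r_g, m_r, m_y, m_g = (float(v) for v in theta)
        return cls(r_r, r_y, r_g, m_r, m_y, m_g)

    def transition_rate(self, phase: Phase) -> float:
        return self.as_array()[int(phase)]

    def motility_rate(self, phase: Phase) -> float:
        return self.as_array()[3 + int(phase)]

    def diffusivity(self, phase: Phase, delta: float = 20.0) -> float:
        """Cell diffusivity D = M Δ² / 4 (μm²/h) for a free random walker."""
        return self.motility_rate(phase) * delta**2 / 4.0


@dataclass(frozen=True)
class SimConfig:
    """Run settings: duration (h), RNG seed and which agents to track."""

    duration: float = 48.0
    seed: int = 0
    tracked_ids: tuple[int, ...] = ()
    record_events: bool = True

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


class SimState:
    """Occupancy-exclusive agent configuration on the lattice at one time.

    Stores flat site indices per agent plus the inverse occupancy map;
    the exclusion property (one agent per site) is enforced by
    construction and checked by :meth:`validate`.
    """

    def __init__(
        self,
        geom: LatticeGeometry,
        agent_site: np.ndarray,
        agent_phase: np.ndarray,
        time: float = 0.0,
    ) -> None:
        self.geom = geom
        self.agent_site = np.asarray(agent_site, dtype=np.int32)
        self.agent_phase = np.asarray(agent_phase, dtype=np.int8)
        self.time = float(time)
        self.n_omitted = 0
        occ = np.full(geom.n_sites, -1, dtype=np.int32)
        if len(self.agent_site) != len(set(self.agent_site.tolist())):
            raise ValueError("exclusion violated: duplicate sites in initial state")
        occ[self.agent_site] = np.arange(len(self.agent_site), dtype=np.int32)
        self.occupancy = occ

    @property
    def n_agents(self) -> int:
        return len(self.agent_site)

    def phase_counts(self) -> tuple[int, int, int]:
        c = np.bincount(self.agent_phase, minlength=3)
        return int(c[0]), int(c[1]), int(c[2])

    def positions_xy(self) -> tuple[np.ndarray, np.ndarray]:
        x, y = site_coordinates(self.geom)
        return x[self.agent_site], y[self.agent_site]

    def copy(self) -> "SimState":
        st = SimState(self.geom, self.agent_site.copy(), self.agent_phase.copy(), self.time)
        st.n_omitted = self.n_omitted
        return st

    def validate(self) -> None:
        """Assert the exclusion and occupancy bookkeeping invariants."""
        assert len(np.unique(self.agent_site)) == self.n_agents
        assert np.all(self.agent_site >= 0) and np.all(self.agent_site < self.geom.n_sites)
        ids = np.flatnonzero(self.occupancy >= 0)
        assert len(ids) == self.n_agents
        assert np.array_equal(np.sort(self.agent_site), ids)


@dataclass
class TrajectoryRecord:
    """Path of one tracked cell: (time, position, phase) at every successful
    move and phase change, starting from its position at t = 0.  Tracking
    stops when the cell divides (returns to red) or the run ends."""

    agent_id: int
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phases: np.ndarray
    termination: str  # "divided" | "simulation_end"

    def phase_path_lengths(self, delta: float | None = None) -> np.ndarray:
        """Path length (μm) accumulated in each phase, from consecutive
        inter-position Euclidean distances (Δ per lattice move)."""
        out = np.zeros(3)
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        step = np.hypot(dx, dy)
        # distance of each step is spent in the phase held before the event
        for k in range(len(step)):
            out[self.phases[k]] += step[k]
        return out


@dataclass
class SimResult:
    """Final configuration, tracked-cell records and event-count log."""

    state: SimState
    records: list[TrajectoryRecord]
    phase_distances: np.ndarray  # (n_tracked, 3) path length per phase, μm
    log: dict = field(default_factory=dict)


def init_from_positions(
    cells: Sequence[tuple[tuple[float, float], Phase]],
    geom: LatticeGeometry,
) -> SimState:
    """Snap (x, y, phase) cell records onto the lattice.

    Later cells mapping onto an already-occupied site are duplicates of
    the same site (the experimental tables resolve < 1% of cells this
    way) and are omitted, as are cells snapping outside the domain; the
    omission count is logged and kept on the returned state.
    """
    sites: list[int] = []
    phases: list[int] = []
    seen: set[int] = set()
    n_dup = 0
    n_out = 0
    for (x, y), phase in cells:
        try:
            i, j = xy_to_site((x, y), geom)
        except ValueError:
            n_out += 1
            continue
        s = geom.site_index(i, j)
        if s in seen:
            n_dup += 1
            continue
        seen.add(s)
        sites.append(s)
        phases.append(int(phase))
    if cells and not sites:
        raise ValueError("all cells fall outside the lattice domain")
    if n_dup or n_out:
        logger.info("omitted %d duplicate-site and %d out-of-domain cells", n_dup, n_out)
    state = SimState(geom, np.array(sites, dtype=np.int32), np.array(phases, dtype=np.int8))
    state.n_omitted = n_dup + n_out
    return state


def init_random_strips(
    counts: tuple[int, int, int],
    strip_width: float,
    geom: LatticeGeometry,
    seed: int | np.random.Generator = 0,
) -> SimState:
    """Seed agents uniformly at random in two vertical strips.

    Mimics the scratch-assay initial condition: ``strip_width`` μm of
    confluent-ish monolayer abutting the left and right edges of the
    imaged region, with the scratch (empty gap) in between.  Phase
    labels are assigned uniformly at random in exactly the requested
    red/yellow/green counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_red, n_yellow, n_green = counts
    total = n_red + n_yellow + n_green
    x, _ = site_coordinates(geom)
    strip_sites = np.flatnonzero((x <= strip_width) | (x >= geom.width - strip_width))
    if total > len(strip_sites):
        raise ValueError(
            f"{total} agents do not fit in {len(strip_sites)} strip sites"
        )
    chosen = rng.choice(strip_sites, size=total, replace=False).astype(np.int32)
    phases = np.repeat(np.array([0, 1, 2], dtype=np.int8), [n_red, n_yellow, n_green])
    phases = rng.permutation(phases)
    return SimState(geom, chosen, phases)


def _total_rate(state: SimState, params: ModelParams) -> float:
    counts = np.bincount(state.agent_phase, minlength=3)
    rates = params.as_array()
    return float(np.sum(counts * (rates[:3] + rates[3:])))


def gillespie_step(
    state: SimState, params: ModelParams, rng: np.random.Generator
) -> tuple[str, float]:
    """Draw and apply a single Gillespie event in place.

    Returns the event outcome and the waiting time Δt ~ Exp(Λ).  With a
    total rate of zero no further event can occur: returns
    ``("none", inf)`` and leaves the state untouched (the caller jumps
    to the end time).
    """
    lam = _total_rate(state, params)
    if lam <= 0.0:
        return "none", math.inf
    dt = rng.exponential(1.0 / lam)
    state.time += dt
    rates = params.as_array()
    weights = rates[:3] + rates[3:]
    agent_w = weights[state.agent_phase]
    aid = int(rng.choice(state.n_agents, p=agent_w / agent_w.sum()))
    p = int(state.agent_phase[aid])
    nbr = neighbour_table(state.geom)

    if rng.random() * weights[p] < rates[3 + p]:
        d = int(rng.integers(6))
        tgt = int(nbr[state.agent_site[aid], d])
        if tgt >= 0 and state.occupancy[tgt] < 0:
            state.occupancy[state.agent_site[aid]] = -1
            state.occupancy[tgt] = aid
            state.agent_site[aid] = np.int32(tgt)
            return "move", dt
        return "move_blocked", dt
    if p < int(Phase.GREEN):
        state.agent_phase[aid] = np.int8(p + 1)
        return "transition", dt
    d = int(rng.integers(6))
    tgt = int(nbr[state.agent_site[aid], d])
    if tgt >= 0 and state.occupancy[tgt] < 0:
        state.agent_site = np.append(state.agent_site, np.int32(tgt))
        state.agent_phase = np.append(state.agent_phase, np.int8(Phase.RED))
        state.occupancy[tgt] = state.n_agents - 1
        state.agent_phase[aid] = np.int8(Phase.RED)
        return "division", dt
    return "division_blocked", dt


def simulate(state: SimState, params: ModelParams, config: SimConfig) -> SimResult:
    """Run the exclusion process from ``state`` for ``config.duration`` hours.

    The input state is not modified.  Bit-reproducible for a given
    (seed, params, initial state): a single RNG stream drives every
    draw.  Tracked agents (``config.tracked_ids``) accumulate per-phase
    path lengths and, when ``record_events`` is set, full
    :class:`TrajectoryRecord` event lists.
    """
    geom = state.geom
    cap = geom.n_sites
    agent_site = np.empty(cap, dtype=np.int32)
    agent_phase = np.empty(cap, dtype=np.int8)
    n0 = state.n_agents
    agent_site[:n0] = state.agent_site
    agent_phase[:n0] = state.agent_phase

    track_ids = np.asarray(config.tracked_ids, dtype=np.int64)
    n_tracks = len(track_ids)
    track_slot = np.full(cap, -1, dtype=np.int32)
    for slot, aid in enumerate(track_ids):
        if not 0 <= aid < n0:
            raise ValueError(f"tracked id {aid} not in initial state")
        track_slot[aid] = slot

    rates = params.as_array()
    # generous per-track record budget: attempts are Poisson(M*T), M <= 10/h
    rec_cap = int(n_tracks * (rates[3:].max() * config.duration * 1.5 + 64)) if n_tracks else 0

    occ = np.full(cap, -1, dtype=np.int32)
    occ[agent_site[:n0]] = np.arange(n0, dtype=np.int32)

    (
        n_final,
        t_final,
        phase_dist,
        track_divided,
        rec_n,
        rec_slot,
        rec_t,
        rec_site,
        rec_phase,
        counters,
    ) = _kernel.run_gillespie(
        occ,
        agent_site,
        agent_phase,
        n0,
        neighbour_table(geom),
        rates,
        float(state.time),
        float(state.time) + config.duration,
        int(config.seed) & 0x7FFFFFFF,
        track_slot,
        n_tracks,
        geom.delta,
        bool(config.record_events and n_tracks),
        rec_cap,
    )
    if counters[_kernel.RECORD_OVERFLOW]:
        logger.warning("trajectory record capacity exceeded; %d events dropped",
                       counters[_kernel.RECORD_OVERFLOW])

    final = SimState(geom, agent_site[:n_final].copy(), agent_phase[:n_final].copy(), t_final)
    final.n_omitted = state.n_omitted

    x_all, y_all = site_coordinates(geom)
    records: list[TrajectoryRecord] = []
    if n_tracks and config.record_events:
        for slot, aid in enumerate(track_ids):
            sel = rec_slot == slot
            t_ev = np.concatenate(([state.time], rec_t[sel]))
            s_ev = np.concatenate(
                ([state.agent_site[aid]], rec_site[sel])
            ).astype(np.int64)
            p_ev = np.concatenate(
                ([state.agent_phase[aid]], rec_phase[sel])
            ).astype(np.int8)
            records.append(
                TrajectoryRecord(
                    agent_id=int(aid),
                    times=t_ev,
                    x=x_all[s_ev],
                    y=y_all[s_ev],
                    phases=p_ev,
                    termination="divided" if track_divided[slot] else "simulation_end",
                )
            )

    log = {
        "n_events": int(counters[_kernel.N_EVENTS]),
        "move_attempts": int(counters[_kernel.MOVE_ATTEMPTS]),
        "move_successes": int(counters[_kernel.MOVE_SUCCESSES]),
        "red_to_yellow": int(counters[_kernel.RED_TO_YELLOW]),
        "yellow_to_green": int(counters[_kernel.YELLOW_TO_GREEN]),
        "division_attempts": int(counters[_kernel.DIVISION_ATTEMPTS]),
        "division_successes": int(counters[_kernel.DIVISION_SUCCESSES]),
    }
    return SimResult(
        state=final,
        records=records,
        phase_distances=phase_dist[:n_tracks].copy() if n_tracks else phase_dist[:0],
        log=log,
    )


def select_tracked_cells(state: SimState, n_cells: int, geom: LatticeGeometry) -> np.ndarray:
    """Pick up to ``n_cells`` red leading-edge agents for trajectory tracking.

    A red agent is on the leading edge when no agent in its lattice row
    lies strictly between it and the vertical midline of the imaged
    region (its path toward the scratch is unhindered).  When more
    qualify than requested, the ones nearest the midline win (ties by
    row index); when fewer qualify a warning is logged and all are
    returned.
    """
    if not np.any(state.agent_phase == int(Phase.RED)):
        raise ValueError("no red agents to track")
    x, _ = state.positions_xy()
    rows = state.agent_site // geom.n_cols  # 0-based row per agent
    mid = geom.midline_x

    eligible: list[tuple[float, int, int]] = []
    for aid in np.flatnonzero(state.agent_phase == int(Phase.RED)):
        same_row = np.flatnonzero(rows == rows[aid])
        lo, hi = min(x[aid], mid), max(x[aid], mid)
        blocked = np.any((x[same_row] > lo) & (x[same_row] < hi))
        if not blocked:
            eligible.append((abs(x[aid] - mid), int(rows[aid]), int(aid)))
    eligible.sort()
    if len(eligible) < n_cells:
        logger.warning(
            "only %d leading-edge red cells available (%d requested)",
            len(eligible), n_cells,
        )
    return np.array([aid for _, _, aid in eligible[:n_cells]], dtype=np.int64)
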