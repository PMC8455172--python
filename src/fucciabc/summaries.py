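"""Summary statistics of a scratch-assay configuration and the ABC discrepancy.

Three selectable blocks, matching what can be read off the processed
microscopy data:

* ``counts``      — number of red/yellow/green cells at the end of the
  experiment (informative about the transition rates);
* ``trajectory``  — mean path length (μm) travelled through the red,
  yellow and green phase by the tracked cells (informative about the
  motility rates);
* ``density``     — median and interquartile range of the x-positions of
  each colour on the left and right halves of the imaged region
  (12 numbers; the cheaper but weakly informative alternative).

The ABC discrepancy is the plain (unweighted) Euclidean norm over the
concatenated blocks present in both vectors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .hex_lattice import LatticeGeometry
from .simulator import SimState, TrajectoryRecord

__all__ = [
    "SummaryVector",
    "count_summaries",
    "trajectory_summaries",
    "density_summaries",
    "summarise",
    "discrepancy",
    "write_summary_csv",
    "read_summary_csv",
    "SUMMARY_COLUMNS",
]

#: CSV column names for the full 18-number vector (S7..S12 are pairs)
SUMMARY_COLUMNS = {
    "counts": ["S1", "S2", "S3"],
    "trajectory": ["S4", "S5", "S6"],
    "density": [
        "S7_L", "S7_R", "S8_L", "S8_R", "S9_L", "S9_R",
        "S10_L", "S10_R", "S11_L", "S11_R", "S12_L", "S12_R",
    ],
}


@dataclass(frozen=True)
class SummaryVector:
    """Selected summary blocks; ``None`` means the block is not used.

    A density block containing NaN (a colour absent on one side) marks
    the vector invalid and any discrepancy against it is +inf.
    """

    counts: tuple[int, int, int] | None = None
    trajectory: tuple[float, float, float] | None = None
    density: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.counts is None and self.trajectory is None and self.density is None:
            raise ValueError("at least one summary block is required")
        if self.density is not None and len(self.density) != 12:
            raise ValueError("density block must hold 12 numbers")

    @property
    def blocks(self) -> tuple[str, ...]:
        out = []
        if self.counts is not None:
            out.append("counts")
        if self.trajectory is not None:
            out.append("trajectory")
        if self.density is not None:
            out.append("density")
        return tuple(out)

    @property
    def valid(self) -> bool:
        return bool(np.all(np.isfinite(self.concat())))

    def concat(self) -> np.ndarray:
        parts = [
            np.asarray(getattr(self, b), dtype=np.float64) for b in self.blocks
        ]
        return np.concatenate(parts)

    def column_names(self) -> list[str]:
        out: list[str] = []
        for b in self.blocks:
            out.extend(SUMMARY_COLUMNS[b])
        return out


def count_summaries(state: SimState) -> tuple[int, int, int]:
    """Number of red, yellow and green agents (S1-S3)."""
    return state.phase_counts()


def trajectory_summaries(
    records: Sequence[TrajectoryRecord] | np.ndarray,
    delta: float | None = None,
) -> tuple[float, float, float]:
    """Mean path length (μm) through each phase over the tracked cells (S4-S6).

    Accepts either :class:`TrajectoryRecord` objects or a pre-computed
    ``(n_cells, 3)`` array of per-cell per-phase path lengths.  A phase a
    cell never entered before dividing (or before the run ended)
    contributes zero for that cell, and the cell still counts in the
    mean's denominator.
    """
    if isinstance(records, np.ndarray):
        dist = np.asarray(records, dtype=np.float64)
        if dist.ndim != 2 or dist.shape[1] != 3:
            raise ValueError("distance array must have shape (n_cells, 3)")
    else:
        if len(records) == 0:
            raise ValueError("at least one trajectory record is required")
        dist = np.stack([r.phase_path_lengths() for r in records])
    if dist.shape[0] == 0:
        raise ValueError("at least one trajectory record is required")
    mean = dist.mean(axis=0)
    return float(mean[0]), float(mean[1]), float(mean[2])


def density_summaries(state: SimState, geom: LatticeGeometry) -> tuple[float, ...]:
    """Median and IQR of x-positions per colour per side (S7-S12, 12 numbers).

    The imaged region is split down the vertical midline; order is
    medians (red L, R; yellow L, R; green L, R) then IQRs in the same
    order.  Quartiles use linear interpolation.  A colour absent on a
    side yields NaN entries, flagging the vector invalid.
    """
    x, _ = state.positions_xy()
    mid = geom.midline_x
    medians: list[float] = []
    iqrs: list[float] = []
    for phase in (0, 1, 2):
        for side in ("left", "right"):
            mask = (state.agent_phase == phase) & ((x < mid) if side == "left" else (x >= mid))
            xs = x[mask]
            if xs.size == 0:
                medians.append(float("nan"))
                iqrs.append(float("nan"))
            else:
                medians.append(float(np.median(xs)))
                q1, q3 = np.percentile(xs, [25.0, 75.0])
                iqrs.append(float(q3 - q1))
    return tuple(medians + iqrs)


def summarise(
    state: SimState,
    geom: LatticeGeometry,
    blocks: Sequence[str],
    phase_distances: np.ndarray | None = None,
    records: Sequence[TrajectoryRecord] | None = None,
) -> SummaryVector:
    """Assemble the requested summary blocks from a simulation endpoint.

    The trajectory block needs either the per-cell per-phase distance
    array produced by :func:`fucciabc.simulator.simulate` or the full
    trajectory records.
    """
    kwargs: dict = {}
    for b in blocks:
        if b == "counts":
            kwargs["counts"] = count_summaries(state)
        elif b == "trajectory":
            source = phase_distances if phase_distances is not None else records
            if source is None:
                raise ValueError("trajectory block requested but no tracked-cell data given")
            kwargs["trajectory"] = trajectory_summaries(source)
        elif b == "density":
            kwargs["density"] = density_summaries(state, geom)
        else:
            raise ValueError(f"unknown summary block {b!r}")
    return SummaryVector(**kwargs)


def discrepancy(s_sim: SummaryVector, s_obs: SummaryVector) -> float:
    """ABC discrepancy ρ = ||S_sim - S_obs||₂ over the shared block structure.

    Vectors must carry the same blocks; an invalid vector (NaN density
    entry) gives ρ = +inf so the configuration is always rejected.
    """
    if s_sim.blocks != s_obs.blocks:
        raise ValueError(f"summary blocks differ: {s_sim.blocks} vs {s_obs.blocks}")
    a, b = s_sim.concat(), s_obs.concat()
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        return float("inf")
    return float(np.linalg.norm(a - b))


def write_summary_csv(path, vectors: Iterable[SummaryVector]) -> None:
    """One row per simulation, named columns (S1..S12 subset), UTF-8, '.' decimal."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("nothing to write")
    cols = vectors[0].column_names()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for v in vectors:
            if v.column_names() != cols:
                raise ValueError("inconsistent summary blocks between rows")
            w.writerow([repr(float(u)) for u in v.concat()])


def read_summary_csv(path) -> list[SummaryVector]:
    """Inverse of :func:`write_summary_csv` (block structure inferred from header)."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    header, data = rows[0], rows[1:]
    out = []
    for row in data:
        vals = dict(zip(header, (float(v) for v in row)))
        kwargs = {}
        if set(SUMMARY_COLUMNS["counts"]) <= set(header):
            kwargs["counts"] = tuple(int(vals[c]) for c in SUMMARY_COLUMNS["counts"])
        if set(SUMMARY_COLUMNS["trajectory"]) <= set(header):
            kwargs["trajectory"] = tuple(vals[c] for c in SUMMARY_COLUMNS["trajectory"])
        if set(SUMMARY_COLUMNS["density"]) <= set(header):
            kwargs["density"] = tuple(vals[c] for c in SUMMARY_COLUMNS["density"])
        out.append(SummaryVector(**kwargs))
    return out
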