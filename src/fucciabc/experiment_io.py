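"""Ingestion of processed experimental exports and tabular interchange.

The upstream image-analysis pipeline (segmentation and centroid
extraction of the fluorescence frames) produces flat tables of cell
coordinates, either already phase-labelled or carrying mean RGB channel
values.  This module classifies phases from RGB codes, snaps coordinates
onto the simulation lattice (dropping the rare duplicate-site records),
matches manually tracked trajectory starts to occupied sites, and reads
and writes the package's CSV dialects (UTF-8, header row, '.' decimal):

* positions:    ``x_um, y_um, phase``            phase ∈ {red, yellow, green}
* RGB:          ``x_um, y_um, red, green``       channels 0-255
* trajectories: ``cell_id, t_h, x_um, y_um, phase``
* summaries:    named columns ``S1 .. S12_R`` (see :mod:`.summaries`)
* populations:  ``R_r .. M_g, rho`` plus the summary columns
"""

from __future__ import annotations

import csv
import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .hex_lattice import LatticeGeometry, site_coordinates
from .simulator import Phase, SimState, TrajectoryRecord, init_from_positions
from .smc_abc import SMCResult
from .summaries import SummaryVector, read_summary_csv, summarise

__all__ = [
    "RGBRecord",
    "classify_phase_rgb",
    "read_positions_csv",
    "write_positions_csv",
    "read_rgb_csv",
    "load_observed",
    "snap_trajectory_starts",
    "write_trajectory_csv",
    "write_population_csv",
]

logger = logging.getLogger(__name__)


class RGBRecord(NamedTuple):
    """One segmented cell centroid with its mean fluorescence channels."""

    x: float
    y: float
    red: float
    green: float


def classify_phase_rgb(rec: RGBRecord) -> Phase | None:
    """FUCCI phase from RGB decimal codes.

    red > 100 and green ≤ 100 → G1 (red); red > 100 and green > 100 →
    eS (yellow); red ≤ 100 and green > 100 → S/G2/M (green).  Anything
    else (both channels dim) is unclassifiable and returns None.
    """
    if not (0 <= rec.red <= 255 and 0 <= rec.green <= 255):
        raise ValueError(f"RGB channels outside [0, 255]: {rec}")
    if rec.red > 100 and rec.green <= 100:
        return Phase.RED
    if rec.red > 100 and rec.green > 100:
        return Phase.YELLOW
    if rec.red <= 100 and rec.green > 100:
        return Phase.GREEN
    return None


def _read_rows(path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty file")
    return [h.strip() for h in rows[0]], rows[1:]


def read_positions_csv(path) -> list[tuple[tuple[float, float], Phase]]:
    """Phase-labelled cell table: columns ``x_um, y_um, phase``."""
    header, rows = _read_rows(path)
    try:
        ix, iy, ip = header.index("x_um"), header.index("y_um"), header.index("phase")
    except ValueError as exc:
        raise ValueError(f"{path}: expected columns x_um, y_um, phase") from exc
    cells = []
    for k, row in enumerate(rows, start=2):
        try:
            cells.append(
                ((float(row[ix]), float(row[iy])), Phase.from_name(row[ip]))
            )
        except (ValueError, KeyError, IndexError) as exc:
            raise ValueError(f"{path}: cannot parse row {k}: {row}") from exc
    return cells


def write_positions_csv(path, state: SimState) -> None:
    """Write a lattice configuration as a positions table."""
    x, y = state.positions_xy()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["x_um", "y_um", "phase"])
        for k in range(state.n_agents):
            w.writerow([repr(float(x[k])), repr(float(y[k])),
                        Phase(int(state.agent_phase[k])).colour])


def read_rgb_csv(path) -> list[RGBRecord]:
    """Centroid + channel table: columns ``x_um, y_um, red, green``."""
    header, rows = _read_rows(path)
    try:
        idx = [header.index(c) for c in ("x_um", "y_um", "red", "green")]
    except ValueError as exc:
        raise ValueError(f"{path}: expected columns x_um, y_um, red, green") from exc
    out = []
    for k, row in enumerate(rows, start=2):
        try:
            out.append(RGBRecord(*(float(row[i]) for i in idx)))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: cannot parse row {k}: {row}") from exc
    return out


def _cells_from_file(path) -> list[tuple[tuple[float, float], Phase]]:
    header, _ = _read_rows(path)
    if "phase" in header:
        return read_positions_csv(path)
    if "red" in header and "green" in header:
        records = read_rgb_csv(path)
        cells = []
        n_dropped = 0
        for rec in records:
            phase = classify_phase_rgb(rec)
            if phase is None:
                n_dropped += 1
            else:
                cells.append(((rec.x, rec.y), phase))
        if n_dropped:
            logger.warning("%s: dropped %d unclassifiable RGB records", path, n_dropped)
        return cells
    raise ValueError(f"{path}: neither a positions nor an RGB table")


def load_observed(
    initial_path,
    geom: LatticeGeometry,
    summary_path=None,
    final_path=None,
    blocks: Sequence[str] = ("counts", "trajectory"),
) -> tuple[SimState, SummaryVector]:
    """Build the observed dataset for inference from processed exports.

    The initial frame (positions or RGB table) is classified and snapped
    onto the lattice (duplicate-site cells omitted).  The observed
    summary vector comes either from a summary CSV or is computed from a
    final-frame cell table (counts and density blocks only — trajectory
    summaries cannot be derived from a single frame).
    """
    initial = init_from_positions(_cells_from_file(initial_path), geom)
    if summary_path is not None:
        vectors = read_summary_csv(summary_path)
        if len(vectors) != 1:
            raise ValueError(f"{summary_path}: expected exactly one summary row")
        observed = vectors[0]
    elif final_path is not None:
        if "trajectory" in blocks:
            raise ValueError("trajectory summaries cannot be computed from a final frame")
        final = init_from_positions(_cells_from_file(final_path), geom)
        observed = summarise(final, geom, blocks)
    else:
        raise ValueError("provide either summary_path or final_path")
    return initial, observed


def snap_trajectory_starts(
    points: Sequence[tuple[float, float]], state: SimState
) -> list[tuple[int, int]]:
    """Match manually tracked starting coordinates to occupied sites.

    Manual clicks are rarely centred on the cell, so each point maps to
    the *occupied* lattice site minimising the Euclidean distance to it;
    exact ties break by (row, column) lexicographic order.
    """
    if state.n_agents == 0:
        raise ValueError("state holds no agents")
    x, y = site_coordinates(state.geom)
    occ_sites = np.sort(state.agent_site)  # sorted flat index == (i, j) lexicographic
    ox, oy = x[occ_sites], y[occ_sites]
    out = []
    for px, py in points:
        d2 = (ox - px) ** 2 + (oy - py) ** 2
        best = occ_sites[int(np.argmin(d2))]  # argmin returns first == smallest (i, j)
        out.append(state.geom.site_ij(int(best)))
    return out


def write_trajectory_csv(path, records: Sequence[TrajectoryRecord]) -> None:
    """Tracked-cell paths: columns ``cell_id, t_h, x_um, y_um, phase``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "t_h", "x_um", "y_um", "phase"])
        for rec in records:
            for k in range(len(rec.times)):
                w.writerow([
                    rec.agent_id,
                    repr(float(rec.times[k])),
                    repr(float(rec.x[k])),
                    repr(float(rec.y[k])),
                    Phase(int(rec.phases[k])).colour,
                ])


def write_population_csv(path, result: SMCResult, summary_names: Sequence[str]) -> None:
    """Particle population with discrepancies and stored summaries."""
    df = pd.DataFrame(result.theta, columns=list(result.param_names))
    df["rho"] = result.rho
    for k, name in enumerate(summary_names):
        df[name] = result.s_sim[:, k]
    df.to_csv(path, index=False)
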