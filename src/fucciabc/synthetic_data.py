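"""Synthetic scratch-assay datasets with known parameters.

Generates "observed" data surrogates by running the lattice model under
a chosen rate vector from scratch-assay initial conditions: two seeded
strips of cells flanking an empty gap, with the initial red/yellow/green
counts of the WM983C experiment.  These datasets drive the
parameter-recovery studies (can SMC-ABC find the generating rates?) and
the summary-statistic identifiability comparison (cell-count +
trajectory summaries versus cell-count + density summaries).

A "desk" geometry — the imaged region scaled by 1/3 in each direction
with cell counts scaled by area — is provided so recovery studies run in
minutes rather than hours; conclusions at that scale carry the usual
caveat of smaller, noisier summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import wm983c
from .hex_lattice import LatticeGeometry
from .simulator import (
    ModelParams,
    SimConfig,
    SimResult,
    SimState,
    init_random_strips,
    select_tracked_cells,
    simulate,
)
from .summaries import SummaryVector, summarise

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_synthetic_dataset",
    "builtin_configs",
    "desk_geometry",
    "desk_config",
    "make_simulator",
    "TRANSITION_STUDY_THETAS",
    "MOTILITY_STUDY_THETAS",
]

#: recovery-study rate vectors varying the transition rates at fixed motility
TRANSITION_STUDY_THETAS: tuple[tuple[float, ...], ...] = (
    (0.04, 0.17, 0.08, 4.0, 4.0, 4.0),
    (0.25, 0.15, 0.22, 4.0, 4.0, 4.0),
    (0.12, 0.07, 0.03, 4.0, 4.0, 4.0),
    (0.3, 0.36, 0.28, 4.0, 4.0, 4.0),
)

#: recovery-study rate vectors varying the motility rates over the prior range
MOTILITY_STUDY_THETAS: tuple[tuple[float, ...], ...] = (
    (0.04, 0.17, 0.08, 4.0, 4.0, 4.0),
    (0.04, 0.17, 0.08, 2.0, 5.0, 8.0),
    (0.04, 0.17, 0.08, 8.0, 2.0, 5.0),
    (0.04, 0.17, 0.08, 5.0, 8.0, 2.0),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the experimental setting: the full imaged region,
    200 μm seeded strips, 119/35/121 initial red/yellow/green cells,
    48 h duration and 20 tracked leading-edge red cells.
    """

    theta_true: ModelParams
    geom: LatticeGeometry = field(default_factory=wm983c.full_geometry)
    strip_width: float = wm983c.STRIP_WIDTH_UM
    counts: tuple[int, int, int] = wm983c.INITIAL_COUNTS
    duration: float = 48.0
    n_tracked: int = 20
    blocks: tuple[str, ...] = ("counts", "trajectory")
    seed: int = 0
    name: str = ""


@dataclass
class SyntheticDataset:
    """A generated dataset: the initial state, the simulated outcome and
    the observed summary vector under the configured blocks."""

    config: SyntheticConfig
    initial_state: SimState
    tracked_ids: np.ndarray
    result: SimResult
    observed: SummaryVector

    @property
    def final_state(self) -> SimState:
        return self.result.state

    def summary(self, blocks: Sequence[str]) -> SummaryVector:
        """The same realisation summarised under a different block choice."""
        return summarise(
            self.final_state,
            self.config.geom,
            blocks,
            phase_distances=self.result.phase_distances,
        )


def generate_synthetic_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Simulate one observed-data surrogate; a pure function of the config.

    Cells are seeded uniformly at random in the two strips, up to
    ``n_tracked`` leading-edge red cells are selected for trajectory
    tracking (all eligible ones, with a warning, if fewer qualify), and
    the model is run for the configured duration under ``theta_true``.
    """
    rng = np.random.default_rng(config.seed)
    initial = init_random_strips(config.counts, config.strip_width, config.geom, rng)
    if config.n_tracked > 0 and config.counts[0] > 0:
        tracked = select_tracked_cells(initial, config.n_tracked, config.geom)
    else:
        tracked = np.array([], dtype=np.int64)
    sim_cfg = SimConfig(
        duration=config.duration,
        seed=int(rng.integers(2**31)),
        tracked_ids=tuple(int(a) for a in tracked),
    )
    result = simulate(initial, config.theta_true, sim_cfg)
    observed = summarise(
        result.state, config.geom, config.blocks,
        phase_distances=result.phase_distances,
    )
    return SyntheticDataset(
        config=config,
        initial_state=initial,
        tracked_ids=tracked,
        result=result,
        observed=observed,
    )


def builtin_configs() -> list[SyntheticConfig]:
    """The recovery-study configurations plus the experimental fixture.

    Four transition-varying and four motility-varying rate vectors on
    the experimental geometry, and one fixture at the reported
    posterior-mean rates of the WM983C dataset.
    """
    configs = [
        SyntheticConfig(
            theta_true=ModelParams.from_array(th), name=f"transition-{k + 1}"
        )
        for k, th in enumerate(TRANSITION_STUDY_THETAS)
    ]
    configs += [
        SyntheticConfig(
            theta_true=ModelParams.from_array(th), name=f"motility-{k + 1}"
        )
        for k, th in enumerate(MOTILITY_STUDY_THETAS)
    ]
    configs.append(
        SyntheticConfig(
            theta_true=wm983c.posterior_mean_params(), name="wm983c-fixture"
        )
    )
    return configs


def desk_geometry(scale: float = 1.0 / 3.0) -> LatticeGeometry:
    """The imaged region scaled down by ``scale`` in each direction."""
    return LatticeGeometry.from_extent(
        wm983c.IMAGED_WIDTH_UM * scale,
        wm983c.IMAGED_HEIGHT_UM * scale,
        wm983c.CELL_DIAMETER_UM,
    )


def desk_config(
    theta_true: ModelParams | Sequence[float],
    seed: int = 0,
    blocks: tuple[str, ...] = ("counts", "trajectory"),
    scale: float = 1.0 / 3.0,
    name: str = "",
) -> SyntheticConfig:
    """Reduced-geometry study conditions: linear dimensions scaled by
    ``scale``, seeded strip width and cell counts scaled accordingly
    (counts by area).  With the default 1/3 scale the initial counts
    become 13/4/13."""
    if not isinstance(theta_true, ModelParams):
        theta_true = ModelParams.from_array(theta_true)
    counts = tuple(int(round(c * scale**2)) for c in wm983c.INITIAL_COUNTS)
    return SyntheticConfig(
        theta_true=theta_true,
        geom=desk_geometry(scale),
        strip_width=wm983c.STRIP_WIDTH_UM * scale,
        counts=counts,  # type: ignore[arg-type]
        n_tracked=20,
        blocks=blocks,
        seed=seed,
        name=name or "desk",
    )


def make_simulator(
    initial_state: SimState,
    tracked_ids: Sequence[int],
    blocks: Sequence[str],
    duration: float = 48.0,
):
    """Model closure for the ABC sampler.

    Returns ``sim(theta, seed) -> SummaryVector``: one forward run of the
    lattice model from the fixed initial state (tracking the same cells
    as the observed data) summarised with the given blocks.
    """
    tracked = tuple(int(a) for a in tracked_ids)
    geom = initial_state.geom
    blocks = tuple(blocks)

    def sim(theta: np.ndarray, seed: int) -> SummaryVector:
        params = ModelParams.from_array(theta)
        cfg = SimConfig(
            duration=duration, seed=seed, tracked_ids=tracked, record_events=False
        )
        res = simulate(initial_state, params, cfg)
        return summarise(res.state, geom, blocks, phase_distances=res.phase_distances)

    return sim
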