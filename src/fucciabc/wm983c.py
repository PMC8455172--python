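"""Published reference values for the WM983C FUCCI melanoma scratch assay.

These are the printed inputs of the experimental study this package
models: the physical size of the imaged region, the processed initial
cell counts, the observed summary statistics at 48 h, and the reported
posterior estimates of the six model rates.  They let the experimental
inference and its posterior-predictive checks be rerun without access
to the raw microscopy images.
"""

from __future__ import annotations

import pandas as pd

from .hex_lattice import LatticeGeometry
from .simulator import ModelParams
from .summaries import SummaryVector

__all__ = [
    "IMAGED_WIDTH_UM",
    "IMAGED_HEIGHT_UM",
    "CELL_DIAMETER_UM",
    "STRIP_WIDTH_UM",
    "INITIAL_COUNTS",
    "OBSERVED_COUNTS",
    "OBSERVED_TRAJECTORY_UM",
    "OBSERVED_DENSITY_UM",
    "POSTERIOR_ESTIMATES",
    "full_geometry",
    "observed_summary",
    "posterior_mean_params",
]

#: imaged region of the scratch assay, μm
IMAGED_WIDTH_UM = 1309.09
IMAGED_HEIGHT_UM = 1745.35

#: mean WM983C cell diameter = lattice site spacing, μm
CELL_DIAMETER_UM = 20.0

#: width of the seeded monolayer strip on each side of the scratch, μm
STRIP_WIDTH_UM = 200.0

#: red/yellow/green cell counts segmented from the initial frame
INITIAL_COUNTS = (119, 35, 121)

#: S1-S3: red/yellow/green cell counts at 48 h
OBSERVED_COUNTS = (566, 111, 166)

#: S4-S6: mean distance (μm) travelled through each phase by 20 tracked cells
OBSERVED_TRAJECTORY_UM = (105.0, 40.0, 100.0)

#: S7-S12: median then IQR of x-positions (μm) per colour on the left and
#: right sides of the scratch (red L, R; yellow L, R; green L, R)
OBSERVED_DENSITY_UM = (
    155.0, 1170.0, 158.0, 1189.0, 177.0, 1129.0,
    196.0, 197.0, 164.0, 144.0, 213.0, 207.0,
)

#: reported posterior estimates (three significant figures) for
#: θ = (R_r, R_y, R_g, M_r, M_y, M_g), h^-1
POSTERIOR_ESTIMATES = pd.DataFrame(
    {
        "mean": [0.0411, 0.192, 0.193, 0.316, 0.514, 1.12],
        "sd": [0.00109, 0.0102, 0.00957, 0.0343, 0.0945, 0.169],
        "q2.5": [0.039, 0.173, 0.177, 0.256, 0.353, 0.836],
        "median": [0.0411, 0.191, 0.192, 0.313, 0.502, 1.10],
        "q97.5": [0.0432, 0.214, 0.213, 0.385, 0.725, 1.48],
        "cv_pct": [2.65, 5.31, 4.96, 10.9, 18.4, 15.1],
    },
    index=["R_r", "R_y", "R_g", "M_r", "M_y", "M_g"],
)


def full_geometry() -> LatticeGeometry:
    """Hexagonal lattice calibrated to the imaged region."""
    return LatticeGeometry.from_extent(
        IMAGED_WIDTH_UM, IMAGED_HEIGHT_UM, CELL_DIAMETER_UM
    )


def observed_summary(blocks=("counts", "trajectory")) -> SummaryVector:
    """Observed WM983C summary statistics restricted to the given blocks."""
    kwargs = {}
    for b in blocks:
        if b == "counts":
            kwargs["counts"] = OBSERVED_COUNTS
        elif b == "trajectory":
            kwargs["trajectory"] = OBSERVED_TRAJECTORY_UM
        elif b == "density":
            kwargs["density"] = OBSERVED_DENSITY_UM
        else:
            raise ValueError(f"unknown summary block {b!r}")
    return SummaryVector(**kwargs)


def posterior_mean_params() -> ModelParams:
    """Posterior-mean rate vector reported for the WM983C dataset."""
    return ModelParams.from_array(POSTERIOR_ESTIMATES["mean"].to_numpy())
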