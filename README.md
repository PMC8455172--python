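# fucciabc

Bayesian parameter estimation for a stochastic model of melanoma cell
invasion with FUCCI cell-cycle labelling.

In a scratch-assay experiment a gap is scratched into a monolayer of
WM983C melanoma cells, which then close it by migrating and
proliferating over 48 h.  FUCCI labelling colours each cell by
cell-cycle phase — red in G1, yellow in early S, green in S/G2/M — so
the experiment reveals, per cell, both movement and cycle progression.
`fucciabc` implements:

* **the simulation model**: an exclusion random walk on a hexagonal
  lattice (site spacing Δ = 20 μm, one agent per site).  Red, yellow
  and green agents attempt nearest-neighbour moves at per-phase
  motility rates M_r, M_y, M_g and progress through the cycle at
  transition rates R_r (red→yellow), R_y (yellow→green) and R_g
  (green→division into two red agents), with moves and divisions onto
  occupied sites aborted — crowding emerges from exclusion alone.
  Event scheduling is exact (Gillespie), compiled with numba.
* **the inference machinery**: sequential Monte Carlo approximate
  Bayesian computation (the replenishment algorithm) targeting
  π_ε(θ | S_obs) ∝ π(θ) P(‖S_sim − S_obs‖₂ ≤ ε) for
  θ = (R_r, R_y, R_g, M_r, M_y, M_g), with an adaptive rank-based
  tolerance schedule, a self-tuned multivariate-normal MCMC move
  kernel, stopping at 1% acceptance, and post-hoc weighted linear
  regression adjustment (Epanechnikov weights, logit-transformed
  parameters).
* **summary statistics** of three kinds: end-point cell counts per
  colour (informative about transition rates), mean distance travelled
  through each phase by tracked leading-edge cells (informative about
  motility rates), and per-side median/IQR cell-position profiles
  (cheaper, but leaves the motilities practically non-identifiable —
  reproducing that contrast is one of the package's test criteria).
* **synthetic-data generation** reproducing the scratch-assay initial
  conditions (seeded strips flanking a gap, counts 119/35/121) for
  parameter-recovery studies, plus ingestion of processed experimental
  exports (cell coordinate/RGB tables) and the published WM983C
  observed summaries.

Intended users: quantitative cell biologists and statisticians studying
collective cell migration, and anyone needing a worked, tested example
of SMC-ABC with regression adjustment on an agent-based model.

## Worked example

Recover known rates from a synthetic dataset at the reduced "desk"
scale (the 1309.09 × 1745.35 μm imaged region scaled by 1/3 per
dimension, initial counts 13/4/13):

```python
import numpy as np
from fucciabc import desk_config, generate_synthetic_dataset, make_simulator
from fucciabc.smc_abc import (PriorSpec, SMCConfig, run_smc_abc,
                              regression_adjust, posterior_summaries)

ds = generate_synthetic_dataset(
    desk_config((0.04, 0.17, 0.08, 4, 4, 4), seed=11)
)
sim = make_simulator(ds.initial_state, ds.tracked_ids, ds.config.blocks)
prior = PriorSpec.scratch_model()
res = run_smc_abc(ds.observed, sim, prior,
                  SMCConfig(n_particles=200, seed=7))
adj = regression_adjust(res.theta, res.s_sim, res.rho, ds.observed, prior)
print(posterior_summaries(adj).round(4))
```

Output (a few minutes; tens of thousands of model simulations):

```
       mean      sd    q2.5  median   q97.5   cv_pct
R_r  0.0422  0.0109  0.0228  0.0420  0.0714  25.8818
R_y  0.3159  0.1474  0.1274  0.2787  0.6464  46.6795
R_g  0.1292  0.0489  0.0544  0.1281  0.2469  37.8466
M_r  5.0959  1.6167  2.2825  4.9183  8.6947  31.7263
M_y  6.1536  1.8912  3.0191  6.1582  9.5771  30.7331
M_g  4.8816  2.0466  1.6347  4.4179  9.2180  41.9237
```

Each row is one rate's adjusted posterior: mean, standard deviation,
(2.5%, 50%, 97.5%) quantiles and the coefficient of variation in
percent.  All six generating values lie inside their 95% credible
intervals; the well-identified red-phase transition rate is recovered
almost exactly (median 0.0420 vs 0.04 h⁻¹), while the motility
marginals are wider — at one ninth of the experimental cell numbers the
trajectory summaries simply carry less information.  Forward
simulation at the published WM983C posterior-mean rates is a one-liner
sanity check:

```python
from fucciabc import wm983c, init_random_strips, simulate, SimConfig
geom = wm983c.full_geometry()
state = init_random_strips(wm983c.INITIAL_COUNTS, wm983c.STRIP_WIDTH_UM, geom, seed=1)
print(simulate(state, wm983c.posterior_mean_params(),
               SimConfig(duration=48.0, seed=2)).state.phase_counts())
# (588, 132, 167)   vs observed 48 h counts (566, 111, 166)
```

## Command line

A thin CLI wraps the library: `fucci-abc simulate | synth | infer |
adjust | predict | recover`, each taking `--config <yaml>`, `--seed`
and `--out <dir>`, and writing CSVs plus a `run_log.yaml` with the
package version and all resolved settings.  A minimal inference config:

```yaml
# infer.yaml — synthetic desk-scale recovery, count+trajectory summaries
blocks: [counts, trajectory]
synthetic:
  theta: [0.04, 0.17, 0.08, 4, 4, 4]   # generating rates, h^-1
  desk: true                            # 1/3-scale geometry, counts 13/4/13
smc:
  n_particles: 200
```

```sh
fucci-abc infer --config infer.yaml --seed 1 --out results/run1
```

For experimental data, replace `synthetic:` with an `observed:` section
pointing at a positions/RGB CSV for the initial frame and a summary CSV
(the WM983C observed summaries are available as
`fucciabc.wm983c.observed_summary()`).

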