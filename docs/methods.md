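# Methods

`fucciabc` couples a stochastic, agent-based model of melanoma cell
invasion in a scratch assay — with the cell cycle made visible through
FUCCI labelling — to a likelihood-free Bayesian inference pipeline.
This note records the model, the inference machinery, the numerical
conventions, and the choices made where the design was genuinely open.

## The lattice model

Cells are agents on a two-dimensional hexagonal lattice with
nearest-neighbour spacing Δ = 20 μm, the mean WM983C cell diameter.
Rows `i = 1..n_rows`, columns `j = 1..n_cols` (1-based) embed as

    x = (j − 1)Δ        (odd rows)      y = i · (√3/2) Δ
    x = (j − ½)Δ        (even rows)

so every interior site has six neighbours at Euclidean distance exactly
Δ — one lattice move is one cell diameter of travel.  (The half-offset
convention and the row/column roles admit several equivalent write-ups;
we fix the one in which the √3/2 compression acts on the row spacing,
since any other assignment breaks the equal-neighbour-distance property
that makes the lattice hexagonal in the first place.)  The lattice is
"calibrated" to an imaged region of width × height μm by taking the
largest grid whose site centres fit inside it; coordinates snap to
sites by rounding the row first (ties toward +∞), then the column under
that row's parity, which inverts the embedding exactly on every site
centre.

Each agent carries a FUCCI phase: **red** (G1), **yellow** (early S),
**green** (S/G2/M).  The six model parameters, all in h⁻¹, are

| parameter | meaning | prior |
|---|---|---|
| R_r | red → yellow cell-cycle transition rate | U(0, 1) |
| R_y | yellow → green transition rate | U(0, 1) |
| R_g | green → division rate | U(0, 1) |
| M_r, M_y, M_g | per-phase motility (move-attempt) rate | U(0, 10) |

Transition-rate priors cover reported melanoma doubling times (16–47 h,
with G1 residence 8–30 h and S/G2/M residence 8–17 h); motility priors
cover reported cell diffusivities up to ≈ 3300 μm² h⁻¹ through
D = M Δ²/4.

Dynamics are a continuous-time Markov process simulated exactly with
the Gillespie algorithm.  All rates are *attempt* rates: a movement
event picks one of the six directions uniformly and is aborted — time
still advances — if the target site is occupied or off-lattice; the
red→yellow and yellow→green transitions always succeed; a division
resets the green mother to red in place and puts a red daughter on a
uniformly drawn neighbour site, the whole event aborting if that site
is unavailable.  At most one agent ever occupies a site (exclusion),
which is the entire crowding mechanism.  The imaged-region boundary is
closed (attempts to leave are aborted), realising the zero-net-flux
boundary condition appropriate for a window into a uniform monolayer.

The production event loop (compiled with numba) selects a phase class
with probability ∝ n_p (M_p + R_p), an agent of that class uniformly,
then movement vs transition with probability M_p vs R_p — the same
Markov law as per-agent clocks, validated in the tests against the
single-agent analytic event ratios, the exponential sojourn laws, the
MSD = M Δ² t diffusion law and the low-density mean-field ODE

    dN_r/dt = 2 R_g N_g − R_r N_r
    dN_y/dt = R_r N_r − R_y N_y
    dN_g/dt = R_y N_y − R_g N_g .

One integer seed drives a single RNG stream, so a run is bit-reproducible
given (seed, parameters, initial state).

## Summary statistics

Three blocks, computable both from simulations and from processed
microscopy exports:

* **counts** — (N_r, N_y, N_g) at the end of the experiment (48 h).
* **trajectory** — the mean distance travelled through each phase by
  the tracked cells.  Tracked cells start red on the leading edge
  (no agent strictly between them and the scratch midline in their
  lattice row; when more qualify than requested, nearest the midline
  wins, ties by row).  Tracking ends at division (return to red) or at
  the end of the run.  "Distance" is cumulative path length — Δ per
  lattice move — not net displacement: the observed values
  (≈ 100 μm over 48 h at M ≈ 0.3 h⁻¹) match attempt-rate × duration ×
  Δ under crowding, which net displacement would undershoot by an
  order of magnitude.  A phase never entered contributes zero and the
  cell still counts in the denominator.
* **density** — median and interquartile range of x-positions per
  colour on each side of the midline (12 numbers; quartiles by linear
  interpolation).  A colour absent on a side marks the vector invalid
  and any discrepancy against it is +∞.

The ABC discrepancy is the plain Euclidean norm over the concatenated
blocks, with no rescaling — a deliberate design choice, since any
reweighting would change which summaries the fit privileges; with
count + trajectory summaries the trajectory entries
(hundreds of μm) consequently dominate the counts, and with
count + density both blocks are of order 10²−10³.

## SMC-ABC replenishment sampler

`run_smc_abc` targets π_ε(θ|S_obs) ∝ π(θ) P(‖S_sim − S_obs‖ ≤ ε):

1. N particles from the prior, one simulation each (infinite
   discrepancies redrawn); ε₁ = max ρ.
2. Each round: sort by ρ, discard the worst N_α = ⌊αN⌋, set ε_t to the
   rank-(N−N_α) discrepancy; refill discarded slots by resampling
   survivors with replacement; diversify every refilled particle with
   R_t ABC-MCMC iterations.  A proposal θ′ ~ MVN(θ, Σ) — Σ the
   survivors' empirical covariance, unscaled — is accepted iff it lies
   inside the prior support *and* one fresh simulation at θ′ meets ε_t
   (the Metropolis–Hastings ratio reduces to this indicator under a
   flat prior and symmetric kernel).  Out-of-support proposals are
   rejected without simulating; the current particle's stored ρ is
   never re-simulated.
3. R_t = ⌈log c / log(1 − p̄_acc)⌉ (clamped ≥ 1) with p̄_acc estimated
   from ⌈R_{t−1}/2⌉ pilot iterations; the first round uses R₀ = 10,
   i.e. 5 pilot iterations (R₀ is a free knob; any moderate value only
   affects the first pilot).  When the pilot estimate is already ≤
   f_acc the round ends there: the estimate comes from hundreds of
   proposals, the completed round would match it in expectation, and
   the sampler then stops by the acceptance rule either way — this
   saves roughly a quarter of all simulations.
4. Stop when the round's overall acceptance rate p̄_acc ≤ f_acc
   (default 1%) or ε_t ≤ ε_target (default 0 — unreachable for
   continuous summaries, so the acceptance rule is the operative one),
   or when an optional simulation budget runs out (the result is then
   flagged truncated).

Defaults N = 1000, α = 0.5, c = 0.01 follow the standard tuning of the
replenishment algorithm; the reduced-scale studies use N = 200.

**Regression adjustment** is applied once, post hoc, to the final
population (the classical post-hoc usage; adjusting earlier rounds
would spend effort on populations the sampler then discards).  Each parameter component is logit-transformed with its
prior bounds, θ̃ = log((θ−a)/(b−θ)); a weighted least-squares fit of θ̃
on (S_sim − S_obs) with Epanechnikov weights
w_i = 0.75(1 − (ρ_i/max ρ)²) gives β̂; the adjustment
θ̃* = θ̃ − (S_sim − S_obs)ᵀβ̂ is back-transformed, so adjusted draws stay
strictly inside the prior.  Values exactly on a bound are nudged by
10⁻¹² of the prior range before the logit; if all weights vanish (all ρ
equal) the fit falls back to uniform weights; rank-deficient designs
are resolved by pseudoinverse.  Weights use the final population's ρ;
duplicates are kept (deduplicating would distort the particle
approximation).

## Synthetic data and study scales

`generate_synthetic_dataset` emulates the scratch-assay initial
condition: cells seeded uniformly at random (without replacement) on
the sites of two strips abutting the left and right edges of the
imaged region — 200 μm wide in the full 1309.09 × 1745.35 μm geometry —
with phase labels assigned at random in exactly the configured
red/yellow/green counts (119/35/121 by default), then simulated 48 h
under a known rate vector with 20 tracked leading-edge red cells.  The
built-in recovery studies use two families of four rate vectors:
transition-varying at fixed motility 4 h⁻¹, and motility-varying at
fixed transitions (0.04, 0.17, 0.08) h⁻¹.

What the generator does *not* emulate: the spatial clustering of a real
confluent monolayer (cells are seeded uniformly within the strips), the
segmentation and tracking errors of the imaging pipeline, fluorescence-
negative gaps between green and red, or any influx across the imaged
boundary.  The uniform-strip surrogate matters quantitatively: at the
reported posterior-mean rates it yields a few percent more cells at
48 h than the experiment recorded, because the real (clustered) initial
configuration self-crowds more strongly — posterior-predictive checks
against experimental counts inherit that offset, and passing synthetic
recovery tests therefore demonstrate correctness of model + sampler,
not image-pipeline realism.

The **desk geometry** scales the imaged region by 1/3 per dimension
(≈ 1/9 area), seeded counts by area (13/4/13) and the strip width by
1/3, keeping Δ, the 48 h duration and the request for 20 tracked cells
(typically only ~10–12 red cells qualify at this scale; all are used).
Reduced-scale posteriors are genuinely wider and mildly attenuated
toward the prior mean for the weakly identified motilities — the
summaries carry ~9× fewer cells — which is the expected cost of the
scaled-down design, not a sampler defect: the same pipeline run longer
(lower f_acc) or larger recovers tighter, better-centred marginals.
The default test suite additionally caps recovery runs at 45k (30k for
density) simulations via the sampler's budget knob so the whole suite
stays a desk-scale job; a capped run stops at a slightly larger
tolerance, which only widens the credible intervals being checked.

## Numerical conventions and degenerate inputs

* Coordinate snapping ties round toward +∞; duplicate-site cells in
  experimental tables are omitted (the first record wins) with a
  logged count, as are cells outside the lattice.
* Trajectory starts from manual tracking map to the *occupied* site of
  minimal Euclidean distance, ties by (row, column).
* Quartiles and posterior quantiles use linear interpolation.
* RGB phase classification thresholds both channels at 100;
  unclassifiable records (both dim) are dropped with a logged count.
* A singular MCMC proposal covariance falls back to its diagonal.
* Total event rate zero means no further events: the run jumps to the
  end time.
* CV = 100·sd/mean is reported as missing when the mean is zero.

## Known limitations

* 2D only; no cell death, no phase-dependent exclusion radius, no
  nutrient/oxygen fields.
* The discrepancy's unweighted norm makes block balance an accident of
  units; semi-automatic summary weighting is out of scope.
* Experimental trajectory summaries digitise frames, whereas the model
  accumulates every lattice move; both are path lengths, but frame
  subsampling biases the observed values slightly downward.
* The full-scale experimental inference (N = 1000 against the WM983C
  summaries) is an overnight job; it is wired up through the CLI but
  not exercised by the default test suite.
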