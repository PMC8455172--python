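"""Sequential Monte Carlo ABC with particle replenishment.

The sampler targets the ABC posterior π_ε(θ | S_obs) ∝ π(θ) P(‖S_sim −
S_obs‖₂ ≤ ε) through a sequence of shrinking tolerances.  Each round:

1. sort particles by discrepancy and set the new tolerance to the
   discrepancy of rank N − N_α (N_α = ⌊αN⌋ particles are discarded);
2. refill the discarded slots by resampling survivors with replacement;
3. diversify every resampled particle with R_t ABC-MCMC iterations:
   a multivariate-normal proposal (covariance = empirical covariance of
   the survivors, unscaled) is accepted iff it stays inside the uniform
   prior and a fresh simulation at the proposal meets the tolerance —
   the Metropolis–Hastings ratio collapses to that indicator for a flat
   prior and symmetric kernel;
4. R_t = ⌈log c / log(1 − p_acc)⌉ is tuned from ⌈R_{t−1}/2⌉ pilot
   iterations so all particles move at least once with chance 1 − c.

The sampler stops when the overall acceptance rate of a round drops to
f_acc or the target tolerance is reached.  A post-hoc weighted linear
regression adjustment (Epanechnikov weights, logit-transformed
parameters) corrects the final sample for the remaining tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .summaries import SummaryVector

__all__ = [
    "PriorSpec",
    "Particle",
    "SMCConfig",
    "SMCResult",
    "sample_prior",
    "update_tolerance",
    "tune_rt",
    "mcmc_move_iteration",
    "resample_and_move",
    "run_smc_abc",
    "regression_adjust",
    "posterior_summaries",
    "posterior_predictive",
]

logger = logging.getLogger(__name__)

#: θ component names for the scratch-assay model
PARAM_NAMES = ("R_r", "R_y", "R_g", "M_r", "M_y", "M_g")

#: simulator closure: (theta, seed) -> summary vector (array or SummaryVector)
Simulator = Callable[[np.ndarray, int], "np.ndarray | SummaryVector"]


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one (a, b) interval per component."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lower) != len(self.upper):
            raise ValueError("lower and upper bounds must have equal length")
        if not all(a < b for a, b in zip(self.lower, self.upper)):
            raise ValueError("every prior interval needs a < b")

    @classmethod
    def scratch_model(cls) -> "PriorSpec":
        """Biologically conservative bounds: transitions U(0, 1) h^-1
        (doubling times of melanoma lines span roughly 16-47 h),
        motilities U(0, 10) h^-1 (diffusivities up to ~3300 μm²/h)."""
        return cls(lower=(0.0,) * 6, upper=(1.0, 1.0, 1.0, 10.0, 10.0, 10.0))

    @property
    def dim(self) -> int:
        return len(self.lower)

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=np.float64)
        return bool(np.all(theta > self.lower) and np.all(theta < self.upper))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return rng.uniform(lo, hi, size=(n, self.dim))


@dataclass
class Particle:
    """One candidate parameter vector with its discrepancy and summaries."""

    theta: np.ndarray
    rho: float
    s_sim: np.ndarray


@dataclass(frozen=True)
class SMCConfig:
    """Sampler settings (defaults follow the replenishment algorithm's
    standard tuning: α = 0.5, c = 0.01, stop at 1% acceptance)."""

    n_particles: int = 1000
    alpha: float = 0.5
    c: float = 0.01
    f_acc: float = 0.01
    eps_target: float = 0.0
    r_initial: int = 10
    max_simulations: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.c < 1:
            raise ValueError("c must lie in (0, 1)")
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")


@dataclass
class SMCResult:
    """Final particle population plus per-round diagnostics."""

    theta: np.ndarray          # (N, p)
    rho: np.ndarray            # (N,)
    s_sim: np.ndarray          # (N, q)
    eps_history: list[float] = field(default_factory=list)
    pacc_history: list[float] = field(default_factory=list)
    rt_history: list[int] = field(default_factory=list)
    n_simulations: int = 0
    truncated: bool = False
    param_names: tuple[str, ...] = PARAM_NAMES

    @property
    def eps_final(self) -> float:
        return self.eps_history[-1] if self.eps_history else float("inf")


def _as_array(summary) -> np.ndarray:
    if isinstance(summary, SummaryVector):
        return summary.concat()
    return np.asarray(summary, dtype=np.float64)


def sample_prior(prior: PriorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Independent uniform draws within the prior bounds, shape (n, p)."""
    return prior.sample(n, rng)


def update_tolerance(rho: np.ndarray, alpha: float) -> tuple[float, np.ndarray, int]:
    """Rank-based tolerance update.

    Sorts discrepancies ascending; the new tolerance is the value at rank
    N − N_α with N_α = ⌊αN⌋; the N_α worst particles are discarded.
    Returns (ε_t, indices of kept particles in ascending-ρ order, number
    discarded).
    """
    rho = np.asarray(rho, dtype=np.float64)
    n = len(rho)
    if n < 2:
        raise ValueError("need at least 2 particles")
    if not np.any(np.isfinite(rho)):
        raise ValueError("all discrepancies are infinite")
    n_alpha = int(math.floor(alpha * n))
    order = np.argsort(rho, kind="stable")
    keep = order[: n - n_alpha]
    eps = float(rho[keep[-1]])
    return eps, keep, n_alpha


def tune_rt(p_acc: float, c: float) -> int:
    """Number of MCMC diversification iterations so that each particle is
    moved at least once with probability 1 − c:
    R_t = ⌈log c / log(1 − p_acc)⌉, clamped to ≥ 1.

    ``p_acc = 0`` is stopping-condition territory — the caller must test
    the acceptance-rate stopping rule first.
    """
    if not 0.0 <= p_acc <= 1.0:
        raise ValueError("p_acc must lie in [0, 1]")
    if p_acc == 0.0:
        raise ValueError("p_acc = 0: acceptance-based stopping applies")
    if p_acc == 1.0:
        return 1
    return max(1, int(math.ceil(math.log(c) / math.log(1.0 - p_acc))))


def mcmc_move_iteration(
    theta: np.ndarray,
    rho: float,
    s_sim: np.ndarray,
    chol: np.ndarray,
    eps: float,
    observed: np.ndarray,
    simulator: Simulator,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray, bool, int]:
    """One ABC-MCMC iteration for a single particle.

    Proposes θ' ~ MVN(θ, Σ) via the Cholesky factor; with the flat prior
    and symmetric proposal the acceptance probability reduces to the
    indicator that θ' is inside the prior support *and* a fresh
    simulation at θ' satisfies ρ' ≤ ε.  Out-of-support proposals are
    rejected without simulating.  Returns the (possibly updated)
    particle, the acceptance flag, and how many simulations were spent.
    """
    prop = theta + chol @ rng.standard_normal(len(theta))
    if not prior.contains(prop):
        return theta, rho, s_sim, False, 0
    sim_seed = int(rng.integers(2**31))
    try:
        s_prop = _as_array(simulator(prop, sim_seed))
    except Exception:  # pragma: no cover - defensive
        logger.warning("simulator failure at %s; proposal rejected", prop, exc_info=True)
        return theta, rho, s_sim, False, 1
    if np.all(np.isfinite(s_prop)):
        rho_prop = float(np.linalg.norm(s_prop - observed))
    else:
        rho_prop = float("inf")
    if rho_prop <= eps:
        return prop, rho_prop, s_prop, True, 1
    return theta, rho, s_sim, False, 1


def _proposal_chol(theta_kept: np.ndarray) -> np.ndarray:
    """Cholesky factor of the survivors' empirical covariance (unscaled);
    falls back to the diagonal of component variances if singular."""
    cov = np.atleast_2d(np.cov(theta_kept, rowvar=False))
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        logger.warning("singular proposal covariance; falling back to diagonal")
        var = np.clip(np.diag(cov), 1e-300, None)
        return np.diag(np.sqrt(var))


def resample_and_move(
    theta: np.ndarray,
    rho: np.ndarray,
    s_sim: np.ndarray,
    keep: np.ndarray,
    eps: float,
    observed: np.ndarray,
    simulator: Simulator,
    prior: PriorSpec,
    config: SMCConfig,
    rng: np.random.Generator,
    r_prev: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, int]:
    """Replenish the discarded slots and diversify them with MCMC moves.

    Discarded slots are refilled by uniform resampling (with replacement)
    from the kept particles; each refilled particle then undergoes
    ⌈R_{t−1}/2⌉ pilot iterations, from whose acceptance rate R_t is
    tuned, followed by the remaining R_t − pilot iterations.  Returns the
    new population, the round's overall acceptance rate p_acc
    (accumulated over pilot + remaining iterations of all moved
    particles), R_t, and the simulation count.
    """
    n = config.n_particles
    n_res = n - len(keep)
    new_theta = np.empty((n, theta.shape[1]))
    new_rho = np.empty(n)
    new_s = np.empty((n, s_sim.shape[1]))
    new_theta[: len(keep)] = theta[keep]
    new_rho[: len(keep)] = rho[keep]
    new_s[: len(keep)] = s_sim[keep]
    src = rng.choice(len(keep), size=n_res, replace=True)
    new_theta[len(keep):] = theta[keep][src]
    new_rho[len(keep):] = rho[keep][src]
    new_s[len(keep):] = s_sim[keep][src]

    chol = _proposal_chol(theta[keep])

    n_sims = 0
    n_accepted = 0
    n_iters = 0

    def sweep(n_sweeps: int) -> None:
        nonlocal n_sims, n_accepted, n_iters
        for _ in range(n_sweeps):
            for k in range(len(keep), n):
                th, rh, ss, acc, spent = mcmc_move_iteration(
                    new_theta[k], new_rho[k], new_s[k], chol, eps,
                    observed, simulator, prior, rng,
                )
                new_theta[k], new_rho[k], new_s[k] = th, rh, ss
                n_sims += spent
                n_iters += 1
                n_accepted += int(acc)

    pilot = max(1, int(math.ceil(r_prev / 2)))
    sweep(pilot)
    p_pilot = n_accepted / max(n_iters, 1)
    if p_pilot <= config.f_acc:
        # the pilot estimate already sits at the stopping threshold; the
        # completed round would match it in expectation, so end the round
        # here and let the acceptance-rate stopping rule fire
        r_t = pilot
    else:
        r_t = max(tune_rt(p_pilot, config.c), pilot)
        sweep(r_t - pilot)
    p_acc = n_accepted / max(n_iters, 1)
    return new_theta, new_rho, new_s, p_acc, r_t, n_sims


def run_smc_abc(
    observed: "np.ndarray | SummaryVector",
    simulator: Simulator,
    prior: PriorSpec,
    config: SMCConfig,
) -> SMCResult:
    """Run the full replenishment sampler.

    Initialises N particles from the prior (one simulation each;
    infinite-discrepancy draws are redrawn), then alternates tolerance
    updates and replenishment rounds until the overall acceptance rate
    falls to ``f_acc``, the tolerance reaches ``eps_target``, or the
    simulation budget is exhausted (which sets ``truncated``).
    """
    rng = np.random.default_rng(config.seed)
    obs = _as_array(observed)
    n = config.n_particles

    theta = np.empty((n, prior.dim))
    rho = np.empty(n)
    s_sim = np.empty((n, len(obs)))
    n_sims = 0
    for i in range(n):
        for _attempt in range(1000):
            th = prior.sample(1, rng)[0]
            s = _as_array(simulator(th, int(rng.integers(2**31))))
            n_sims += 1
            r = float(np.linalg.norm(s - obs)) if np.all(np.isfinite(s)) else float("inf")
            if math.isfinite(r):
                break
        else:
            raise RuntimeError("could not draw a finite-discrepancy particle from the prior")
        theta[i], rho[i], s_sim[i] = th, r, s

    result = SMCResult(theta=theta, rho=rho, s_sim=s_sim)
    result.eps_history.append(float(rho.max()))
    logger.info("SMC init: N=%d, eps_1=%.4g, %d simulations", n, rho.max(), n_sims)

    r_prev = config.r_initial
    t = 1
    while True:
        eps, keep, _ = update_tolerance(rho, config.alpha)
        theta, rho, s_sim, p_acc, r_t, spent = resample_and_move(
            theta, rho, s_sim, keep, eps, obs, simulator, prior, config, rng, r_prev,
        )
        n_sims += spent
        t += 1
        r_prev = r_t
        result.theta, result.rho, result.s_sim = theta, rho, s_sim
        result.eps_history.append(eps)
        result.pacc_history.append(p_acc)
        result.rt_history.append(r_t)
        logger.info(
            "SMC round %d: eps=%.4g, p_acc=%.3f, R_t=%d, sims=%d",
            t, eps, p_acc, r_t, n_sims,
        )
        if eps <= config.eps_target:
            logger.info("stopping: tolerance target reached")
            break
        if p_acc <= config.f_acc:
            logger.info("stopping: acceptance rate %.4f <= f_acc", p_acc)
            break
        if config.max_simulations is not None and n_sims >= config.max_simulations:
            logger.warning("stopping: simulation budget exhausted")
            result.truncated = True
            break
    result.n_simulations = n_sims
    return result


def regression_adjust(
    theta: np.ndarray,
    s_sim: np.ndarray,
    rho: np.ndarray,
    observed: "np.ndarray | SummaryVector",
    prior: PriorSpec,
) -> np.ndarray:
    """Post-hoc weighted linear regression adjustment of the final sample.

    Each parameter component is logit-transformed with its prior bounds,
    θ̃ = log((θ − a)/(b − θ)), regressed on (S_sim − S_obs) by weighted
    least squares with Epanechnikov weights w_i = 0.75(1 − (ρ_i/max ρ)²),
    shifted to the observed summaries (θ̃* = θ̃ − (S_sim − S_obs)ᵀβ̂) and
    back-transformed, so the adjusted draws always stay strictly inside
    the prior support.
    """
    theta = np.asarray(theta, dtype=np.float64)
    s_sim = np.asarray(s_sim, dtype=np.float64)
    rho = np.asarray(rho, dtype=np.float64)
    obs = _as_array(observed)
    n, p = theta.shape
    q = s_sim.shape[1]
    if n < q + 2:
        raise ValueError(f"need at least {q + 2} particles for a {q}-summary adjustment")

    diff = s_sim - obs[None, :]
    rmax = float(rho.max())
    if rmax > 0:
        w = 0.75 * (1.0 - (rho / rmax) ** 2)
    else:
        w = np.ones(n)
    if not np.any(w > 0):
        logger.warning("all Epanechnikov weights vanish (equal discrepancies); "
                       "using uniform weights")
        w = np.ones(n)

    design = sm.add_constant(diff, has_constant="add")
    if np.linalg.matrix_rank(design[w > 0]) < design.shape[1]:
        logger.warning("rank-deficient summary design; coefficients resolved by pseudoinverse")

    lo = np.asarray(prior.lower)
    hi = np.asarray(prior.upper)
    nudge = (hi - lo) * 1e-12
    adjusted = np.empty_like(theta)
    for jdx in range(p):
        a, b = lo[jdx], hi[jdx]
        tj = theta[:, jdx]
        clipped = np.clip(tj, a + nudge[jdx], b - nudge[jdx])
        if np.any(clipped != tj):
            logger.warning("parameter %d on a prior bound; nudged before logit", jdx)
        z = np.log((clipped - a) / (b - clipped))
        fit = sm.WLS(z, design, weights=w).fit()
        beta = fit.params[1:]
        z_star = z - diff @ beta
        adjusted[:, jdx] = (a + b * np.exp(z_star)) / (1.0 + np.exp(z_star))
        big = z_star > 500  # exp overflow guard: limit is b
        adjusted[big, jdx] = b - nudge[jdx]
    return adjusted


def posterior_summaries(
    sample: np.ndarray, names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean, sd, (2.5%, 50%, 97.5%) quantiles and CV% per parameter.

    CV = 100·sd/mean; reported as missing when the mean is zero.
    Quantiles use linear interpolation.
    """
    sample = np.atleast_2d(np.asarray(sample, dtype=np.float64))
    if sample.shape[0] == 1 and sample.shape[1] > 1 and names is None:
        sample = sample.T
    if sample.size == 0:
        raise ValueError("empty sample")
    p = sample.shape[1]
    if names is None:
        names = PARAM_NAMES[:p] if p <= len(PARAM_NAMES) else [f"theta_{k}" for k in range(p)]
    mean = sample.mean(axis=0)
    sd = sample.std(axis=0, ddof=1) if sample.shape[0] > 1 else np.zeros(p)
    q = np.percentile(sample, [2.5, 50.0, 97.5], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, 100.0 * sd / np.abs(mean), np.nan)
    return pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "q2.5": q[0],
            "median": q[1],
            "q97.5": q[2],
            "cv_pct": cv,
        },
        index=list(names),
    )


def posterior_predictive(
    sample: np.ndarray,
    simulator: Simulator,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulated summary statistics under parameters drawn from the sample.

    Draws parameter vectors with replacement, simulates each once and
    stacks the resulting summary vectors (one row per draw) for
    comparison against the observed summaries.
    """
    sample = np.atleast_2d(np.asarray(sample, dtype=np.float64))
    if sample.shape[0] == 0:
        raise ValueError("empty posterior sample")
    rows = []
    for _ in range(n_draws):
        th = sample[int(rng.integers(sample.shape[0]))]
        rows.append(_as_array(simulator(th, int(rng.integers(2**31)))))
    return np.stack(rows)
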