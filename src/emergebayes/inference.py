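"""Posterior sampling and its deterministic validation oracle.

Two independent routes to the posterior over (alpha, B, C):

* :func:`fit_mcmc` — adaptive random-walk Metropolis on the transformed
  space (logit alpha, log B, log C), the reference sampler.
* :func:`grid_posterior` — brute-force evaluation of the unnormalized
  posterior on a 3-D lattice followed by trapezoid normalization; slow but
  deterministic, used to validate the sampler.

Convergence diagnostics (split R-hat, bulk effective sample size) are
computed with arviz.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .core_model import (
    EmergenceDataset,
    HOURS_PER_DAY,
    ModelParams,
    PriorSpec,
    _log_interval_probs,
    _beta_logpdf,
    _truncnorm0_logpdf,
    log_posterior_unnorm,
)

logger = logging.getLogger("emergebayes")

PARAM_NAMES = ("alpha", "B", "C")

__all__ = [
    "PARAM_NAMES",
    "PosteriorSamples",
    "SamplerConfig",
    "GridPosterior",
    "sample_prior",
    "fit_mcmc",
    "grid_posterior",
    "diagnostics",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """A set of (alpha, B, C) draws with chain bookkeeping.

    ``draws`` has shape (S, 3) with columns alpha, B, C in natural units,
    stored chain-major (all kept draws of chain 0, then chain 1, ...);
    ``S = chains * n_kept``.
    """

    draws: np.ndarray
    source: str  # "prior" | "posterior"
    chains: int
    n_burnin: int
    n_kept: int
    thin: int = 1
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)
    acceptance_rate: float = float("nan")

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != 3:
            raise ValueError("draws must have shape (S, 3)")
        if self.chains * self.n_kept != self.draws.shape[0]:
            raise ValueError("chains * n_kept must equal the number of draws")
        a, b, c = self.draws.T
        if np.any((a < 0) | (a > 1)) or np.any(b <= 0) or np.any(c <= 0):
            raise ValueError("draws violate parameter support")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def param(self, name: str) -> np.ndarray:
        """Marginal draws of one parameter ("alpha", "B" or "C")."""
        try:
            return self.draws[:, PARAM_NAMES.index(name)]
        except ValueError:
            raise ValueError(f"unknown parameter {name!r}; expected one of {PARAM_NAMES}")

    def by_chain(self) -> np.ndarray:
        """Draws reshaped to (chains, n_kept, 3)."""
        return self.draws.reshape(self.chains, self.n_kept, 3)


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    n_iter: int = 10000
    n_burnin: int = 5000
    thin: int = 1
    target_acceptance: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chains, self.n_iter, self.n_burnin, self.thin) < 1:
            raise ValueError("all sampler counts must be positive")
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")


@dataclass
class GridPosterior:
    """Posterior evaluated on a 3-D lattice, trapezoid-normalized.

    ``density[i, j, k]`` is the posterior density at
    (alpha_grid[i], b_grid[j], c_grid[k]); it integrates to one under the
    trapezoid rule on the stored grids.
    """

    alpha_grid: np.ndarray
    b_grid: np.ndarray
    c_grid: np.ndarray
    density: np.ndarray
    means: dict
    sds: dict


# ---------------------------------------------------------------------------
# Prior sampling
# ---------------------------------------------------------------------------

def _truncnorm0_ppf(u, mu: float, sd: float):
    """Inverse CDF of Gaussian(mu, sd) truncated to (0, inf)."""
    p0 = special.ndtr(-mu / sd)  # mass below zero of the untruncated law
    return mu + sd * special.ndtri(p0 + np.asarray(u) * (1.0 - p0))


def sample_prior(prior: PriorSpec, S: int, seed: int) -> PosteriorSamples:
    """Draw ``S`` independent (alpha, B, C) triples from the prior."""
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = rng.beta(prior.alpha_a, prior.alpha_b, size=S)
    B = _truncnorm0_ppf(rng.random(S), prior.mu_B, prior.sd_B)
    C = _truncnorm0_ppf(rng.random(S), prior.mu_C, prior.sd_C)
    return PosteriorSamples(
        draws=np.column_stack([alpha, B, C]),
        source="prior",
        chains=1,
        n_burnin=0,
        n_kept=S,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Adaptive random-walk Metropolis
# ---------------------------------------------------------------------------

def _to_z(alpha: float, B: float, C: float) -> np.ndarray:
    return np.array([special.logit(alpha), math.log(B), math.log(C)])

def _from_z(z: np.ndarray) -> tuple[float, float, float]:
    return float(special.expit(z[0])), float(math.exp(z[1])), float(math.exp(z[2]))


def _make_target(prior: PriorSpec, data: EmergenceDataset):
    """Log target on z = (logit alpha, log B, log C), Jacobian included."""

    def target(z: np.ndarray) -> float:
        alpha, B, C = _from_z(z)
        if not (0.0 < alpha < 1.0 and np.isfinite(B) and np.isfinite(C)):
            return -np.inf
        p = ModelParams(alpha, B, C, validate=False)
        lp = log_posterior_unnorm(prior, data, p)
        if not np.isfinite(lp):
            return -np.inf
        # |d(alpha,B,C)/dz| = alpha (1 - alpha) B C
        return lp + math.log(alpha) + math.log1p(-alpha) + z[1] + z[2]

    return target


def _initial_point(data: EmergenceDataset, prior: PriorSpec) -> np.ndarray:
    """Crude moment-based start, falling back to prior means."""
    alpha0 = 0.5
    C0 = prior.mu_C
    if data.n_total > 0:
        alpha0 = min(max(data.n_emerged / data.n_total, 0.05), 0.95)
    if data.n_emerged > 0:
        cum = np.cumsum(data.counts)
        i = int(np.searchsorted(cum, 0.5 * data.n_emerged))
        mid_h = 0.5 * (data.edges[i] + data.edges[i + 1])
        C0 = max(mid_h / HOURS_PER_DAY, 1e-3)
    return _to_z(alpha0, prior.mu_B, C0)


def fit_mcmc(
    data: EmergenceDataset, prior: PriorSpec, config: SamplerConfig | None = None
) -> PosteriorSamples:
    """Sample the posterior by adaptive random-walk Metropolis.

    Proposals are Gaussian steps in (logit alpha, log B, log C); during
    burn-in the global step size tracks the target acceptance rate
    (Robbins–Monro on its log) and the per-coordinate scales track the
    empirical sd of the recent chain history.  Adaptation is frozen after
    burn-in so the kept draws form a valid Markov chain.  Bit-reproducible
    given ``config.seed``.
    """
    if config is None:
        config = SamplerConfig()
    if data.n_total < 1:
        raise ValueError("need at least one seed to fit")
    target = _make_target(prior, data)
    z0 = _initial_point(data, prior)
    lp0 = target(z0)
    if not np.isfinite(lp0):
        raise RuntimeError(
            "log posterior is not finite at the initial point; the data are "
            "impossible under every parameter value near the moment estimate"
        )

    n_kept = (config.n_iter - config.n_burnin + config.thin - 1) // config.thin
    all_draws = np.empty((config.chains, n_kept, 3))
    accepted_post = 0
    children = np.random.SeedSequence(config.seed).spawn(config.chains)
    for ci in range(config.chains):
        rng = np.random.default_rng(children[ci])
        z = z0 + 0.05 * rng.standard_normal(3)  # overdisperse chain starts
        lp = target(z)
        if not np.isfinite(lp):
            z, lp = z0.copy(), lp0
        lam = 0.5
        sd_vec = np.array([0.5, 0.2, 0.1])
        history = np.empty((config.n_burnin, 3))
        win_acc = 0
        kept = 0
        for it in range(config.n_iter):
            prop = z + lam * sd_vec * rng.standard_normal(3)
            lp_prop = target(prop)
            if math.log(rng.random()) < lp_prop - lp:
                z, lp = prop, lp_prop
                if it < config.n_burnin:
                    win_acc += 1
                else:
                    accepted_post += 1
            if it < config.n_burnin:
                history[it] = z
                if (it + 1) % 50 == 0:
                    rate = win_acc / 50.0
                    lam *= math.exp(0.66 * (rate - config.target_acceptance))
                    win_acc = 0
                if (it + 1) % 200 == 0 and it + 1 >= 400:
                    recent = history[max(0, it - 999) : it + 1]
                    sd_vec = np.maximum(recent.std(axis=0), 0.02)
            elif (it - config.n_burnin) % config.thin == 0:
                alpha, B, C = _from_z(z)
                all_draws[ci, kept] = (alpha, B, C)
                kept += 1
        assert kept == n_kept

    acc_rate = accepted_post / (config.chains * (config.n_iter - config.n_burnin))
    samples = PosteriorSamples(
        draws=all_draws.reshape(-1, 3),
        source="posterior",
        chains=config.chains,
        n_burnin=config.n_burnin,
        n_kept=n_kept,
        thin=config.thin,
        seed=config.seed,
        acceptance_rate=acc_rate,
    )
    samples.diagnostics = diagnostics(samples)
    for name in PARAM_NAMES:
        rhat = samples.diagnostics[name]["rhat"]
        if rhat is not None and np.isfinite(rhat) and rhat > 1.05:
            logger.warning("split R-hat for %s is %.3f (> 1.05)", name, rhat)
    return samples


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def diagnostics(samples: PosteriorSamples) -> dict:
    """Split R-hat and bulk ESS per parameter (arviz), flagging R-hat > 1.01.

    With a single chain R-hat is unavailable and reported as ``None``.
    """
    import arviz as az

    arr = samples.by_chain()
    report: dict = {}
    flagged: list[str] = []
    data = {name: arr[:, :, i] for i, name in enumerate(PARAM_NAMES)}
    ds = az.convert_to_dataset(data)
    ess = az.ess(ds, method="bulk")
    rhat = az.rhat(ds, method="split") if samples.chains >= 2 else None
    for name in PARAM_NAMES:
        r = float(rhat[name].values) if rhat is not None else None
        report[name] = {"rhat": r, "ess_bulk": float(ess[name].values)}
        if r is not None and (not np.isfinite(r) or r > 1.01):
            flagged.append(name)
    report["flagged"] = flagged
    return report


# ---------------------------------------------------------------------------
# Grid oracle
# ---------------------------------------------------------------------------

def _prior_ranges(prior: PriorSpec) -> list[tuple[float, float]]:
    """Axis ranges covering at least the central 99.9% prior mass.

    The alpha axis is widened to essentially the whole unit interval so that
    posteriors concentrated far from the prior bulk (a vague or even
    mis-centred Beta) remain inside the lattice.
    """
    qa = stats.beta.ppf([5e-4, 1 - 5e-4], prior.alpha_a, prior.alpha_b)
    a_lo, a_hi = min(qa[0], 1e-3), max(qa[1], 1 - 1e-3)

    def trunc_range(mu, sd):
        p0 = special.ndtr(-mu / sd)
        q = mu + sd * special.ndtri(p0 + np.array([5e-4, 1 - 5e-4]) * (1 - p0))
        return max(q[0], 1e-6), q[1]

    return [(a_lo, a_hi), trunc_range(prior.mu_B, prior.sd_B),
            trunc_range(prior.mu_C, prior.sd_C)]


def _grid_eval(
    data: EmergenceDataset,
    prior: PriorSpec,
    ranges: list[tuple[float, float]],
    n_grid: int,
):
    alpha_g = np.linspace(*ranges[0], n_grid)
    b_g = np.linspace(*ranges[1], n_grid)
    c_g = np.linspace(*ranges[2], n_grid)

    # likelihood factorizes: counts enter through sum(N) * log(alpha) plus an
    # alpha-free (B, C) table; the censored factor couples alpha with F(t_T)
    t_d = data.edges / HOURS_PER_DAY
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        A = np.exp(
            -b_g[:, None, None] * (t_d[None, None, :] - c_g[None, :, None])
        )  # (nb, nc, T+1)
        loglik_bc = np.zeros((n_grid, n_grid))
        nz = np.nonzero(data.counts)[0]
        if nz.size:
            dt = np.diff(t_d)
            delta = A[..., :-1] * -np.expm1(-b_g[:, None, None] * dt[None, None, :])
            logdiff = -A[..., 1:] + np.log(-np.expm1(-delta))
            logdiff = np.where(np.isinf(A[..., :-1]), -A[..., 1:], logdiff)
            logdiff = np.where(delta == 0.0, -np.inf, logdiff)
            loglik_bc = np.einsum("i,bci->bc", data.counts[nz].astype(float),
                                  logdiff[..., nz])
        F_T = np.exp(-A[..., -1])
        n_emerged = data.n_emerged
        logpost = (
            n_emerged * np.log(alpha_g)[:, None, None]
            + loglik_bc[None, :, :]
            + data.n_censored * np.log1p(-alpha_g[:, None, None] * F_T[None, :, :])
        ) if data.n_total else np.zeros((n_grid, n_grid, n_grid))
        logpost = (
            logpost
            + _beta_logpdf(alpha_g, prior.alpha_a, prior.alpha_b)[:, None, None]
            + _truncnorm0_logpdf(b_g, prior.mu_B, prior.sd_B)[None, :, None]
            + _truncnorm0_logpdf(c_g, prior.mu_C, prior.sd_C)[None, None, :]
        )
    if not np.any(np.isfinite(logpost)):
        raise RuntimeError("posterior is zero everywhere on the grid (degenerate data)")
    dens = np.exp(logpost - np.nanmax(logpost[np.isfinite(logpost)]))
    dens[~np.isfinite(logpost)] = 0.0

    def trap_w(x):
        w = np.empty_like(x)
        w[0] = 0.5 * (x[1] - x[0])
        w[-1] = 0.5 * (x[-1] - x[-2])
        w[1:-1] = 0.5 * (x[2:] - x[:-2])
        return w

    W = (
        trap_w(alpha_g)[:, None, None]
        * trap_w(b_g)[None, :, None]
        * trap_w(c_g)[None, None, :]
    )
    total = float((dens * W).sum())
    if total <= 0:
        raise RuntimeError("posterior is zero everywhere on the grid (degenerate data)")
    dens /= total
    grids = (alpha_g, b_g, c_g)
    means, sds = {}, {}
    for ax, (name, g) in enumerate(zip(PARAM_NAMES, grids)):
        shape = [1, 1, 1]
        shape[ax] = n_grid
        gg = g.reshape(shape)
        m = float((gg * dens * W).sum())
        v = float(((gg - m) ** 2 * dens * W).sum())
        means[name] = m
        sds[name] = math.sqrt(max(v, 0.0))
    return grids, dens, means, sds


def grid_posterior(
    data: EmergenceDataset,
    prior: PriorSpec,
    n_grid: int = 60,
    refine: bool = True,
) -> GridPosterior:
    """Deterministic lattice approximation of the posterior.

    Evaluates ``exp(log_posterior_unnorm)`` on an ``n_grid``³ lattice whose
    ranges cover the prior's central mass (the alpha axis widened to the
    whole unit interval), normalizes by the trapezoid rule, and — when
    ``refine`` — zooms twice onto a box of mean ± 8 sd per axis so marginal
    moments are accurate even for concentrated posteriors (the second pass
    makes the window, and hence the result, independent of the coarse
    first-pass moments).
    """
    if n_grid < 20:
        raise ValueError("n_grid must be >= 20")
    ranges = _prior_ranges(prior)
    grids, dens, means, sds = _grid_eval(data, prior, ranges, n_grid)
    if refine and data.n_total > 0:
        for _ in range(2):
            new_ranges = []
            for (lo, hi), name in zip(ranges, PARAM_NAMES):
                m, s = means[name], max(sds[name], 1e-6)
                new_ranges.append((max(lo, m - 8 * s), min(hi, m + 8 * s)))
            grids, dens, means, sds = _grid_eval(data, prior, new_ranges, n_grid)
    return GridPosterior(
        alpha_grid=grids[0],
        b_grid=grids[1],
        c_grid=grids[2],
        density=dens,
        means=means,
        sds=sds,
    )
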