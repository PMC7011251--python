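"""Cure-rate Gompertz model for interval-censored emergence data.

A tray of seeds is imaged on a fixed grid of observation times (hours).
Each seed either emerges during one known interval, or is never seen to
emerge.  The model is a two-component mixture: a seed is "viable" with
probability ``alpha`` (the emergence yield) and, if viable, its emergence
time follows a Gumbel-type (Gompertz) distribution

    F(t) = exp(-exp(-B (t - C)))

with uniformity ``B`` (1/day) and half-time ``C`` (days); ``F(C) = 1/e``.
A seed not seen to emerge by the end of the experiment is either non-viable
or late, giving the censored factor ``1 - alpha F(t_T)``.  The likelihood of
one tray is

    L = [1 - alpha F(t_T)]^M  *  prod_i [alpha (F(t_{i+1}) - F(t_i))]^{N_i}

where ``N_i`` counts seeds emerging in interval ``[t_i, t_{i+1})`` and ``M``
counts the never-emerged.  Priors: Beta on ``alpha``; zero-truncated
Gaussians on ``B`` and ``C``.  All densities here are evaluated in log
space with underflow-stable interval probabilities.

Observation times are stored in **hours** (the native imaging cadence);
the model operates in **days** and the conversion happens in exactly one
place (:func:`log_likelihood` / :data:`HOURS_PER_DAY`).
"""

from __future__ import annotations

import math
from dataclasses import InitVar, dataclass

import numpy as np
from scipy import special

HOURS_PER_DAY = 24.0

__all__ = [
    "HOURS_PER_DAY",
    "EmergenceDataset",
    "ModelParams",
    "PriorSpec",
    "gompertz_cdf",
    "gompertz_quantile",
    "median_emergence_time",
    "log_interval_prob",
    "log_likelihood",
    "log_prior",
    "log_posterior_unnorm",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EmergenceDataset:
    """Binned emergence counts for one tray.

    Parameters
    ----------
    edges
        Observation-interval boundaries ``t_0 < t_1 < ... < t_T`` in hours,
        strictly increasing, ``t_0 >= 0``.  Length ``T + 1``.
    counts
        Nonnegative integers ``N_i``, one per interval ``[t_i, t_{i+1})``.
    n_censored
        ``M``, the number of seeds never observed to emerge.
    n_total
        Tray size ``n``; if omitted it is derived as ``sum(counts) + M``.
    label
        Free-text tray / treatment identifier.
    """

    edges: np.ndarray
    counts: np.ndarray
    n_censored: int
    n_total: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts)
        if counts.size and not np.all(counts == np.floor(counts)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64) if counts.size else np.zeros(0, np.int64)
        if self.edges.ndim != 1 or self.edges.size < 1:
            raise ValueError("edges must be a 1-D array with at least one boundary")
        if self.edges[0] < 0:
            raise ValueError("first observation time must be >= 0")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if self.counts.size != self.edges.size - 1:
            raise ValueError(
                f"need one count per interval: {self.counts.size} counts "
                f"for {self.edges.size - 1} intervals"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        self.n_censored = int(self.n_censored)
        if self.n_censored < 0:
            raise ValueError("n_censored must be nonnegative")
        derived = int(self.counts.sum()) + self.n_censored
        if self.n_total is None:
            self.n_total = derived
        elif int(self.n_total) != derived:
            raise ValueError(
                f"sum(counts) + n_censored = {derived} != n_total = {self.n_total}"
            )
        self.n_total = int(self.n_total)

    @property
    def n_intervals(self) -> int:
        return self.edges.size - 1

    @property
    def n_emerged(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmergenceDataset):
            return NotImplemented
        return (
            np.array_equal(self.edges, other.edges)
            and np.array_equal(self.counts, other.counts)
            and self.n_censored == other.n_censored
            and self.n_total == other.n_total
            and self.label == other.label
        )


@dataclass(frozen=True)
class ModelParams:
    """One point (alpha, B, C) in parameter space.

    alpha : emergence yield, probability in [0, 1] that a seed is viable.
    B     : emergence uniformity, rate > 0 (1/day).
    C     : emergence half-time, location > 0 (days); F(C) = 1/e.
    """

    alpha: float
    B: float
    C: float
    #: pass validate=False to represent an out-of-support point, e.g. when
    #: probing where the prior density vanishes
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if not validate:
            return
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not self.B > 0:
            raise ValueError(f"B must be positive, got {self.B}")
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the three independent priors.

    ``alpha ~ Beta(alpha_a, alpha_b)``; ``B`` and ``C`` each follow a
    Gaussian truncated to (0, inf) with the stated mean and sd, with the
    truncation constant included so each prior integrates to one.
    """

    alpha_a: float = 1.0
    alpha_b: float = 9.0
    mu_B: float = 2.0
    sd_B: float = 0.5
    mu_C: float = 5.0
    sd_C: float = 2.0

    def __post_init__(self) -> None:
        for name in ("alpha_a", "alpha_b", "sd_B", "sd_C"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# Emergence function (Gumbel / Gompertz CDF)
# ---------------------------------------------------------------------------

def _log_cdf(B: float, C: float, t):
    """log F(t) = -exp(-B (t - C)); vectorized over t (days)."""
    return -np.exp(-B * (np.asarray(t, dtype=float) - C))


def gompertz_cdf(params: ModelParams, t):
    """Probability that a *viable* seed emerges before time ``t`` (days).

    Increasing double-exponential (Gumbel minimum) form; does **not**
    include the yield factor ``alpha``.  ``t`` may be a scalar or array;
    negative times are a domain error.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = np.exp(_log_cdf(params.B, params.C, t))
    return float(out) if out.ndim == 0 else out


def gompertz_quantile(params: ModelParams, q):
    """Inverse of :func:`gompertz_cdf`: t such that F(t) = q (days)."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantile level must lie strictly in (0, 1)")
    out = params.C - np.log(-np.log(q)) / params.B
    return float(out) if out.ndim == 0 else out


def median_emergence_time(B, C):
    """Time at which a viable seed has emerged with probability 1/2.

    ``t50 = C - log(log 2) / B``; under the Gumbel form this exceeds the
    half-time C (where F = 1/e ~ 0.368), so it is reported separately.
    """
    return np.asarray(C, dtype=float) - math.log(math.log(2.0)) / np.asarray(B, dtype=float)


def _log_interval_probs(alpha: float, B: float, C: float, lo, hi):
    """log( alpha * [F(hi) - F(lo)] ) elementwise, underflow-stable.

    With a = exp(-B (t - C)) the difference F(hi) - F(lo) equals
    exp(-a_hi) * (1 - exp(-(a_lo - a_hi))), and a_lo - a_hi is computed as
    a_lo * (1 - exp(-B (hi - lo))) so right-tail intervals where both CDF
    values round to the same float stay finite.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        a_lo = np.exp(-B * (lo - C))
        a_hi = np.exp(-B * (hi - C))
        # a_lo - a_hi without cancellation; hi = inf gives the full tail a_lo
        delta = a_lo * -np.expm1(-B * (hi - lo))
        log_diff = -a_hi + np.log(-np.expm1(-delta))
        # left tail so deep that a_lo overflows: F(lo) = 0, diff = F(hi)
        log_diff = np.where(np.isinf(a_lo), -a_hi, log_diff)
        # both CDF values indistinguishable from each other (or from 0)
        log_diff = np.where(delta == 0.0, -np.inf, log_diff)
        out = np.log(alpha) + log_diff
    return out


def log_interval_prob(params: ModelParams, t_lo: float, t_hi: float) -> float:
    """log probability that a seed emerges during ``[t_lo, t_hi)`` (days).

    This is ``log(alpha [F(t_hi) - F(t_lo)])``; returns ``-inf`` when
    ``alpha = 0`` or when the interval probability underflows to zero.
    ``t_hi`` may be ``inf``.
    """
    if not 0.0 <= t_lo < t_hi:
        raise ValueError(f"need 0 <= t_lo < t_hi, got [{t_lo}, {t_hi}]")
    return float(_log_interval_probs(params.alpha, params.B, params.C, t_lo, t_hi))


# ---------------------------------------------------------------------------
# Likelihood, prior, posterior
# ---------------------------------------------------------------------------

def log_likelihood(params: ModelParams, data: EmergenceDataset) -> float:
    """Log of the cure-rate interval-censored likelihood of one tray.

    ``M log(1 - alpha F(t_T)) + sum_i N_i log(alpha [F(t_{i+1}) - F(t_i)])``
    over intervals with ``N_i > 0`` (empty intervals contribute a factor of
    one).  Edges are converted from hours to days before evaluating F.
    Returns ``-inf`` (not an exception) when any observed factor has zero
    probability.
    """
    if data.n_total == 0:
        return 0.0
    edges_d = data.edges / HOURS_PER_DAY
    total = 0.0
    nz = np.nonzero(data.counts)[0]
    if nz.size:
        terms = _log_interval_probs(
            params.alpha, params.B, params.C, edges_d[nz], edges_d[nz + 1]
        )
        total += float(data.counts[nz] @ terms)
    if data.n_censored:
        F_T = math.exp(_log_cdf(params.B, params.C, edges_d[-1]))
        with np.errstate(divide="ignore"):
            total += data.n_censored * float(np.log1p(-params.alpha * F_T))
    return total


def _beta_logpdf(x, a: float, b: float):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            special.xlogy(a - 1.0, x)
            + special.xlog1py(b - 1.0, -x)
            - special.betaln(a, b)
        )
    return np.where((x < 0) | (x > 1), -np.inf, out)


def _truncnorm0_logpdf(x, mu: float, sd: float):
    """Log density of a Gaussian(mu, sd) truncated to (0, inf)."""
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sd
    # normalizer P(X > 0) = Phi(mu / sd)
    log_z0 = special.log_ndtr(mu / sd)
    out = -0.5 * z * z - math.log(sd) - 0.5 * math.log(2.0 * math.pi) - log_z0
    return np.where(x <= 0, -np.inf, out)


def log_prior(prior: PriorSpec, params: ModelParams) -> float:
    """Joint log prior density at ``params``; ``-inf`` outside support."""
    return float(
        _beta_logpdf(params.alpha, prior.alpha_a, prior.alpha_b)
        + _truncnorm0_logpdf(params.B, prior.mu_B, prior.sd_B)
        + _truncnorm0_logpdf(params.C, prior.mu_C, prior.sd_C)
    )


def log_posterior_unnorm(
    prior: PriorSpec, data: EmergenceDataset, params: ModelParams
) -> float:
    """Unnormalized log posterior: ``log_prior + log_likelihood``.

    The evidence (normalization constant) is intentionally omitted; only
    posterior ratios and samples are ever needed.
    """
    lp = log_prior(prior, params)
    if lp == -np.inf:
        return -np.inf
    return lp + log_likelihood(params, data)
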