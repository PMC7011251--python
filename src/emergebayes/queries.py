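"""Posterior-draw queries, emergence curves and summary tables.

Once posteriors are in hand, treatment questions reduce to counting over
paired posterior draws:

* "do primed seedlings emerge earlier?" — :func:`prob_param_less` on the
  half-time C of the two groups;
* "does priming raise the yield by at least 5%?" — :func:`prob_scaled_ge`
  on alpha with factor 1.05.

Curve ensembles (:func:`curves_from_samples`) visualize prior-to-posterior
contraction; :func:`empirical_curve` gives the raw step function of a tray;
:func:`summarize` produces a per-group table of posterior means, sds and
central 95% credible intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    HOURS_PER_DAY,
    EmergenceDataset,
    ModelParams,
    gompertz_cdf,
    median_emergence_time,
)
from .inference import PARAM_NAMES, PosteriorSamples

__all__ = [
    "EmergenceCurve",
    "prob_param_less",
    "prob_scaled_ge",
    "mc_standard_error",
    "curves_from_samples",
    "empirical_curve",
    "summarize",
    "plot_curve_ensemble",
    "plot_param_posteriors",
]


@dataclass
class EmergenceCurve:
    """A time grid (days) with emergence probabilities in [0, 1].

    ``kind`` is one of "prior-sample", "posterior-sample" or "empirical".
    Model-based curves are alpha * F(t); the empirical curve is the
    right-continuous cumulative fraction emerged.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("curve values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Pairwise posterior-draw probabilities
# ---------------------------------------------------------------------------

def _paired_draws(
    samples_a: PosteriorSamples,
    samples_b: PosteriorSamples,
    param: str,
    n_pairs: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    if param not in PARAM_NAMES:
        raise ValueError(f"param must be one of {PARAM_NAMES}, got {param!r}")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if samples_a.n_draws == 0 or samples_b.n_draws == 0:
        raise ValueError("both sample sets must be non-empty")
    rng = np.random.default_rng(seed)
    xa = samples_a.param(param)[rng.integers(samples_a.n_draws, size=n_pairs)]
    xb = samples_b.param(param)[rng.integers(samples_b.n_draws, size=n_pairs)]
    return xa, xb


def prob_param_less(
    samples_a: PosteriorSamples,
    samples_b: PosteriorSamples,
    param: str,
    n_pairs: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of P(param_a < param_b) from two posteriors.

    Draws ``n_pairs`` values with replacement from each sample set
    independently (the two posteriors come from independent fits), pairs
    them, and returns the fraction of pairs with the first value strictly
    below the second.  Reproducible given ``seed``.
    """
    xa, xb = _paired_draws(samples_a, samples_b, param, n_pairs, seed)
    return float(np.mean(xa < xb))


def prob_scaled_ge(
    samples_a: PosteriorSamples,
    samples_b: PosteriorSamples,
    param: str,
    factor: float = 1.05,
    n_pairs: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of P(param_a >= factor * param_b).

    With ``param="alpha"`` and ``factor=1.05`` this answers "what is the
    probability that group A's emergence yield exceeds group B's by at
    least 5%?".  Ties count as successes (>=).
    """
    if not factor > 0:
        raise ValueError("factor must be positive")
    xa, xb = _paired_draws(samples_a, samples_b, param, n_pairs, seed)
    return float(np.mean(xa >= factor * xb))


def mc_standard_error(p: float, n_pairs: int) -> float:
    """Binomial Monte-Carlo standard error sqrt(p (1-p) / n_pairs)."""
    return math.sqrt(max(p * (1.0 - p), 0.0) / n_pairs)


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

def curves_from_samples(
    samples: PosteriorSamples,
    time_grid,
    n_curves: int = 100,
    seed: int = 0,
) -> list[EmergenceCurve]:
    """Emergence curves alpha_s * F(t; B_s, C_s) for subsampled draws.

    Subsamples ``n_curves`` parameter triples without replacement, so
    ``n_curves`` may not exceed the number of stored draws.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size == 0:
        raise ValueError("time grid must be non-empty")
    if n_curves > samples.n_draws:
        raise ValueError(
            f"cannot subsample {n_curves} curves from {samples.n_draws} draws"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(samples.n_draws, size=n_curves, replace=False)
    kind = f"{samples.source}-sample"
    curves = []
    for a, b, c in samples.draws[idx]:
        p = ModelParams(a, b, c)
        curves.append(EmergenceCurve(time_grid, a * gompertz_cdf(p, time_grid), kind))
    return curves


def empirical_curve(data: EmergenceDataset) -> EmergenceCurve:
    """Right-continuous cumulative fraction emerged, on the edge grid (days).

    The value at t_j is (sum of counts before t_j) / n_total; the terminal
    value is (n_total - M) / n_total.
    """
    if data.n_total == 0:
        raise ValueError("empirical curve undefined for an empty tray")
    cum = np.concatenate([[0.0], np.cumsum(data.counts)]) / data.n_total
    return EmergenceCurve(data.edges / HOURS_PER_DAY, cum, "empirical")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(samples_by_group: dict) -> pd.DataFrame:
    """Per-group posterior table: mean, sd and central 95% CI per parameter.

    Rows are group labels; columns are ``{param}_{stat}`` for param in
    alpha, B, C plus the derived median emergence time ``t50`` (days),
    computed per draw as C - log(log 2)/B.  Uncertainty is the posterior
    sd; intervals are the 2.5 and 97.5 posterior percentiles.
    """
    rows = {}
    for label, samples in samples_by_group.items():
        if samples.n_draws == 0:
            raise ValueError(f"group {label!r} has no draws")
        cols = {name: samples.param(name) for name in PARAM_NAMES}
        cols["t50"] = median_emergence_time(cols["B"], cols["C"])
        row = {}
        for name, x in cols.items():
            lo, hi = np.percentile(x, [2.5, 97.5])
            row[f"{name}_mean"] = float(np.mean(x))
            row[f"{name}_sd"] = float(np.std(x))
            row[f"{name}_ci_lo"] = float(lo)
            row[f"{name}_ci_hi"] = float(hi)
        rows[label] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_curve_ensemble(curves, path, data: EmergenceDataset | None = None) -> None:
    """Write a spaghetti plot of emergence curves, optionally with the data."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(curve.times, curve.values, color="C0", alpha=0.15, lw=1)
    if data is not None:
        emp = empirical_curve(data)
        ax.step(emp.times, emp.values, where="post", color="k", lw=1.5,
                label=data.label or "data")
        ax.legend(loc="lower right")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("fraction emerged")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_param_posteriors(samples_by_group: dict, param: str, path) -> None:
    """Overlaid posterior histograms of one parameter across groups."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, samples in samples_by_group.items():
        ax.hist(samples.param(param), bins=60, density=True, histtype="step",
                label=str(label))
    ax.set_xlabel(param)
    ax.set_ylabel("posterior density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
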