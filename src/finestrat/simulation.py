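"""Synthetic populations and the design-based comparison studies.

The generator emulates the study design used to compare the three variance
estimators: a population of N units split into H evenly sized strata with
stratum scores x_i = i/H, unit values

    y_k = mu*(x_i) + sigma * e_k,    e_k ~ iid N(0, 1),

where mu* is one of seven mean shapes (linear, quadratic, bump, jump,
exponential, one-cycle and four-cycle sinusoids) rescaled so its minimum on
[0, 1] is 0 and its maximum is 2.  Units additionally carry individual
auxiliary scores drawn uniformly within their stratum's cell
((i-1)/H, i/H] — marginally uniform on (0, 1) — so the sample mean x-bar
varies across replicates and the conditional study is non-degenerate.

The unconditional study keeps the population fixed, draws R independent
SRSWOR samples (n_i per stratum), computes the collapsed, kernel, and
bootstrap estimates on each, and reports empirical bias, RMSE, and CV against
the exact design variance.  The conditional study sorts the same R replicates
by x-bar, forms equally sized groups (50 groups of 20 when R = 1000), and
reports per-group mean x-bar, conditional bias, and CRMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .design import (
    StratifiedPopulation,
    Stratum,
    draw_srswor,
    ht_stratum_totals,
    true_variance,
)
from .estimators import (
    BootstrapSpec,
    bootstrap_variance,
    kernel_weights,
    make_pairing,
    v_collapsed,
    v_kernel,
)
from .exceptions import ConfigError, UndefinedRescaleError

__all__ = [
    "MEAN_FUNCTIONS",
    "RescaledMean",
    "rescale",
    "make_population",
    "SimulationConfig",
    "SimulationResult",
    "run_unconditional",
    "run_conditional",
]

logger = logging.getLogger("finestrat")

ESTIMATORS = ("collapsed", "kernel", "bootstrap")


# ---------------------------------------------------------------------------
# Mean functions
# ---------------------------------------------------------------------------


def _linear(x):
    return 1.0 + 2.0 * (x - 0.5)


def _quadratic(x):
    return 1.0 + 2.0 * (x - 0.5) ** 2


def _bump(x):
    return 1.0 + 2.0 * (x - 0.5) + np.exp(-200.0 * (x - 0.5) ** 2)


def _jump(x):
    return np.where(x <= 0.65, 1.0 + 2.0 * (x - 0.5), 0.65)


def _exponential(x):
    return np.exp(-8.0 * x)


def _cycle1(x):
    return 2.0 + np.sin(2.0 * np.pi * x)


def _cycle4(x):
    return 2.0 + np.sin(8.0 * np.pi * x)


#: The seven raw mean shapes on [0, 1]; ids are names, not indices.
MEAN_FUNCTIONS: dict[str, Callable] = {
    "linear": _linear,
    "quadratic": _quadratic,
    "bump": _bump,
    "jump": _jump,
    "exponential": _exponential,
    "cycle1": _cycle1,
    "cycle4": _cycle4,
}

RESCALE_GRID_POINTS = 100_001


@dataclass(frozen=True)
class RescaledMean:
    """A mean function affinely rescaled to range [0, 2] on [0, 1]."""

    raw: Callable
    low: float
    high: float
    name: str = ""

    def __call__(self, x):
        return 2.0 * (self.raw(x) - self.low) / (self.high - self.low)


def rescale(mu: Callable | str, grid_points: int = RESCALE_GRID_POINTS) -> RescaledMean:
    """Rescale a bounded mean function so min = 0 and max = 2 on [0, 1].

    Extrema are located on a dense grid (10^5 + 1 points by default).  A
    constant function has no defined rescale and raises
    :class:`UndefinedRescaleError`.
    """
    name = ""
    if isinstance(mu, str):
        if mu not in MEAN_FUNCTIONS:
            raise ConfigError(
                f"unknown mean function {mu!r}; choose from {sorted(MEAN_FUNCTIONS)}"
            )
        name, mu = mu, MEAN_FUNCTIONS[mu]
    grid = np.linspace(0.0, 1.0, grid_points)
    vals = np.asarray(mu(grid), dtype=float)
    low, high = float(vals.min()), float(vals.max())
    if high - low < 1e-12:
        raise UndefinedRescaleError("mean function is constant on [0, 1]")
    return RescaledMean(raw=mu, low=low, high=high, name=name)


# ---------------------------------------------------------------------------
# Population generator
# ---------------------------------------------------------------------------


def make_population(
    N: int,
    H: int,
    sigma: float,
    mean_fn: Callable | str | RescaledMean,
    rng: np.random.Generator | int | None = None,
) -> StratifiedPopulation:
    """Generate the synthetic stratified population.

    H strata of N_i = N/H units each; stratum i has score x_i = i/H and unit
    values mu*(x_i) + sigma * e_k.  Unit-level auxiliary scores are uniform
    within the stratum cell ((i-1)/H, i/H].
    """
    if N % H != 0:
        raise ConfigError(f"N={N} is not divisible by H={H}")
    if sigma < 0:
        raise ConfigError("sigma must be nonnegative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu = mean_fn if isinstance(mean_fn, RescaledMean) else rescale(mean_fn)
    N_i = N // H
    strata = []
    for i in range(1, H + 1):
        x_i = i / H
        e = rng.standard_normal(N_i) if sigma > 0 else np.zeros(N_i)
        y = mu(x_i) + sigma * e
        unit_x = (i - 1) / H + rng.uniform(size=N_i) / H
        strata.append(Stratum(id=i, x=x_i, y=y, unit_x=unit_x))
    return StratifiedPopulation(strata)


# ---------------------------------------------------------------------------
# Simulation configuration and engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario configuration for the comparison studies.

    Defaults follow the reference study conditions: N = 3000 units, noise
    sigma in {0, 0.25, 0.5}, H in {50, 100, 200} strata, bandwidth inside
    (1/H, 2/H), two PSUs per stratum, R = 1000 replicates grouped 50 x 20 in
    the conditional analysis, and B = 1000 bootstrap resamples of size
    n* = 2.
    """

    N: int = 3000
    H: int = 100
    sigma: float = 0.25
    mean_fn: str = "linear"
    h: float = 0.015
    n_per_stratum: int = 2
    R: int = 1000
    B: int = 1000
    n_star: int = 2
    corrector_mode: str = "sum_to_one"
    seed: int = 0
    n_collapsed: int | None = None
    n_groups: int = 50

    def __post_init__(self):
        if self.N % self.H != 0:
            raise ConfigError(f"N={self.N} is not divisible by H={self.H}")
        if self.h <= 0:
            raise ConfigError("bandwidth h must be positive")
        if self.R < 1:
            raise ConfigError("R must be >= 1")
        if self.n_per_stratum < 1:
            raise ConfigError("n_per_stratum must be >= 1")
        if self.mean_fn not in MEAN_FUNCTIONS:
            raise ConfigError(
                f"unknown mean function {self.mean_fn!r}; "
                f"choose from {sorted(MEAN_FUNCTIONS)}"
            )
        if self.n_collapsed is not None:
            if not (2 <= self.n_collapsed <= self.H):
                raise ConfigError("n_collapsed must lie in [2, H]")
            if self.n_collapsed % 2 != 0 and self.n_collapsed != self.H:
                raise ConfigError("n_collapsed must be even (pairs) or equal H")

    @property
    def bootstrap_spec(self) -> BootstrapSpec:
        return BootstrapSpec(B=self.B, n_star=self.n_star, mode=self.corrector_mode)


@dataclass(frozen=True)
class SimulationResult:
    """Replicate-level values plus summary tables for one scenario."""

    config: SimulationConfig
    v_true: float
    replicates: pd.DataFrame
    metrics: pd.DataFrame
    conditional: pd.DataFrame | None = None

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: H, h, sigma, mean_fn, estimator, metric, value."""
        rows = []
        for _, r in self.metrics.iterrows():
            for metric in ("bias", "rmse", "cv"):
                rows.append(
                    {
                        "H": self.config.H,
                        "h": self.config.h,
                        "sigma": self.config.sigma,
                        "mean_fn": self.config.mean_fn,
                        "estimator": r["estimator"],
                        "metric": metric,
                        "value": r[metric],
                    }
                )
        return pd.DataFrame(rows)


def _partial_collapsed(sample, t_hat, n_collapsed):
    """Collapsed estimator when only the first ``n_collapsed`` strata are paired.

    The remaining strata (which must hold n_i >= 2 units) contribute the
    standard within-stratum SRSWOR variance estimate N^2 (1 - f) s^2 / n.
    """
    plan = make_pairing(n_collapsed)
    value = v_collapsed(t_hat[:n_collapsed], plan).value
    for s in sample.strata[n_collapsed:]:
        if s.n < 2:
            raise ConfigError(
                "uncollapsed strata need n_i >= 2 for the within-stratum estimate"
            )
        f = s.n / s.population_size
        value += s.population_size**2 * (1.0 - f) * float(np.var(s.y, ddof=1)) / s.n
    return value


def _run_replicates(config: SimulationConfig):
    """Shared engine: fixed population, R independent sample replicates.

    Seed layout: the root SeedSequence spawns (population stream, replicate
    parent); the replicate parent spawns one child per replicate, and each
    child spawns (sampling stream, bootstrap stream).  Extending R therefore
    leaves earlier replicates unchanged.
    """
    root = np.random.SeedSequence(config.seed)
    pop_ss, rep_parent = root.spawn(2)
    population = make_population(
        config.N,
        config.H,
        config.sigma,
        config.mean_fn,
        rng=np.random.default_rng(pop_ss),
    )
    v_true = true_variance(population, config.n_per_stratum).total

    plan = make_pairing(config.H)
    W = kernel_weights(population.scores, config.h)
    spec = config.bootstrap_spec

    rows = []
    for r, child in enumerate(rep_parent.spawn(config.R)):
        sample_ss, boot_ss = child.spawn(2)
        sample = draw_srswor(population, config.n_per_stratum, seed=sample_ss)
        t_hat, t_hat_total = ht_stratum_totals(sample)
        row = {"replicate": r, "xbar": sample.xbar, "t_hat": t_hat_total}
        # estimator failures are recorded per replicate, never fatal
        try:
            if config.n_collapsed is not None and config.n_collapsed < config.H:
                row["collapsed"] = _partial_collapsed(sample, t_hat, config.n_collapsed)
            else:
                row["collapsed"] = v_collapsed(t_hat, plan).value
        except Exception as exc:  # pragma: no cover - defensive
            row["collapsed"], row["collapsed_error"] = np.nan, str(exc)
        try:
            row["kernel"] = v_kernel(t_hat, W).value
        except Exception as exc:  # pragma: no cover - defensive
            row["kernel"], row["kernel_error"] = np.nan, str(exc)
        try:
            row["bootstrap"] = bootstrap_variance(
                sample, spec, rng=np.random.default_rng(boot_ss)
            ).value
        except Exception as exc:
            row["bootstrap"], row["bootstrap_error"] = np.nan, str(exc)
        rows.append(row)
    return population, v_true, pd.DataFrame(rows)


def _summary_metrics(replicates: pd.DataFrame, v_true: float) -> pd.DataFrame:
    rows = []
    for est in ESTIMATORS:
        v = replicates[est].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        mean = float(np.mean(v))
        bias = mean - v_true
        rmse = float(np.sqrt(np.mean((v - v_true) ** 2)))
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        cv = sd / mean if mean != 0.0 else np.inf
        rows.append(
            {
                "estimator": est,
                "mean": mean,
                "bias": bias,
                "rmse": rmse,
                "cv": cv,
                "n_ok": int(v.size),
            }
        )
    return pd.DataFrame(rows)


def run_unconditional(config: SimulationConfig) -> SimulationResult:
    """Unconditional comparison: empirical bias, RMSE, and CV per estimator.

    The population is generated once and held fixed; bias and RMSE are taken
    against the exact design variance of the HT total under the SRSWOR
    design.
    """
    logger.info("unconditional study: %s", config)
    _, v_true, replicates = _run_replicates(config)
    metrics = _summary_metrics(replicates, v_true)
    logger.info("true design variance: %g", v_true)
    return SimulationResult(
        config=config, v_true=v_true, replicates=replicates, metrics=metrics
    )


def run_conditional(config: SimulationConfig) -> SimulationResult:
    """Conditional comparison: group replicates by the sample mean x-bar.

    The R replicates are sorted by x-bar and cut into ``n_groups`` equally
    sized consecutive groups (50 groups of 20 when R = 1000); each group
    reports its mean x-bar, conditional bias, and conditional RMSE (CRMSE)
    per estimator.  Equally weighted pooling of the group biases reproduces
    the unconditional bias exactly.
    """
    if config.R % config.n_groups != 0:
        raise ConfigError(
            f"R={config.R} is not divisible into {config.n_groups} equal groups"
        )
    logger.info("conditional study: %s", config)
    _, v_true, replicates = _run_replicates(config)
    metrics = _summary_metrics(replicates, v_true)

    per_group = config.R // config.n_groups
    order = np.argsort(replicates["xbar"].to_numpy(), kind="stable")
    sorted_reps = replicates.iloc[order].reset_index(drop=True)
    rows = []
    for g in range(config.n_groups):
        block = sorted_reps.iloc[g * per_group : (g + 1) * per_group]
        for est in ESTIMATORS:
            v = block[est].to_numpy(dtype=float)
            rows.append(
                {
                    "group": g,
                    "xbar": float(block["xbar"].mean()),
                    "estimator": est,
                    "bias": float(np.mean(v) - v_true),
                    "crmse": float(np.sqrt(np.mean((v - v_true) ** 2))),
                }
            )
    conditional = pd.DataFrame(rows)
    return SimulationResult(
        config=config,
        v_true=v_true,
        replicates=replicates,
        metrics=metrics,
        conditional=conditional,
    )


def plot_conditional(result: SimulationResult, path, metric: str = "bias"):
    """Plot per-group conditional bias or CRMSE against mean x-bar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.conditional is None:
        raise ValueError("result has no conditional table")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for est in ESTIMATORS:
        sub = result.conditional[result.conditional["estimator"] == est]
        ax.plot(sub["xbar"], sub[metric], marker="o", ms=3, lw=1, label=est)
    ax.set_xlabel("group mean of sample x-bar")
    ax.set_ylabel(f"conditional {metric}")
    ax.set_title(
        f"{result.config.mean_fn}, H={result.config.H}, sigma={result.config.sigma}"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
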