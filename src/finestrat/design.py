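"""Finite-population data model and design-based estimation primitives.

A :class:`StratifiedPopulation` is the full sampling frame: H strata, each
with a known size ``N_i``, a stratum-level auxiliary score ``x_i`` used for
ordering/pairing/kernel smoothing, and the unit values ``y_k``.  A
:class:`StratifiedSample` holds the drawn units together with their inclusion
probabilities; the Horvitz-Thompson (HT) estimator of the population total is

    t_hat = sum_i t_hat_i,    t_hat_i = sum_{k in s_i} y_k / pi_k,

which is design-unbiased whenever all pi_k > 0.  Under simple random sampling
without replacement (SRSWOR) within stratum, pi_k = n_i / N_i and the design
variance of t_hat_i has the closed form N_i^2 (1 - n_i/N_i) S_i^2 / n_i.

Strata are always kept globally ordered by (x, id); every pairing and kernel
operation downstream consumes that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .exceptions import InfeasibleDesignError, InvalidDesignError

__all__ = [
    "Stratum",
    "StratifiedPopulation",
    "SampledStratum",
    "StratifiedSample",
    "DesignVariance",
    "ht_stratum_totals",
    "draw_srswor",
    "true_variance",
]


def _as_1d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _sort_key(item) -> tuple:
    return (item.x, str(item.id))


@dataclass(frozen=True)
class Stratum:
    """One population stratum: id, auxiliary score x, and all N_i unit values.

    ``unit_x`` optionally carries unit-level auxiliary values (e.g. the
    uniform scores the synthetic generator produces); when absent every unit
    is taken to share the stratum score ``x``.
    """

    id: object
    x: float
    y: np.ndarray
    unit_x: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "y", _as_1d_float(self.y, "y"))
        if self.unit_x is not None:
            ux = _as_1d_float(self.unit_x, "unit_x")
            if ux.size != self.y.size:
                raise ValueError("unit_x must have one value per unit")
            object.__setattr__(self, "unit_x", ux)

    @property
    def size(self) -> int:
        """Stratum population size N_i."""
        return int(self.y.size)

    @property
    def total(self) -> float:
        """True stratum total t_i."""
        return float(self.y.sum())


class StratifiedPopulation:
    """An ordered collection of strata; the ground truth for design moments."""

    def __init__(self, strata: Iterable[Stratum]):
        strata = sorted(strata, key=_sort_key)
        if not strata:
            raise ValueError("population must contain at least one stratum")
        ids = [s.id for s in strata]
        if len(set(ids)) != len(ids):
            raise ValueError("stratum ids must be unique")
        self.strata: tuple[Stratum, ...] = tuple(strata)

    @classmethod
    def from_units(cls, stratum_ids, x, y, unit_x=None) -> "StratifiedPopulation":
        """Build a population from parallel per-unit arrays.

        ``x`` must be constant within each stratum (it is a stratum score).
        """
        stratum_ids = np.asarray(stratum_ids)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        strata = []
        for sid in pd_unique(stratum_ids):
            mask = stratum_ids == sid
            xs = np.unique(x[mask])
            if xs.size != 1:
                raise ValueError(f"stratum {sid!r} has non-constant score x")
            ux = None if unit_x is None else np.asarray(unit_x, float)[mask]
            strata.append(Stratum(id=sid, x=float(xs[0]), y=y[mask], unit_x=ux))
        return cls(strata)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([s.size for s in self.strata], dtype=int)

    @property
    def total_size(self) -> int:
        return int(self.sizes.sum())

    @property
    def scores(self) -> np.ndarray:
        """Stratum scores x_i, ascending."""
        return np.array([s.x for s in self.strata], dtype=float)

    @property
    def stratum_totals(self) -> np.ndarray:
        return np.array([s.total for s in self.strata], dtype=float)

    @property
    def total(self) -> float:
        return float(self.stratum_totals.sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"StratifiedPopulation(H={self.n_strata}, N={self.total_size}, "
            f"t={self.total:.6g})"
        )


def pd_unique(values: np.ndarray):
    """First-appearance unique (order-preserving), without requiring pandas."""
    seen: dict = {}
    for v in values.tolist():
        seen.setdefault(v, None)
    return list(seen)


@dataclass(frozen=True)
class SampledStratum:
    """Sampled units of one stratum with their inclusion probabilities."""

    id: object
    x: float
    population_size: int
    y: np.ndarray
    pi: np.ndarray
    unit_x: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "y", _as_1d_float(self.y, "y"))
        pi = _as_1d_float(self.pi, "pi")
        if pi.size != self.y.size:
            raise InvalidDesignError("pi must have one value per sampled unit")
        if np.any(pi <= 0.0) or np.any(pi > 1.0):
            raise InvalidDesignError("inclusion probabilities must lie in (0, 1]")
        object.__setattr__(self, "pi", pi)
        if self.population_size < self.y.size:
            raise InvalidDesignError("sample larger than stratum population")
        if self.unit_x is not None:
            ux = _as_1d_float(self.unit_x, "unit_x")
            if ux.size != self.y.size:
                raise ValueError("unit_x must have one value per sampled unit")
            object.__setattr__(self, "unit_x", ux)

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def ht_total(self) -> float:
        return float(np.sum(self.y / self.pi))


class StratifiedSample:
    """Sampled units from every stratum, ordered by the stratum score."""

    def __init__(self, strata: Iterable[SampledStratum], with_replacement: bool = False):
        strata = sorted(strata, key=_sort_key)
        if not strata:
            raise InvalidDesignError("sample must contain at least one stratum")
        ids = [s.id for s in strata]
        if len(set(ids)) != len(ids):
            raise InvalidDesignError("stratum ids must be unique")
        self.strata: tuple[SampledStratum, ...] = tuple(strata)
        self.with_replacement = bool(with_replacement)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s.x for s in self.strata], dtype=float)

    @property
    def sample_sizes(self) -> np.ndarray:
        return np.array([s.n for s in self.strata], dtype=int)

    @property
    def population_sizes(self) -> np.ndarray:
        return np.array([s.population_size for s in self.strata], dtype=int)

    @property
    def xbar(self) -> float:
        """Sample mean of the auxiliary score over all sampled units.

        Uses unit-level scores when present, otherwise the stratum score.
        """
        parts = [
            s.unit_x if s.unit_x is not None else np.full(s.n, s.x)
            for s in self.strata
        ]
        return float(np.concatenate(parts).mean())

    def scale_y(self, a: float) -> "StratifiedSample":
        """Return a copy with every observed y multiplied by ``a``."""
        return StratifiedSample(
            [
                SampledStratum(
                    id=s.id,
                    x=s.x,
                    population_size=s.population_size,
                    y=a * s.y,
                    pi=s.pi,
                    unit_x=s.unit_x,
                )
                for s in self.strata
            ],
            with_replacement=self.with_replacement,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StratifiedSample(H={self.n_strata}, n={int(self.sample_sizes.sum())})"


@dataclass(frozen=True)
class DesignVariance:
    """True per-stratum design variances V_i and their total V = sum V_i."""

    per_stratum: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.per_stratum, dtype=float)
        if np.any(v < -1e-12):
            raise ValueError("design variances must be nonnegative")
        object.__setattr__(self, "per_stratum", np.maximum(v, 0.0))

    @property
    def total(self) -> float:
        return float(self.per_stratum.sum())


def ht_stratum_totals(sample: StratifiedSample) -> tuple[np.ndarray, float]:
    """Horvitz-Thompson stratum totals t_hat_i and the overall total t_hat.

    Parameters
    ----------
    sample
        Stratified sample with positive inclusion probabilities.

    Returns
    -------
    (t_hat_i, t_hat)
        Vector of per-stratum HT totals (in x-order) and their sum.
    """
    totals = np.array([s.ht_total for s in sample.strata], dtype=float)
    return totals, float(totals.sum())


def _normalize_sizes(n, H: int) -> np.ndarray:
    if np.isscalar(n):
        n = np.full(H, int(n))
    n = np.asarray(n, dtype=int)
    if n.shape != (H,):
        raise ValueError(f"expected {H} per-stratum sample sizes, got shape {n.shape}")
    if np.any(n < 1):
        raise InfeasibleDesignError("per-stratum sample sizes must be >= 1")
    return n


def draw_srswor(
    population: StratifiedPopulation,
    n,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> StratifiedSample:
    """Draw an SRSWOR sample of size n_i from each stratum.

    Each size-n_i subset of stratum i is equally likely and pi_k = n_i/N_i is
    recorded on every sampled unit.  Reproducible: the per-stratum random
    streams are spawned deterministically from one root seed.

    Parameters
    ----------
    population
        The sampling frame.
    n
        Scalar or per-stratum (x-ordered) sample sizes.
    seed
        Root seed (int or SeedSequence) or an existing Generator.
    """
    H = population.n_strata
    n = _normalize_sizes(n, H)
    sizes = population.sizes
    if np.any(n > sizes):
        bad = np.nonzero(n > sizes)[0][0]
        raise InfeasibleDesignError(
            f"stratum {population.strata[bad].id!r}: n_i={n[bad]} exceeds N_i={sizes[bad]}"
        )
    if isinstance(seed, np.random.Generator):
        rngs = [seed] * H
    else:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        rngs = [np.random.default_rng(child) for child in ss.spawn(H)]

    sampled = []
    for stratum, n_i, rng in zip(population.strata, n, rngs):
        idx = rng.choice(stratum.size, size=int(n_i), replace=False)
        idx.sort()
        pi = np.full(int(n_i), n_i / stratum.size)
        ux = None if stratum.unit_x is None else stratum.unit_x[idx]
        sampled.append(
            SampledStratum(
                id=stratum.id,
                x=stratum.x,
                population_size=stratum.size,
                y=stratum.y[idx],
                pi=pi,
                unit_x=ux,
            )
        )
    return StratifiedSample(sampled)


def true_variance(population: StratifiedPopulation, n) -> DesignVariance:
    """Exact design variance of the HT total under per-stratum SRSWOR.

    For n_i >= 2 the closed form ``N_i^2 (1 - n_i/N_i) S_i^2 / n_i`` is used
    (S_i^2 the stratum population variance with divisor N_i - 1).  For
    n_i = 1 the joint inclusion probabilities vanish (pi_kl = 0, k != l) and
    the general HT variance reduces to ``N_i * sum(y^2) - t_i^2``; the two
    expressions agree algebraically, but the n_i = 1 branch is evaluated
    directly from its defining double sum.
    """
    H = population.n_strata
    n = _normalize_sizes(n, H)
    V = np.empty(H, dtype=float)
    for j, (stratum, n_i) in enumerate(zip(population.strata, n)):
        N_i = stratum.size
        if n_i > N_i:
            raise InfeasibleDesignError(
                f"stratum {stratum.id!r}: n_i={n_i} exceeds N_i={N_i}"
            )
        y = stratum.y
        if N_i == 1:
            V[j] = 0.0
        elif n_i == 1:
            # pi_k = 1/N, pi_kl = 0 for k != l: the double sum collapses to
            # N * sum(y_k^2) - t_i^2.
            V[j] = N_i * float(np.sum(y * y)) - stratum.total ** 2
        else:
            s2 = float(np.var(y, ddof=1))
            f = n_i / N_i
            V[j] = N_i * N_i * (1.0 - f) * s2 / n_i
    return DesignVariance(per_stratum=V)
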