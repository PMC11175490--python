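"""Exact design and resampling distributions on tiny instances.

These brute-force enumerators are the ground-truth surface for the package:
every SRSWOR sample (or every ordered bootstrap draw) is visited once with
its exact probability, so design expectations, variances, and bias identities
can be checked without Monte-Carlo error.  Probabilities are exact rationals
(:class:`fractions.Fraction`) by default; hard combinatorial caps guard
against accidental blow-ups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

from .design import (
    SampledStratum,
    StratifiedPopulation,
    StratifiedSample,
    _normalize_sizes,
)
from .exceptions import EnumerationLimitError

__all__ = ["DesignDistribution", "enumerate_design", "exact_bootstrap_law"]

MAX_OUTCOMES = 10**6


@dataclass(frozen=True)
class DesignDistribution:
    """A finite distribution of a statistic over an enumerated design.

    One entry per distinct sample (or ordered bootstrap draw); probabilities
    are Fractions summing exactly to one when ``exact`` arithmetic is used.
    """

    probabilities: tuple
    values: tuple

    def __post_init__(self):
        if len(self.probabilities) != len(self.values):
            raise ValueError("probabilities and values must have equal length")
        total = sum(self.probabilities)
        if isinstance(total, Fraction):
            if total != 1:
                raise ValueError(f"probabilities sum to {total}, not 1")
        elif abs(float(total) - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_exact(self) -> bool:
        return bool(self.probabilities) and isinstance(self.probabilities[0], Fraction)

    def _terms(self):
        # Fraction(v) is exact for any float v, so exact probabilities give
        # exact rational moments (floats are binary rationals).
        if self.is_exact:
            return [(p, Fraction(v)) for p, v in zip(self.probabilities, self.values)]
        return list(zip(self.probabilities, self.values))

    def mean(self) -> float:
        return float(sum(p * v for p, v in self._terms()))

    def variance(self) -> float:
        terms = self._terms()
        m = sum(p * v for p, v in terms)
        return float(sum(p * (v - m) * (v - m) for p, v in terms))

    def sd(self) -> float:
        return math.sqrt(max(self.variance(), 0.0))


def enumerate_design(
    population: StratifiedPopulation,
    n,
    statistic: Callable[[StratifiedSample], float],
    exact: bool = True,
) -> DesignDistribution:
    """Enumerate every SRSWOR sample and evaluate ``statistic`` on each.

    Each combination of size-n_i subsets (one per stratum) appears once with
    probability 1 / prod_i C(N_i, n_i).  Raises
    :class:`EnumerationLimitError` when the number of combinations exceeds
    ``MAX_OUTCOMES``.
    """
    H = population.n_strata
    n = _normalize_sizes(n, H)
    sizes = population.sizes
    counts = [math.comb(int(N), int(k)) for N, k in zip(sizes, n)]
    total = math.prod(counts)
    if total > MAX_OUTCOMES:
        raise EnumerationLimitError(
            f"{total} sample combinations exceed the cap of {MAX_OUTCOMES}"
        )
    prob = Fraction(1, total) if exact else 1.0 / total

    per_stratum_choices = [
        list(itertools.combinations(range(int(N)), int(k)))
        for N, k in zip(sizes, n)
    ]
    probs, values = [], []
    for combo in itertools.product(*per_stratum_choices):
        sampled = []
        for stratum, k, idx in zip(population.strata, n, combo):
            idx = np.asarray(idx, dtype=int)
            pi = np.full(int(k), k / stratum.size)
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
        probs.append(prob)
        values.append(float(statistic(StratifiedSample(sampled))))
    return DesignDistribution(probabilities=tuple(probs), values=tuple(values))


def exact_bootstrap_law(
    z: Sequence[float], n_star: int, exact: bool = True
) -> DesignDistribution:
    """Exact distribution of one pseudo-stratum's bootstrap replicate total.

    All m^{n*} ordered with-replacement draws from the m HT contributions are
    enumerated, each with probability m^{-n*}; the replicate total is
    (m/n*) * sum(draw), so the exact mean equals sum(z).
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("z must be a non-empty vector of HT contributions")
    m = z.size
    if n_star < 1:
        raise ValueError("n_star must be >= 1")
    total = m**n_star
    if total > MAX_OUTCOMES:
        raise EnumerationLimitError(
            f"{total} ordered draws exceed the cap of {MAX_OUTCOMES}"
        )
    prob = Fraction(1, total) if exact else 1.0 / total
    scale = m / n_star
    probs, values = [], []
    for draw in itertools.product(range(m), repeat=n_star):
        probs.append(prob)
        values.append(float(scale * z[list(draw)].sum()))
    return DesignDistribution(probabilities=tuple(probs), values=tuple(values))
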