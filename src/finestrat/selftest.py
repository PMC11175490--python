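"""Built-in identity suite: exact design-moment checks on tiny instances.

Each check pits an estimator or closed-form moment against the brute-force
enumeration oracle (or a quadrature/grid oracle) and reports pass/fail; the
``finestrat selftest`` subcommand prints the table.  All checks are exact up
to floating-point roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .design import StratifiedPopulation, Stratum, ht_stratum_totals, true_variance
from .estimators import (
    collapsed_bias_exact,
    epanechnikov,
    kernel_expectation_exact,
    kernel_weights,
    make_pairing,
    pair_weights,
    v_collapsed,
    v_kernel,
)
from .oracle import enumerate_design, exact_bootstrap_law
from .simulation import MEAN_FUNCTIONS, rescale

__all__ = ["SelfTestResult", "run_selftest"]


@dataclass(frozen=True)
class SelfTestResult:
    name: str
    passed: bool
    detail: str


def _toy_population(H: int, seed: int = 0) -> StratifiedPopulation:
    rng = np.random.default_rng(seed)
    strata = [
        Stratum(id=i, x=i / H, y=rng.integers(0, 9, size=int(rng.integers(2, 5))))
        for i in range(1, H + 1)
    ]
    return StratifiedPopulation(strata)


def run_selftest(seed: int = 0) -> list[SelfTestResult]:
    """Run the full identity suite; every check should pass on any machine."""
    results: list[SelfTestResult] = []

    def record(name: str, passed: bool, detail: str):
        results.append(SelfTestResult(name=name, passed=bool(passed), detail=detail))

    # 1. HT unbiasedness: enumerated E[t_hat] = t exactly
    pop = _toy_population(3, seed)
    dist = enumerate_design(pop, 1, lambda s: ht_stratum_totals(s)[1])
    err = abs(dist.mean() - pop.total)
    record("ht_unbiasedness", err <= 1e-10, f"|E[t_hat] - t| = {err:.2e}")

    # 2. variance additivity: enumerated var(t_hat) = sum V_i
    err = abs(dist.variance() - true_variance(pop, 1).total)
    record("variance_additivity", err <= 1e-8, f"|var - sum V_i| = {err:.2e}")

    # 3. collapsed bias identity: E[V_col] - var(t_hat) = closed form
    pop4 = _toy_population(4, seed + 1)
    plan = make_pairing(4)
    dist_col = enumerate_design(
        pop4, 1, lambda s: v_collapsed(ht_stratum_totals(s)[0], plan).value
    )
    dist_t = enumerate_design(pop4, 1, lambda s: ht_stratum_totals(s)[1])
    lhs = dist_col.mean() - dist_t.variance()
    rhs = collapsed_bias_exact(pop4.stratum_totals, plan)
    record("collapsed_bias_identity", abs(lhs - rhs) <= 1e-8, f"|diff| = {abs(lhs - rhs):.2e}")

    # 4. kernel expectation identity
    W = kernel_weights(pop4.scores, 1.5 / 4)
    dist_ker = enumerate_design(
        pop4, 1, lambda s: v_kernel(ht_stratum_totals(s)[0], W).value
    )
    expectation, bias = kernel_expectation_exact(
        pop4.stratum_totals, true_variance(pop4, 1), W
    )
    err = abs(dist_ker.mean() - expectation)
    record(
        "kernel_expectation_identity",
        err <= 1e-8 and bias >= 0,
        f"|diff| = {err:.2e}, bias = {bias:.4g}",
    )

    # 5. degenerate equivalence: binary pair weights make kernel == collapsed
    rng = np.random.default_rng(seed + 2)
    t_hat = rng.normal(size=6)
    plan6 = make_pairing(6)
    a = v_kernel(t_hat, pair_weights(plan6)).value
    b = v_collapsed(t_hat, plan6).value
    rel = abs(a - b) / max(abs(b), 1e-300)
    record("pair_weight_equivalence", rel <= 1e-12, f"rel diff = {rel:.2e}")

    # 6. exact bootstrap law is unbiased for the pseudo-stratum total
    z = np.array([4.0, 6.0, 1.0])
    law = exact_bootstrap_law(z, 2)
    err = abs(law.mean() - z.sum())
    record("bootstrap_law_unbiased", err <= 1e-10, f"|E[t*] - t| = {err:.2e}")

    # 7. kernel facts
    k0 = float(epanechnikov(0.0))
    k1 = float(epanechnikov(1.0))
    integral, _ = integrate.quad(epanechnikov, -1, 1)
    record(
        "epanechnikov_facts",
        abs(k0 - 0.75) <= 1e-15 and k1 == 0.0 and abs(integral - 1.0) <= 1e-8,
        f"K(0)={k0}, K(1)={k1}, integral={integral:.10f}",
    )

    # 8. rescaling contract: every mean function spans [0, 2] on the grid
    ok, worst = True, 0.0
    grid = np.linspace(0, 1, 100_001)
    for name in MEAN_FUNCTIONS:
        mu = rescale(name)
        vals = mu(grid)
        dev = max(abs(float(vals.min())), abs(float(vals.max()) - 2.0))
        worst = max(worst, dev)
        ok = ok and dev <= 1e-6
    record("rescale_contract", ok, f"worst endpoint deviation = {worst:.2e}")

    return results


def format_selftest(results: list[SelfTestResult]) -> str:
    width = max(len(r.name) for r in results)
    lines = [
        f"{r.name.ljust(width)}  {'PASS' if r.passed else 'FAIL'}  {r.detail}"
        for r in results
    ]
    n_fail = sum(not r.passed for r in results)
    lines.append(f"{len(results) - n_fail}/{len(results)} checks passed")
    return "\n".join(lines)
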