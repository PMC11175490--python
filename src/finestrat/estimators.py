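"""Variance estimators for a total under fine stratification.

Three estimators of var(t_hat) when each stratum contributes only one or two
PSUs, so the within-stratum variance cannot be estimated directly:

* **Collapsed stratum** — strata are grouped (normally paired by their score
  x) and between-stratum squared differences stand in for the within-stratum
  variance:

      V_col = 1/2 * sum_i (t_hat_i - sum_j c_j(i) t_hat_j)^2,

  with c_j(i) = 1 iff i != j share a group.  It is design-biased upward by
  ``1/2 * sum_i (t_i - sum_j c_j(i) t_j)^2`` evaluated on the *true* stratum
  totals, which is small when paired strata are well matched.

* **Kernel-weighted** — the binary pair indicator is replaced by smooth
  row-normalized Epanechnikov weights d_j(i) over the stratum scores:

      V_ker = (1/c_d) * sum_i (t_hat_i - sum_j d_j(i) t_hat_j)^2,

  where the nonrandom constant c_d = (1/H) sum_i (1 - 2 d_i(i) + sum_j
  d_j(i)^2) makes the variance part of the expectation unbiased when the
  stratum variances are constant.

* **Bootstrap-bias-corrected** — singleton strata are merged into
  pseudo-strata of >= 2 units; within each pseudo-stratum j, n* units are
  resampled with replacement B times from the HT contributions, the
  first-order bootstrap bias corrector a_j = 2 t_hat_j - mean_b(t_hat*_bj) is
  formed, and the corrector (normalized to sum to one by default) replaces
  the kernel weights:

      V_boot = (1/c_b) * sum_i (t_hat_i - sum_j w_j t_hat_j)^2,

  with c_b defined by analogy with c_d.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import StratifiedSample, SampledStratum, ht_stratum_totals
from .exceptions import (
    CannotBootstrapError,
    CannotCollapseError,
    DegenerateBandwidthError,
    DegenerateCorrectorError,
    DegenerateNormalizerError,
)

__all__ = [
    "CollapsingPlan",
    "KernelSpec",
    "KernelWeightMatrix",
    "BootstrapSpec",
    "VarianceEstimate",
    "CorrectorResult",
    "CollapseResult",
    "make_pairing",
    "v_collapsed",
    "collapsed_bias_exact",
    "epanechnikov",
    "kernel_weights",
    "pair_weights",
    "v_kernel",
    "kernel_expectation_exact",
    "collapse_singletons",
    "bootstrap_replicates",
    "bias_corrector",
    "v_bootstrap",
    "collapsed_variance",
    "kernel_variance",
    "bootstrap_variance",
]


@dataclass(frozen=True)
class VarianceEstimate:
    """A variance estimate with its estimator id and diagnostics."""

    value: float
    estimator: str
    diagnostics: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.value)


# ---------------------------------------------------------------------------
# Collapsed stratum estimator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CollapsingPlan:
    """A partition of the x-ordered stratum indices into pseudo-strata.

    The indicator c_j(i) is 1 iff i != j belong to the same group; it is
    symmetric with zero diagonal by construction.
    """

    groups: tuple[tuple[int, ...], ...]
    n_strata: int

    def __post_init__(self):
        flat = [i for g in self.groups for i in g]
        if sorted(flat) != list(range(self.n_strata)):
            raise ValueError("groups must partition the stratum indices exactly once")
        object.__setattr__(
            self, "groups", tuple(tuple(int(i) for i in g) for g in self.groups)
        )

    @property
    def group_sizes(self) -> tuple[int, ...]:
        return tuple(len(g) for g in self.groups)

    def indicator(self) -> np.ndarray:
        """The H x H matrix with entries c_j(i)."""
        C = np.zeros((self.n_strata, self.n_strata))
        for g in self.groups:
            for i in g:
                for j in g:
                    if i != j:
                        C[i, j] = 1.0
        return C

    def is_identity(self) -> bool:
        return all(len(g) == 1 for g in self.groups)


def make_pairing(n_strata: int, group_size: int = 2) -> CollapsingPlan:
    """Group consecutive strata (in x-order) into pseudo-strata.

    Strata (0,1), (2,3), ... are paired; when the count is not divisible by
    ``group_size`` the remainder is folded into the final group, so an odd H
    with pairs yields one trailing group of three.
    """
    if n_strata < 2:
        raise CannotCollapseError("need at least two strata to collapse")
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    groups = [
        tuple(range(start, min(start + group_size, n_strata)))
        for start in range(0, n_strata, group_size)
    ]
    if len(groups[-1]) < 2:
        tail = groups.pop()
        groups[-1] = groups[-1] + tail
    return CollapsingPlan(groups=tuple(groups), n_strata=n_strata)


def _collapsed_quadratic(totals: np.ndarray, plan: CollapsingPlan) -> float:
    if len(totals) != plan.n_strata:
        raise ValueError("totals length must equal the plan's stratum count")
    if any(s < 2 for s in plan.group_sizes):
        raise CannotCollapseError("every collapsed group must contain >= 2 strata")
    C = plan.indicator()
    resid = totals - C @ totals
    return 0.5 * float(np.sum(resid * resid))


def v_collapsed(t_hat: Sequence[float], plan: CollapsingPlan) -> VarianceEstimate:
    """Collapsed stratum variance estimator (pairs give sum of (t_i - t_j)^2)."""
    t_hat = np.asarray(t_hat, dtype=float)
    value = _collapsed_quadratic(t_hat, plan)
    return VarianceEstimate(
        value=value, estimator="collapsed", diagnostics={"plan": plan}
    )


def collapsed_bias_exact(t: Sequence[float], plan: CollapsingPlan) -> float:
    """Exact design bias of the collapsed estimator, from true stratum totals.

    Equals ``1/2 * sum_i (t_i - sum_j c_j(i) t_j)^2`` and is therefore always
    nonnegative; it vanishes when the totals are matched within every pair.
    For size-2 groups this is exactly E[V_col] - var(t_hat).
    """
    return _collapsed_quadratic(np.asarray(t, dtype=float), plan)


# ---------------------------------------------------------------------------
# Kernel-weighted estimator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelSpec:
    """Kernel id and bandwidth for the local stratum weights."""

    h: float
    kernel: str = "epanechnikov"

    def __post_init__(self):
        if not self.h > 0:
            raise ValueError("bandwidth h must be positive")
        if self.kernel != "epanechnikov":
            raise ValueError(f"unsupported kernel {self.kernel!r}")


def epanechnikov(s) -> np.ndarray:
    """Epanechnikov kernel K(s) = 3/4 (1 - s^2) on |s| <= 1, else 0."""
    s = np.asarray(s, dtype=float)
    out = 0.75 * (1.0 - s * s)
    out = np.where(np.abs(s) <= 1.0, out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class KernelWeightMatrix:
    """H x H local weights d_j(i), each row summing to one, with constant c_d.

    c_d = (1/H) sum_i (1 - 2 d_i(i) + sum_j d_j(i)^2); it is nonnegative and
    vanishes only when the matrix is the identity (every stratum sees only
    itself), which makes the kernel estimator undefined.
    """

    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(d < -1e-12):
            raise ValueError("kernel weights must be nonnegative")
        rows = d.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("every weight row must sum to one")
        object.__setattr__(self, "d", d)

    @property
    def n_strata(self) -> int:
        return self.d.shape[0]

    @property
    def c_d(self) -> float:
        diag = np.diag(self.d)
        return float(np.mean(1.0 - 2.0 * diag + np.sum(self.d * self.d, axis=1)))


def kernel_weights(x: Sequence[float], spec: KernelSpec | float) -> KernelWeightMatrix:
    """Row-normalized Epanechnikov weights over the stratum scores.

    d_j(i) = K((x_j - x_i)/h) / sum_m K((x_m - x_i)/h); the self weight
    d_i(i) is always positive (K(0) = 3/4), so rows are well defined.  A
    bandwidth below the smallest stratum spacing makes the matrix the
    identity and c_d = 0, which raises :class:`DegenerateBandwidthError`.
    A warning (not an error) is emitted when h falls outside (1/H, 2/H),
    the range yielding the smallest nonempty window on the grid x_i = i/H.
    """
    if not isinstance(spec, KernelSpec):
        spec = KernelSpec(h=float(spec))
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least two stratum scores")
    if np.any(np.diff(x) < 0):
        raise ValueError("stratum scores must be sorted ascending")
    H = x.size
    if not (1.0 / H < spec.h < 2.0 / H):
        warnings.warn(
            f"bandwidth h={spec.h:g} outside (1/H, 2/H) = ({1.0 / H:g}, {2.0 / H:g})",
            stacklevel=2,
        )
    K = epanechnikov((x[None, :] - x[:, None]) / spec.h)
    d = K / K.sum(axis=1, keepdims=True)
    W = KernelWeightMatrix(d=d)
    if W.c_d <= 0.0:
        raise DegenerateBandwidthError(
            f"bandwidth h={spec.h:g} leaves every stratum alone in its window (c_d = 0)"
        )
    return W


def pair_weights(plan: CollapsingPlan) -> KernelWeightMatrix:
    """Binary pair-indicator weights d_j(i) := c_j(i) (size-2 groups only).

    With these weights c_d = 2 and the kernel estimator coincides exactly
    with the collapsed stratum estimator.
    """
    if any(s != 2 for s in plan.group_sizes):
        raise ValueError("pair weights require every group to have exactly 2 strata")
    return KernelWeightMatrix(d=plan.indicator())


def v_kernel(t_hat: Sequence[float], W: KernelWeightMatrix) -> VarianceEstimate:
    """Kernel-weighted variance estimator (1/c_d) sum_i (t_i - d(i).t)^2."""
    t_hat = np.asarray(t_hat, dtype=float)
    if t_hat.size != W.n_strata:
        raise ValueError("totals length must match the weight matrix")
    c_d = W.c_d
    if c_d <= 0.0:
        raise DegenerateBandwidthError("normalizing constant c_d is not positive")
    resid = t_hat - W.d @ t_hat
    value = float(np.sum(resid * resid)) / c_d
    return VarianceEstimate(value=value, estimator="kernel", diagnostics={"c_d": c_d})


def kernel_expectation_exact(
    t: Sequence[float], V: Sequence[float], W: KernelWeightMatrix
) -> tuple[float, float]:
    """Exact design expectation and bias of the kernel estimator.

    With independent strata, E (t_hat_i - sum_j d_j(i) t_hat_j)^2 splits into
    a variance part ``V_i (1 - 2 d_i(i)) + sum_j d_j(i)^2 V_j`` and a squared
    mean part ``(sum_j d_j(i)(t_i - t_j))^2``, so

        E[V_ker] = c_d^{-1} { sum_i [V_i(1 - 2 d_i(i)) + sum_j d_j(i)^2 V_j]
                              + sum_i (sum_j d_j(i)(t_i - t_j))^2 },

    and the bias (against var(t_hat) = sum_i V_i) is nonnegative whenever the
    V_i are constant across strata — the case the constant c_d is calibrated
    for, where the variance part reduces to ``sum_i V_i``.  The returned
    ``bias`` is the squared-mean term divided by c_d (the exact bias in that
    constant-variance case and the dominant bias term in general).

    Returns
    -------
    (expectation, bias)
    """
    from .design import DesignVariance

    t = np.asarray(t, dtype=float)
    if isinstance(V, DesignVariance):
        V = V.per_stratum
    V = np.asarray(V, dtype=float)
    d = W.d
    c_d = W.c_d
    if c_d <= 0.0:
        raise DegenerateBandwidthError("normalizing constant c_d is not positive")
    diag = np.diag(d)
    var_part = float(np.sum(V * (1.0 - 2.0 * diag)) + np.sum((d * d) @ V))
    mean_resid = t - d @ t
    bias = float(np.sum(mean_resid * mean_resid)) / c_d
    return var_part / c_d + bias, bias


# ---------------------------------------------------------------------------
# Bootstrap-bias-corrected estimator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap configuration.

    Parameters
    ----------
    B
        Number of resamples.
    n_star
        Within-pseudo-stratum resample size (the design's default is 2).
    mode
        ``"sum_to_one"`` normalizes the bias correctors to unit sum before
        they are used as weights (dimensionally consistent with the kernel
        weights); ``"raw"`` uses the correctors verbatim.
    replicate_scale
        ``"unbiased"`` rescales each replicate total by m_j/n* so resampling
        is exactly unbiased for the pseudo-stratum HT total; ``"raw_sum"``
        leaves the replicate as the plain sum of the n* draws.
    """

    B: int = 1000
    n_star: int = 2
    mode: str = "sum_to_one"
    replicate_scale: str = "unbiased"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.n_star < 1:
            raise ValueError("n_star must be >= 1")
        if self.mode not in ("sum_to_one", "raw"):
            raise ValueError("mode must be 'sum_to_one' or 'raw'")
        if self.replicate_scale not in ("unbiased", "raw_sum"):
            raise ValueError("replicate_scale must be 'unbiased' or 'raw_sum'")


@dataclass(frozen=True)
class CollapseResult:
    """Pseudo-sample after merging singleton strata, with the plan and log."""

    sample: StratifiedSample
    plan: CollapsingPlan
    log: tuple[str, ...]


def collapse_singletons(sample: StratifiedSample) -> CollapseResult:
    """Merge singleton strata into pseudo-strata with >= 2 sampled units.

    Every stratum with a single sampled unit is merged with the not-yet-merged
    stratum of smallest sample size (ties broken by nearest score x, then
    smallest id).  A leftover singleton with no free partner joins the nearest
    existing pseudo-stratum.  Strata already holding >= 2 units stand alone
    (the identity plan when no stratum is a singleton).
    """
    strata = sample.strata
    H = len(strata)
    total_n = int(sum(s.n for s in strata))
    if total_n < 2:
        raise CannotBootstrapError("need at least two sampled units overall")

    available = set(range(H))
    groups: list[list[int]] = []
    log: list[str] = []

    for i in range(H):
        if i not in available or strata[i].n != 1:
            continue
        candidates = [j for j in available if j != i]
        if candidates:
            j = min(
                candidates,
                key=lambda j: (strata[j].n, abs(strata[j].x - strata[i].x), str(strata[j].id)),
            )
            groups.append([i, j])
            available.discard(i)
            available.discard(j)
            log.append(f"merged stratum {strata[i].id!r} with {strata[j].id!r}")
        else:
            # no free partner: fold into the nearest existing group
            target = min(
                range(len(groups)),
                key=lambda g: min(abs(strata[j].x - strata[i].x) for j in groups[g]),
            )
            groups[target].append(i)
            available.discard(i)
            log.append(
                f"folded leftover stratum {strata[i].id!r} into pseudo-stratum {target}"
            )
    for i in sorted(available):
        groups.append([i])
    groups.sort(key=lambda g: min(g))

    plan = CollapsingPlan(groups=tuple(tuple(sorted(g)) for g in groups), n_strata=H)

    pseudo = []
    for g in plan.groups:
        members = [strata[i] for i in g]
        n_g = sum(m.n for m in members)
        pseudo.append(
            SampledStratum(
                id="+".join(str(m.id) for m in members),
                x=float(sum(m.x * m.n for m in members) / n_g),
                population_size=int(sum(m.population_size for m in members)),
                y=np.concatenate([m.y for m in members]),
                pi=np.concatenate([m.pi for m in members]),
                unit_x=None,
            )
        )
    return CollapseResult(
        sample=StratifiedSample(pseudo), plan=plan, log=tuple(log)
    )


def bootstrap_replicates(
    pseudo_sample: StratifiedSample,
    spec: BootstrapSpec,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw B bootstrap replicate totals per pseudo-stratum.

    For pseudo-stratum j with m_j HT contributions z_k = y_k/pi_k, each
    replicate draws n* contributions with replacement and (by default) scales
    the sum by m_j/n*, so the bootstrap expectation of every replicate total
    equals the pseudo-stratum HT total exactly.

    Returns
    -------
    ndarray of shape (B, J)
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    B, n_star = spec.B, spec.n_star
    J = pseudo_sample.n_strata
    out = np.empty((B, J), dtype=float)
    for j, stratum in enumerate(pseudo_sample.strata):
        z = stratum.y / stratum.pi
        m = z.size
        idx = rng.integers(0, m, size=(B, n_star))
        sums = z[idx].sum(axis=1)
        if spec.replicate_scale == "unbiased":
            sums *= m / n_star
        out[:, j] = sums
    return out


@dataclass(frozen=True)
class CorrectorResult:
    """Bootstrap bias correctors a_j and (optionally) normalized weights w_j."""

    bias: np.ndarray
    a: np.ndarray
    w: np.ndarray | None


def bias_corrector(
    replicates: np.ndarray, t_b: Sequence[float], mode: str = "sum_to_one"
) -> CorrectorResult:
    """First-order bootstrap bias corrector a_j = 2 t_hat_j - mean_b(t*_bj).

    The estimated bootstrap bias is mean_b(t*_bj) - t_hat_j; subtracting it
    from t_hat_j gives the corrector.  Under the unbiased resampling scheme
    the corrector's expectation is exactly t_hat_j, and it equals t_hat_j
    exactly when the replicate law is enumerated rather than sampled.

    With ``mode="sum_to_one"`` the correctors are additionally normalized to
    unit sum so they can stand in the weight slot of the kernel estimator.
    """
    replicates = np.asarray(replicates, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    if replicates.ndim != 2 or replicates.shape[1] != t_b.size:
        raise ValueError("replicates must have shape (B, J) matching t_b")
    bias = replicates.mean(axis=0) - t_b
    a = t_b - bias
    w = None
    if mode == "sum_to_one":
        total = a.sum()
        if total == 0.0:
            raise DegenerateCorrectorError("bias correctors sum to zero")
        w = a / total
    elif mode != "raw":
        raise ValueError("mode must be 'sum_to_one' or 'raw'")
    return CorrectorResult(bias=bias, a=a, w=w)


def v_bootstrap(
    t_b: Sequence[float],
    w: Sequence[float],
    c_b: float | None = None,
) -> VarianceEstimate:
    """Bootstrap variance estimator (1/c_b) sum_i (t_i - sum_j w_j t_j)^2.

    ``w`` is the corrector weight vector (normalized correctors in the default
    mode, raw correctors otherwise); the normalizing constant defaults to

        c_b = (1/J) sum_i (1 - 2 w_i + sum_j w_j^2),

    the direct analogue of the kernel constant c_d.  A negative c_b is
    reported with its sign preserved and flagged via a warning; c_b = 0
    raises :class:`DegenerateNormalizerError`.
    """
    t_b = np.asarray(t_b, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape != t_b.shape:
        raise ValueError("w must have one weight per pseudo-stratum")
    if c_b is None:
        c_b = float(np.mean(1.0 - 2.0 * w + np.sum(w * w)))
    if c_b == 0.0:
        raise DegenerateNormalizerError("normalizing constant c_b is zero")
    if c_b < 0.0:
        warnings.warn(
            f"normalizing constant c_b={c_b:g} is negative; estimate sign preserved",
            stacklevel=2,
        )
    resid = t_b - float(w @ t_b)
    value = float(np.sum(resid * resid)) / c_b
    return VarianceEstimate(
        value=value,
        estimator="bootstrap",
        diagnostics={"c_b": c_b, "w": w},
    )


# ---------------------------------------------------------------------------
# Sample-level conveniences
# ---------------------------------------------------------------------------


def collapsed_variance(
    sample: StratifiedSample, plan: CollapsingPlan | None = None
) -> VarianceEstimate:
    """Collapsed stratum estimate from a sample (adjacent pairs by default)."""
    t_hat, _ = ht_stratum_totals(sample)
    if plan is None:
        plan = make_pairing(sample.n_strata)
    return v_collapsed(t_hat, plan)


def kernel_variance(
    sample: StratifiedSample, spec: KernelSpec | float
) -> VarianceEstimate:
    """Kernel-weighted estimate from a sample, weights over the stratum scores."""
    t_hat, _ = ht_stratum_totals(sample)
    W = kernel_weights(sample.scores, spec)
    return v_kernel(t_hat, W)


def bootstrap_variance(
    sample: StratifiedSample,
    spec: BootstrapSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> VarianceEstimate:
    """Bootstrap-bias-corrected estimate from a sample.

    Chains singleton collapsing, replicate drawing, the bias corrector, and
    the normalized quadratic form; diagnostics carry the merge log, the
    corrector weights, and c_b.
    """
    if spec is None:
        spec = BootstrapSpec()
    collapsed = collapse_singletons(sample)
    t_b, _ = ht_stratum_totals(collapsed.sample)
    reps = bootstrap_replicates(collapsed.sample, spec, rng)
    corr = bias_corrector(reps, t_b, mode=spec.mode)
    weights = corr.w if spec.mode == "sum_to_one" else corr.a
    est = v_bootstrap(t_b, weights)
    diag = dict(est.diagnostics)
    diag.update(
        {
            "plan": collapsed.plan,
            "merge_log": collapsed.log,
            "mode": spec.mode,
            "B": spec.B,
            "n_star": spec.n_star,
        }
    )
    return VarianceEstimate(value=est.value, estimator="bootstrap", diagnostics=diag)
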