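"""Bootstrap pseudo-strata, replicate law, bias corrector, and V_boot."""

import numpy as np
import pytest

from finestrat import (
    BootstrapSpec,
    SampledStratum,
    StratifiedSample,
    bias_corrector,
    bootstrap_replicates,
    bootstrap_variance,
    collapse_singletons,
    exact_bootstrap_law,
    make_pairing,
    v_bootstrap,
)
from finestrat.exceptions import (
    CannotBootstrapError,
    DegenerateCorrectorError,
    DegenerateNormalizerError,
)


def sample_with_sizes(sizes, x=None, seed=0):
    rng = np.random.default_rng(seed)
    strata = []
    for i, n in enumerate(sizes, start=1):
        xi = x[i - 1] if x is not None else i / len(sizes)
        N = max(n, 3) * 2
        strata.append(
            SampledStratum(
                id=i,
                x=xi,
                population_size=N,
                y=rng.normal(size=n),
                pi=np.full(n, n / N),
            )
        )
    return StratifiedSample(strata)


class TestCollapseSingletons:
    def test_no_singletons_identity_plan(self):
        result = collapse_singletons(sample_with_sizes([2, 2, 2]))
        assert result.plan.is_identity()
        assert result.sample.n_strata == 3
        assert result.log == ()

    def test_two_singletons_forced_merge(self):
        result = collapse_singletons(sample_with_sizes([1, 1]))
        assert result.sample.n_strata == 1
        assert result.sample.strata[0].n == 2
        assert result.plan.groups == ((0, 1),)

    def test_all_singletons_even_matches_pairing(self):
        H = 6
        result = collapse_singletons(sample_with_sizes([1] * H))
        assert result.plan.groups == make_pairing(H).groups

    def test_all_singletons_odd_leftover_folds_into_last_group(self):
        result = collapse_singletons(sample_with_sizes([1] * 5))
        sizes = sorted(len(g) for g in result.plan.groups)
        assert sizes == [2, 3]
        assert all(s.n >= 2 for s in result.sample.strata)

    def test_singleton_prefers_smallest_stratum(self):
        # stratum 2 (n=1) should merge with stratum 3 (n=2), not stratum 1 (n=4)
        result = collapse_singletons(sample_with_sizes([4, 1, 2]))
        merged = [g for g in result.plan.groups if len(g) > 1]
        assert merged == [(1, 2)]

    def test_too_small_sample_rejected(self):
        with pytest.raises(CannotBootstrapError):
            collapse_singletons(sample_with_sizes([1]))

    def test_merged_units_preserve_ht_contributions(self):
        sample = sample_with_sizes([1, 1, 2])
        result = collapse_singletons(sample)
        z_before = np.sort(
            np.concatenate([s.y / s.pi for s in sample.strata])
        )
        z_after = np.sort(
            np.concatenate([s.y / s.pi for s in result.sample.strata])
        )
        np.testing.assert_allclose(z_after, z_before)


class TestReplicates:
    def test_constant_contributions_no_variation(self):
        strata = [
            SampledStratum(id=1, x=0.5, population_size=4, y=[3.0, 3.0], pi=[0.5, 0.5])
        ]
        reps = bootstrap_replicates(
            StratifiedSample(strata), BootstrapSpec(B=50), rng=0
        )
        np.testing.assert_allclose(reps, 12.0)  # t_hat = 3/0.5 + 3/0.5

    def test_two_point_law_enumeration(self):
        # z = (4, 6), n* = 2: ordered draws give totals {8, 10, 10, 12}, mean 10
        law = exact_bootstrap_law([4.0, 6.0], 2)
        assert sorted(law.values) == [8.0, 10.0, 10.0, 12.0]
        assert law.mean() == pytest.approx(10.0)

    def test_monte_carlo_mean_near_ht_total(self):
        strata = [
            SampledStratum(
                id=1, x=0.5, population_size=8, y=[1.0, 4.0, 7.0], pi=[3 / 8] * 3
            )
        ]
        pseudo = StratifiedSample(strata)
        t_b = pseudo.strata[0].ht_total
        reps = bootstrap_replicates(pseudo, BootstrapSpec(B=100_000), rng=1)
        se = reps[:, 0].std(ddof=1) / np.sqrt(reps.shape[0])
        assert abs(reps[:, 0].mean() - t_b) < 3 * se

    def test_raw_sum_scale_differs_by_m_over_nstar(self):
        strata = [
            SampledStratum(id=1, x=0.5, population_size=9, y=[1.0, 2.0, 3.0], pi=[1 / 3] * 3)
        ]
        pseudo = StratifiedSample(strata)
        a = bootstrap_replicates(pseudo, BootstrapSpec(B=20, replicate_scale="unbiased"), rng=5)
        b = bootstrap_replicates(pseudo, BootstrapSpec(B=20, replicate_scale="raw_sum"), rng=5)
        np.testing.assert_allclose(a, b * (3 / 2))


class TestBiasCorrector:
    def test_degenerate_strata_give_zero_bias(self):
        reps = np.full((100, 2), [10.0, 30.0])
        corr = bias_corrector(reps, [10.0, 30.0])
        np.testing.assert_allclose(corr.bias, 0.0)
        np.testing.assert_allclose(corr.a, [10.0, 30.0])

    def test_exact_law_corrector_is_unbiased(self):
        """Feeding the enumerated replicate law gives exactly zero bootstrap bias."""
        z = np.array([4.0, 6.0, 1.0])
        law = exact_bootstrap_law(z, 2)
        # expand the exact law to (B, 1) replicates with equal weight
        reps = np.array(law.values)[:, None]
        corr = bias_corrector(reps, [z.sum()])
        assert corr.bias[0] == pytest.approx(0.0, abs=1e-12)
        assert corr.a[0] == pytest.approx(z.sum())

    def test_hand_normalization(self):
        reps = np.full((10, 2), [10.0, 30.0])
        corr = bias_corrector(reps, [10.0, 30.0], mode="sum_to_one")
        np.testing.assert_allclose(corr.w, [0.25, 0.75])

    def test_zero_sum_correctors_rejected(self):
        reps = np.full((10, 2), [10.0, -10.0])
        with pytest.raises(DegenerateCorrectorError):
            bias_corrector(reps, [10.0, -10.0], mode="sum_to_one")


class TestVBootstrap:
    def test_hand_value(self):
        # weighted mean 25, squared deviations 225 + 25, c_b = 0.625 -> 400
        est = v_bootstrap([10.0, 30.0], [0.25, 0.75])
        assert est.value == pytest.approx(400.0)
        assert est.diagnostics["c_b"] == pytest.approx(0.625)

    def test_equal_totals_give_zero(self):
        est = v_bootstrap([5.0, 5.0, 5.0], np.full(3, 1 / 3))
        assert est.value == pytest.approx(0.0)

    def test_zero_normalizer_rejected(self):
        # J=1 with w=1: c_b = 1 - 2 + 1 = 0
        with pytest.raises(DegenerateNormalizerError):
            v_bootstrap([10.0], [1.0])

    def test_default_normalizer_never_negative(self, rng):
        # c_b = 1 - 2*sum(w)/J + sum(w^2) >= (J-1)/J for any weight vector
        for _ in range(200):
            w = rng.normal(scale=3, size=rng.integers(2, 8))
            J = w.size
            c_b = float(np.mean(1.0 - 2.0 * w + np.sum(w * w)))
            assert c_b >= (J - 1) / J - 1e-12

    def test_negative_override_warns_and_preserves_sign(self):
        with pytest.warns(UserWarning, match="negative"):
            est = v_bootstrap([10.0, 30.0], [0.25, 0.75], c_b=-0.625)
        assert est.value == pytest.approx(-400.0)

    def test_scale_equivariance_end_to_end(self):
        """y -> a*y scales V_boot by a^2 under sum-to-one weights."""
        sample = sample_with_sizes([1, 1, 2, 2], seed=3)
        spec = BootstrapSpec(B=300)
        base = bootstrap_variance(sample, spec, rng=np.random.default_rng(9)).value
        for a in (0.5, 3.0):
            scaled = bootstrap_variance(
                sample.scale_y(a), spec, rng=np.random.default_rng(9)
            ).value
            assert scaled == pytest.approx(a * a * base, rel=1e-9)

    def test_pipeline_deterministic_under_seed(self):
        sample = sample_with_sizes([1, 2, 1, 2], seed=4)
        spec = BootstrapSpec(B=100)
        a = bootstrap_variance(sample, spec, rng=np.random.default_rng(11)).value
        b = bootstrap_variance(sample, spec, rng=np.random.default_rng(11)).value
        assert a == b
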