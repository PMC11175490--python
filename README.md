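# finestrat

Design-based variance estimation for population totals under **fine
stratification** — survey designs with many small strata, each contributing
only one or two primary sampling units (PSUs), so the within-stratum variance
of the Horvitz–Thompson (HT) total cannot be estimated directly.

## Who this is for

Survey statisticians and methodologists who need variance estimates (and
honest appraisals of their bias) for stratified single-stage designs with
n_i ∈ {1, 2} PSUs per stratum — e.g. deeply stratified establishment or
health surveys — and researchers running design-based simulation studies
comparing such estimators.

## The estimators

The target is the total t = Σᵢ tᵢ of H strata, estimated by the HT total
t̂ = Σᵢ t̂ᵢ with t̂ᵢ = Σ_{k∈sᵢ} y_k/π_k. Under SRSWOR within stratum,
π_k = nᵢ/Nᵢ. Three estimators of var(t̂) are implemented:

**Collapsed stratum.** Strata are paired by their auxiliary score x (adjacent
pairs in x-order):

    V̂_col = ½ Σᵢ (t̂ᵢ − Σⱼ c_j(i) t̂ⱼ)²,

with c_j(i) = 1 iff i ≠ j share a pair. Its design bias is
½ Σᵢ (tᵢ − Σⱼ c_j(i) tⱼ)² ≥ 0, evaluated on the *true* totals — small only
when paired strata are well matched.

**Kernel-weighted.** The pair indicator is replaced by row-normalized
Epanechnikov weights d_j(i) ∝ K((x_j − x_i)/h), K(s) = ¾(1 − s²) on |s| ≤ 1:

    V̂_ker = (1/c_d) Σᵢ (t̂ᵢ − Σⱼ d_j(i) t̂ⱼ)²,
    c_d = (1/H) Σᵢ (1 − 2d_i(i) + Σⱼ d_j(i)²),

where c_d makes the variance part of E[V̂_ker] unbiased when the stratum
variances are constant.

**Bootstrap-bias-corrected.** Singleton strata are merged into pseudo-strata
of ≥ 2 units; within each pseudo-stratum, n* = 2 of the HT contributions are
resampled with replacement B times, giving the first-order bias corrector
â_j = 2t̂ⱼ − mean_b(t̂*_bj). The correctors, normalized to sum to one, take
the weight slot of the kernel form with c_b defined by analogy with c_d.

An **exact-enumeration oracle** (`finestrat.oracle`) visits every SRSWOR
sample (or bootstrap draw) on tiny instances with exact rational
probabilities, so all design-moment identities in the test suite are checked
against brute force, not against other formulas.

## Worked example

```python
import numpy as np
import finestrat as fs

# synthetic frame: N=1000 units, H=50 strata on x_i = i/H,
# y = 2x + N(0, 0.25^2) noise (linear mean rescaled to [0, 2])
pop = fs.make_population(N=1000, H=50, sigma=0.25, mean_fn="linear", rng=0)
print(f"true var(t_hat) = {fs.true_variance(pop, 2).total:.2f}")

sample = fs.draw_srswor(pop, 2, seed=1)          # two PSUs per stratum
col  = fs.collapsed_variance(sample)
ker  = fs.kernel_variance(sample, 0.03)          # bandwidth h in (1/H, 2/H)
boot = fs.bootstrap_variance(sample, fs.BootstrapSpec(B=500),
                             rng=np.random.default_rng(2))
print(f"collapsed  = {col.value:.2f}")
print(f"kernel     = {ker.value:.2f}  (c_d = {ker.diagnostics['c_d']:.4f})")
print(f"bootstrap  = {boot.value:.2f}  (c_b = {boot.diagnostics['c_b']:.4f})")
```

prints

```
true var(t_hat) = 540.50
collapsed  = 631.83
kernel     = 582.78  (c_d = 0.4091)
bootstrap  = 8940.51  (c_b = 0.9861)
```

The collapsed and kernel estimates sit near the true design variance (both
carry the expected positive bias); the bootstrap-corrected estimator's
quadratic form is dominated by the between-stratum spread of the totals on
this trending population — see `docs/methods.md` for why, and for when each
estimator is trustworthy.

The same computations are available from the shell:

```sh
finestrat estimate --input sample.csv --estimator all --bandwidth 0.03 --seed 1
finestrat simulate --N 3000 --H 100 --sigma 0.25 --mean-fn linear \
    --bandwidth 0.015 --R 1000 --B 1000 --seed 1 --out tidy.csv
finestrat conditional --N 3000 --H 100 --R 1000 --seed 1 --out cond.csv
finestrat selftest          # exact identity suite, prints a pass/fail table
finestrat smho --input smho98.csv   # optional vignette on user-supplied data
```

Sample CSVs carry one row per sampled unit with columns
`stratum,N_i,x_i,y[,pi]`. The SMHO vignette expects a user-supplied export
of the 1998 Survey of Mental Health Organizations data (`smho98` in the
PracTools R package); it is not bundled.

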