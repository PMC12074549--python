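# pnim — partially nonlinear index models

`pnim` estimates regressions of the form

    Y = α + g(X'β₁, …, X'β_q) + f(T) + ε,

where a high-dimensional covariate block `X ∈ R^p` affects the response only
through a small number `q` of linear indices with an unspecified link `g`,
while a single covariate of interest `T` (age, time, dose, …) enters through
an unrestricted smooth effect `f`. The model sits between the partially
linear model (`g` linear, `q = 1`) and the fully nonparametric regression,
and is aimed at settings such as medical-cost analysis where many binary
comorbidity/insurance indicators should be compressed into a few indices
while the age effect stays free-form.

Estimation is two-stage:

1. **Partial sufficient dimension reduction.** The partial central subspace
   S_{Y|X}(T) — the smallest span of directions β such that Y ⟂ X | (X'β, T)
   — is estimated for continuous `T` by partial discretization expectation
   estimation: dichotomize `T` at thresholds `s` drawn from its own observed
   values, run sliced inverse regression within each stratum {T ≤ s},
   {T > s}, pool the per-stratum projections weighted by stratum proportion
   into M_n(s), and average over `l` thresholds. The structural dimension
   `q` is selected from the averaged spectrum by a BIC-type criterion

       d̂ = argmax_k  n·Σ_{j≤k}(log(λ̂_j+1) − λ̂_j) / (2·Σ_{j≤p}(log(λ̂_j+1) − λ̂_j))
                      − 2·C_n·k(k+1)/(2p),      C_n = n^{1/3} p^{2/3}.

2. **Density-ratio weighted kernel estimation.** On the reduced data
   Z = X B̂ the model is a standard additive regression. Each component is
   isolated by marginal integration with the weight Φ(z,t) =
   f_Z(z)f_T(t)/f(z,t), whose conditional moments E[Φ|Z] = 1 and
   E[Φ·f̃(T)|Z] = 0 delete the other component:

       ĝ*(z) = n⁻¹ Σ_i K_h1(Z_i, z) · f̂_T(T_i)/f̂(Z_i, T_i) · Y_i,

   and symmetrically for f̂*(t). Bandwidths come from leave-one-out
   cross-validation; an optional oracle-efficient second stage refits each
   component by local-linear regression on pseudo-responses with the other
   pilot component subtracted.

Subspace recovery is scored by the squared trace correlation
r² = tr(A)/dim(A), A = Σ_V^{-1/2} Σ_VU Σ_U^{-1} Σ_UV Σ_V^{-1/2} for
U = X'B_true, V = X'B̂ — the mean squared canonical correlation, 1 iff the
spans agree.

## Worked example

```python
import pnim

sample, truth = pnim.generate_model_I(1000, "B", seed=7)
model = pnim.PartiallyNonlinearIndexModel(sample.Y, sample.X, sample.T)
res = model.fit(slices=5, n_thresholds=10, seed=1, bandwidths="cv")
print(res.summary())
print("r2 vs truth:", pnim.trace_correlation(sample.X, truth.B_true, res.basis))
```

prints (abridged)

```
Partially Nonlinear Index Model
==============================================
No. observations:     1000    covariates p: 10
slices K:   5   thresholds l: 10   C_n: 46.42
structural dimension d_hat: 1
leading eigenvalues: [9.7660e-01 1.6338e-02 3.0481e-03 ...]
intercept alpha_hat: -0.0376
bandwidths: h1=0.250 h2=0.147 h3=0.102 h4=0.073
trimmed fraction: 1.000%

Index directions (unit-norm columns):
     direction_1
x1        0.7093
x2       -0.0153
x3        0.6943
...
r2 vs truth: 0.9858177696182633
```

The single dominant eigenvalue and `d_hat = 1` say that one index carries
all covariate information; the fitted direction loads on x1 and x3
(0.709, 0.694), matching the true β₁ = (1/√2)(e₁ + e₃) with r² ≈ 0.986;
`res.g(...)`/`res.f(...)` evaluate the centered components (here an
exp-shaped `g` and the 1.5·sin(2πt) age-style effect).

Benchmark tables are regenerated with the study runner:

```python
cell = pnim.run_study("I-A", n=1000, K=5, l=10, reps=200, seed=0)
print(cell.r2_mean, cell.r2_sd, cell.dim_correct_prop)
```

A CLI mirrors the stages: `pnim simulate | reduce | fit | refine | study`
(see `pnim --help`).

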