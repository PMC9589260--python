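# pdjdsnmf

Prior-knowledge-driven joint deep semi-nonnegative matrix factorization
(PD-JDSNMF) for integrating mRNA, lncRNA and miRNA expression over the
same samples and mining cross-omics co-expression modules — the kind of
analysis used to nominate RNA biomarkers in bulk disease cohorts such as
heart-failure transcriptomes.

## The model

Given three expression matrices `X_i ∈ R^{n×p_i}` (samples × features,
shared samples), the model factorizes every matrix against one common
sample latent matrix `U ∈ R^{n×k0}` (unconstrained sign) and a per-omics
hierarchy of coefficient matrices produced by sigmoid-activated layers:

    X_i ≈ U H_i^0,      H_i^0 = s(Z_i^1 s(Z_i^2 … s(Z_i^N H_i^N))),
    s(x) = 1 / (1 + e^{-x})

so every derived layer `H_i^0 … H_i^{N-1}` lies in (0,1) — nonnegative by
construction — while the junction matrices `Z_i^n ∈ R^{k_{n-1}×k_n}` and
the deepest layer `H_i^N` are free. The fitted objective is

    Σ_i ‖X_i − U H_i^0‖_F²
      + λ1 Σ_S ‖S‖_F²                      S ∈ {U, all Z, all H^N}
      + λ2 Tr(H^0 M H^0ᵀ)                  PPI prior on the mRNA omics
      + λ3 Σ_i Tr(H_i^0 B_i H_i^0ᵀ)       graph-Laplacian smoothness

where `B_i = D_i − L_i` is the Laplacian of a feature connectivity graph
(by default thresholded absolute Pearson correlation, |r| ≥ 0.8) and `M`
is the Laplacian of the binary protein–protein interaction adjacency
(`ppi_mode="literal"` uses the raw adjacency instead). Both trace
penalties equal `½ Σ_{p,q} A[p,q] ‖h_p − h_q‖²`, pulling connected
features toward similar factor loadings.

A co-expression module is one latent factor: for each factor row of
`H_i^0`, features whose z-score across the row is ≥ 1.96 are members, so
a fit with `k0` factors yields exactly `k0` modules spanning all three
omics. Each module is scored by the Pearson correlation between the data
and the reconstruction restricted to its member features.

Model selection follows the reconstruction Pearson correlation between
each `X_i` and `U H_i^0`: a 3×3×3 grid over (λ1, λ2, λ3) ∈ {0.001, 0.01,
0.1}³ (27 combinations) and a sweep over layer-dimension profiles
reported as `mean ± std` of the three per-omics correlations.

## Worked example

Synthetic data drawn from the model class itself, with 10 planted
cross-omics modules, a module-consistent PPI, and noise at a
signal-to-noise variance ratio of 10:

```python
from pdjdsnmf import (PDJDSNMF, LayerDims, SyntheticSpec, generate,
                      module_summary, score_recovery)

spec = SyntheticSpec(n=100, p=(300, 120, 30), dims=LayerDims([10, 8, 6, 4]),
                     snr=10.0, seed=0)
X, ppi, truth = generate(spec)

model = PDJDSNMF(X, ppi, dims=[10, 8, 6, 4])      # λ = (0.001, 0.1, 0.01)
res = model.fit(max_iter=500, seed=0, method="lbfgs", init_method="nmf")
print(res.summary())

ms = res.extract_modules(zscore_threshold=1.96)
print(module_summary(ms).head(4).to_string(index=False))
print("recovery F1:", round(score_recovery(ms, truth["modules"])["mean_best_f1"], 3))
```

prints

```
PD-JDSNMF fit summary
==========================================
layers (k): [10, 8, 6, 4]   sublayers: 3
lambda1=0.001  lambda2=0.1  lambda3=0.01  ppi_mode=laplacian
iterations: 500   converged: False   seed: 0
final objective: 427.334
------------------------------------------
reconstruction Pearson correlation
  mrna           0.9054
  lncrna         0.8710
  mirna          0.9158
  mean           0.8974

module  n_mrna  n_lncrna  n_mirna  correlation
     9    14.0       8.0      2.0     0.970102
     3    20.0       5.0      2.0     0.965289
     6    20.0       8.0      2.0     0.963647
     0    20.0       8.0      2.0     0.962345

recovery F1: 0.958
```

The per-omics correlations (~0.87–0.92) sit just under the noise ceiling
for snr = 10, the 10 extracted modules carry member counts close to the
planted (20, 8, 2) per omics, and the best-match F1 of 0.958 says the
z-score membership recovers the planted module structure almost exactly.

The same pipeline is scriptable from the shell:

```
pdjdsnmf simulate --out sim --seed 0
pdjdsnmf fit      --mrna sim/mrna.tsv --lncrna sim/lncrna.tsv \
                  --mirna sim/mirna.tsv --ppi sim/ppi.tsv \
                  --dims 10,8,6,4 --out fit --seed 0
pdjdsnmf modules  --mrna sim/mrna.tsv --lncrna sim/lncrna.tsv \
                  --mirna sim/mirna.tsv --ppi sim/ppi.tsv \
                  --dims 10,8,6,4 --out mods --seed 0
```

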