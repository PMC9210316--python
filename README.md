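# mtkernel

Bayesian multitrait multienvironment **kernel regression** for genomic
prediction.

Plant breeders select candidate lines from genome-wide markers before (or
instead of) phenotyping them everywhere. When several traits are genetically
correlated — days to heading and days to maturity in wheat correlate above
0.97 — a multitrait model borrows information across traits and environments
and predicts markedly better than trait-by-trait fits. `mtkernel` implements
that model with a choice of genomic kernels, so nonlinear genotype–phenotype
maps can be captured with the same machinery as ordinary GBLUP.

For the n × nT phenotype matrix Y (line × environment cells by traits):

    Y = X_E B_E + U_L + U_LE + E

    vec(U_L)  ~ N(0, Σ_T  ⊗ KL)      KL  = Z_L K_l Z_L'
    vec(U_LE) ~ N(0, Σ_TE ⊗ KLE)     KLE = KL ∘ KE   (Hadamard G×E)
    rows of E ~ iid N(0, R)

with K_l one of the **linear (GBLUP)**, **Gaussian (RBF)**, **polynomial**,
or **sigmoid** kernels built from scaled markers, and Σ_T, Σ_TE, R
unstructured trait covariances with inverse-Wishart priors. A Gibbs sampler
works in the eigenbasis of each kernel (so indefinite kernels are handled by
spectral truncation), imputes missing trait entries each sweep, and returns
posterior summaries. The evaluation layer implements cell-level fivefold
cross-validation (CV2) with two masking scenarios — **MT** (all traits of a
test cell masked) and **MT_P** (auxiliary traits stay observed) — scoring
per-environment mean squared error of prediction. A simulator generates
synthetic trials with known ground truth. See `docs/methods.md` for the full
model description.

## Worked example

```python
import numpy as np
from mtkernel import (SimulationConfig, simulate_multitrait, ModelSpec,
                      fit_multitrait, genetic_correlations,
                      ScenarioMask, run_cv_experiment)

# a synthetic trial: 80 lines x 3 environments, 2 traits, genetic corr 0.9
sim = simulate_multitrait(SimulationConfig(n_lines=80, n_markers=200,
                                           n_envs=3, seed=7))

# Gaussian-kernel fit with G x E
spec = ModelSpec(kernel_name="gaussian", include_gxe=True,
                 n_iter=2000, burn_in=500, thin=5, seed=1)
fit = fit_multitrait(sim.phenotypes, sim.markers, spec)
print("posterior-mean genetic correlation:",
      round(float(genetic_correlations(fit)[0, 1]), 3))
```

prints

```
posterior-mean genetic correlation: 0.89
```

— the generating correlation was 0.9. A paired cross-validation comparison
(identical folds and masks for every method) under the MT_P scenario:

```python
grid = {
    "gblup": ModelSpec(kernel_name="linear",   n_iter=1000, burn_in=300, thin=2, seed=1),
    "gk":    ModelSpec(kernel_name="gaussian", n_iter=1000, burn_in=300, thin=2, seed=1),
}
reports, comparison = run_cv_experiment(
    sim.phenotypes, sim.markers, grid,
    ScenarioMask("MT_P", target_traits=["trait1"], observed_traits=["trait2"]),
    k=5, seed=3)
print(comparison.to_string(index=False))
```

```
method  trait      mse reference  pct_improvement_vs_reference
 gblup trait1 0.244396     gblup                      0.000000
    gk trait1 0.247367     gblup                     -1.201246
```

The across-environment MSE of 0.24 for the masked target trait is far below
the trait's variance (~2) because the observed auxiliary trait sharpens every
prediction through the residual correlation; on this linear-truth dataset the
Gaussian kernel buys nothing over GBLUP (−1.2%), which is exactly what a
well-calibrated comparison should say.

## Command line

```sh
mtkernel simulate --config sim.yaml --seed 1 --out data/
mtkernel fit --markers data/markers.csv --phenos data/phenotypes.csv \
         --kernel gaussian --gxe --seed 1 --out fit/
mtkernel predict --fit fit/ --out predictions.csv
mtkernel cv --markers data/markers.csv --phenos data/phenotypes.csv \
         --methods brr,gblup,gk,pk,sk --scenario MT_P --gxe both \
         --folds 5 --seed 1 --out cv/
```

`cv` writes a tidy per-fold report, per-environment and across-environment
aggregates, and a percent-improvement comparison table. All outputs are
byte-reproducible from the seed.

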