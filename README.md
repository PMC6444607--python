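# adlasso

Adaptive LASSO for genome-wide prediction. Fits a (weighted) L1-penalized
regression of phenotypes on one-hot-encoded SNP genotypes with:

- an **ADMM solver** using proximal updates, where the quadratic
  sub-problem is solved through a one-time eigendecomposition of the
  n x n Gram matrix (never the q x q system, so p >> n is cheap);
- an **Armijo backtracking line search** that re-tunes the learning rate
  at every ADMM iteration (start 1.0, halve until sufficient decrease);
- **adaptive penalty weights** `w_j = 1 / |x_j' y / n|^gamma` from
  univariate marginal regressions (`gamma = 0` recovers the plain LASSO);
- a **golden-section search** over the penalty level that minimizes the
  squared test error between `lam_a` and `lam_max = ||X'y||_inf`,
  warm-starting every solver call and re-evaluating exactly one interior
  point per iteration;
- **additive/dominance effect extraction** from the per-genotype-class
  indicator coefficients (`a = -theta(gen0) + theta(gen2)`,
  `d = theta(gen1)`);
- a **synthetic data generator** with a known QTL architecture (two major
  additive loci, a truncated-normal polygenic background, and dominance /
  over-dominance / under-dominance loci) for end-to-end testing.

## CLI

```sh
# generate a synthetic dataset with known truth
adlasso simulate --n-individuals 2000 --n-snps 1000 --seed 1 --out sim/

# full pipeline: MAF filter, one-hot encode, tune lambda, fit, evaluate
adlasso fit --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
    --lam-a-frac 0.0001 --eps-gss 0.01 --out fit/

# artifacts: coefficients.tsv, effects.tsv (per-SNP a and d),
# evaluation.json (MSE_test, r_test, lam_opt), gss_trace.tsv, manifest.json

adlasso encode --genotypes sim/genotypes.tsv --out design.tsv
adlasso predict --genotypes sim/genotypes.tsv \
    --coefficients fit/coefficients.tsv --out preds.tsv
adlasso evaluate --predictions preds.tsv --phenotypes sim/phenotypes.tsv
```

Input formats are plain delimited text: genotypes as individuals x SNPs
with a header of SNP ids and a leading id column, entries coded 0/1/2;
phenotypes as two columns (id, value); covariates with a kind row
(`indicator` or `continuous`) under the header.

## Library

```python
from adlasso import (SimulationConfig, simulate_dataset, one_hot_encode,
                     center_phenotype, auto_fit, FitConfig, extract_effects)

ds = simulate_dataset(SimulationConfig(n_individuals=2000, n_snps=1000, seed=1))
X = one_hot_encode(ds.genotypes)
train, test = ds.split.repeats[0]
pv = center_phenotype(ds.phenotypes[train])
res = auto_fit((X.values[train], pv.values),
               (X.values[test], ds.phenotypes[test] - pv.training_mean),
               config=FitConfig(), lam_a_frac=1e-4, eps_gss=1e-2)
effects = extract_effects(res.theta_opt, X.columns)
```

## Tests and acceptance report

```sh
python -m pytest -q tests/            # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(dimensional identities, solver-vs-oracle equivalence and KKT residuals,
closed forms, golden-section bookkeeping, warm-start invariance,
parameter recovery on simulated data, determinism).
`scripts/acceptance.py` regenerates the reported quantities from scratch
and writes them as JSON.
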