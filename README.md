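# simguided

**Simulation-guided, leakage-proof machine-learning benchmarking for
multimodal clinical cohorts.**

Observational multimodal studies — for example a few hundred psychiatric
patients with cognitive testing, structural MRI, electrophysiology,
symptom ratings and register data — rarely come with an independent
replication sample. Testing many algorithms directly on such data and
reporting the best one inflates accuracy; testing only one is a gamble.
`simguided` implements the alternative: simulate cohorts that match the
real data's shape, dimensionality and missingness at known signal-to-noise
ratios, select algorithms and settings on the simulations, and carry only
the selected few to the real data, inside a nested cross-validation that
provably never leaks test information into any fitted parameter.

The package provides:

- a **latent cohort simulator**: each subject carries a 1-D trait z
  (cluster variant: z ∈ {−1,+1}; spectrum variant: z ~ N(0,1)) driving
  every feature as x_ij = w_j·z_i + ε_ij, with noise rescaled so that
  10·log₁₀(Var_signal/Var_noise) hits the requested dB exactly, and a
  default sweep of −20…+20 dB × 2 variants × 10 seeds = 180 datasets;
- **missingness grafting**: block-wise and random missingness patterns
  extracted from a reference cohort are applied to simulated data;
- **train-only preprocessing**: per-submodality median or probabilistic
  PCA imputation (EM with monotone observed-data likelihood; missing
  cells imputed by posterior means) and train-derived standardization;
- a frozen **algorithm registry** (21 classification configurations from
  8 families, 32 regression configurations from 9) with inner-loop
  Bayesian hyperparameter optimization (expected improvement over a GP
  surrogate), plus a budgeted **auto-ensemble** built by greedy forward
  selection with replacement;
- an **outer CV engine** (stratified 75/25 splits, replicated) with
  **late integration** of per-submodality predictions, balanced accuracy
  / NMSE scoring, 95% percentile CIs, paired sign-flip permutation
  comparisons, and best/median/poorest **ranking-transfer validation**.

## Worked example

Simulate a 120-subject cluster cohort at −5 dB, benchmark a classifier
with the full nested CV, and compare it against a weaker one:

```python
import simguided as sg

spec = sg.LatentCohortSpec(layout=sg.small_layout(120, 4, 3),
                           variant="cluster", snr_db=-5.0, seed=3)
ds = sg.generate_cohort(spec)

cv = sg.OuterCVSpec(n_replications=10, seed=0)
res = sg.outer_cv(ds, sg.get_config("logreg_default"), "classification", cv)
s = res.summary()
print(f"logreg  BACC {100*s.mean:.1f} [{100*s.ci_low:.1f}, {100*s.ci_high:.1f}]"
      f"  significant={s.significant}")

weak = sg.outer_cv(ds, sg.get_config("knn_default"), "classification", cv)
p = sg.compare_algorithms(res.scores, weak.scores, seed=0)
w = weak.summary()
print(f"knn     BACC {100*w.mean:.1f} [{100*w.ci_low:.1f}, {100*w.ci_high:.1f}]")
print(f"paired sign-flip p = {p:.4f}")
```

Output:

```
logreg  BACC 94.1 [89.4, 97.1]  significant=True
knn     BACC 78.1 [63.3, 88.9]
paired sign-flip p = 0.0020
```

Even below 0 dB the latent subgroups remain learnable: logistic
regression averages 94.1% balanced accuracy over the ten outer
replications (the percentile CI excludes the 50% chance level, hence
significant), k-NN trails by sixteen points, and the paired sign-flip
permutation test across the shared CV replications confirms the gap is
systematic rather than split luck. Lower the SNR to −20 dB and both
collapse onto chance; that collapse, its monotone rise with SNR, and the
transfer of algorithm rankings to fresh cohorts are exactly what the
shipped experiment suite measures.

The same protocol runs end-to-end from the shell:

```bash
simguided run --out demo_run          # simulate -> benchmark -> select -> validate
simguided report --run-dir demo_run
simguided fixture --seed 0 --out fixture/   # 289-subject reference cohort
```

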