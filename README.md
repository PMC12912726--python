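# vertdescent

Tools for a comparative question in arboreal locomotion: **how do
mammals get back down?** Ascending a vertical trunk is well studied;
descending it is not, yet descent is where body plan, head mass, and
grasping ability collide with gravity. `vertdescent` implements the
full analysis chain for footfall-level locomotor data from mammals
climbing vertical supports — from raw touchdown/lift-off events to
evolutionary model comparison — for researchers in functional
morphology and phylogenetic comparative methods.

The pipeline covers:

- **Kinematics** — per-stride duty factors, girdle lags, limb phases,
  stance periods, absolute and relative speeds, and Hildebrand-style
  gait classification (LSLC / LSDC / DSDC / DSLC; bound / half-bound /
  gallop). A stride is symmetrical when both girdle lags lie in
  [40, 60]% of stride duration; symmetrical gaits split by mean limb
  phase quartile, asymmetrical ones by fore/hind stance periods at the
  10% cut.
- **Ethogram statistics** — species × support descent-strategy
  proportions (head-first / side / tail-first, individual-averaged),
  bootstrap ANOVA/MANOVA for support-diameter effects, Mann-Whitney
  ascent/descent contrasts with percent change, Wilcoxon contrasts of
  symmetrical-gait fractions, MANOVA on PCA-reduced gait frequencies,
  Benjamini-Hochberg correction throughout.
- **Morphometrics** — eight limb/body proportions, encephalization
  quotient EQ = brain / (0.12 · body^(2/3)), and major-axis brain-body
  allometry.
- **Phylogenetics** — Newick I/O, majority-rule consensus, forced
  ultrametricity, grafting of dated fossil tips, phylogenetic
  covariance matrices; Blomberg's K and the multivariate K_mult with
  permutation tests and effect sizes.
- **Fossil inference** — multivariate-normal multiple imputation
  (EM start, 5000 × 50-step data-augmentation chains) predicting
  descent proportions of extinct taxa from partial morphology.
- **Trait evolution** — maximum-likelihood BM, early-burst, OU,
  multi-rate BM and multi-optimum OU fits on fossil-bearing trees,
  AIC comparison, and phylogenetic half-life ln(2)/α.

A synthetic-data module generates every input with known ground truth
(gait archetypes with jitter, bout tables, birth-death trees with
fossils, morphology matrices with fossil-style missingness), so the
whole pipeline is testable end to end.

## Worked example

Run the full study on synthetic data:

```sh
vertdescent all --seed 1 --out demo
```

or from Python:

```python
>>> from vertdescent import synth, physignal
>>> from vertdescent.kinematics import gait_table

>>> table, truth = synth.gen_footfall_bouts(n_per_archetype=5, seed=0)
>>> gaits = gait_table(table)
>>> float((gaits.set_index("bout")["gait"] == truth).mean())   # round trip
1.0

>>> tree, _ = synth.synthetic_study_tree(n_extant=21, n_fossil=0, seed=11)
>>> trait = synth.sim_traits_on_tree(tree, "BM", {"sigma2": 1.0, "z0": 0.0},
...                                  seed=5).iloc[0]
>>> physignal.blomberg_k(tree, trait, n_perm=999, seed=1)
SignalResult(statistic=1.5339537101548064, p=0.001,
             effect_size=10.680166201463399, n_perm=999, seed=1,
             n_components=None)
```

A Brownian trait on the tree carries strong phylogenetic signal
(K ≈ 1.5, none of 999 tip shuffles reached it), exactly what the
statistic is calibrated to detect.

`vertdescent all --seed 1 --out demo` writes, among other outputs,
`demo/model_comparison.csv` — the model comparison for the synthetic
head-first-proportion trait:

```
            model         lnL  k         aic  half_life  converged  delta_aic
0  OUM (primates) -163.017633  4  334.035267   0.000693       True   0.000000
1              OU -170.133317  3  346.266635   0.117276       True  12.231368
2              BM -176.754869  2  357.509738        NaN       True  23.474471
3  BMM (primates) -176.373871  3  358.747742        NaN       True  24.712475
4              EB -176.754869  3  359.509738        NaN       True  25.474471
```

Read: the two-optimum OU model (separate descent-behavior optima for
the primate clade and the background, shared pull strength α and rate
σ²) beats every single-regime model by more than 12 AIC units, and the
fitted α is so large on the unit-height tree that the half-life — the
time for the trait to move halfway to its optimum — is a tiny fraction
of total tree depth: descent strategy tracks the clade's optimum
tightly rather than wandering. The synthetic generator plants exactly
this structure (group-level strategy probabilities), so this is the
expected recovery. On small `lnL` differences, note EB's rate bound
r ≤ 0 makes BM its boundary case (identical lnL, one more parameter).

Per-stride classification, strategy tables, fossil predictions and
signal statistics are written alongside (`gait_table.csv`,
`strategy_proportions.csv`, `fossil_predictions.csv`,
`model_comparison.csv`, `report.json` with every seed used).

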