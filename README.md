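# cpmflow

Connectome-based predictive modeling (CPM) of dimensional behavior scores
from task functional connectivity, with permutation inference, dependent-
correlation model comparison, anatomical localization, and a synthetic-data
harness.

## The problem

Irritability in youth has been linked to aberrant responses to frustrative
nonreward — the state evoked when an expected reward is withheld. One way to
probe its neural basis is to scan children during a frustrating task,
compute whole-brain functional connectivity separately for frustration and
nonfrustration blocks, and ask whether connectivity in the frustrated state
predicts trait irritability (the Affective Reactivity Index, a six-item
scale scored 0–12) in subjects the model has never seen.

`cpmflow` implements that analysis chain as a tested, reusable library for
anyone applying CPM to brain–behavior prediction:

1. **Connectomes.** Node time courses (e.g., the 268-node Shen parcellation)
   are correlated pairwise and Fisher z-transformed into symmetric K×K
   matrices; the K(K−1)/2 unique edges are the feature space.
2. **CPM.** Within each fold of tenfold cross-validation, every edge is
   correlated with the behavior across training subjects (Pearson, Spearman,
   or partial correlation given covariates such as motion, age, and sex).
   Edges with r > 0, p < α form the *positive network*, r < 0 the *negative
   network*. Each network is summed into a scalar strength per subject, and
   behavior is regressed on the strength scores:

       ŷ = b₀ + b₁·Σ_{e∈pos} z_e + b₂·Σ_{e∈neg} z_e

   Held-out subjects are predicted by the fold's model; the procedure is
   repeated over 100 cross-validation iterations and the median-performing
   model (by Spearman ρ of predicted vs actual) is reported, along with
   RMSE = √(1/n Σ(actualᵢ − predictedᵢ)²).
3. **Inference.** Because out-of-fold predictions are not independent,
   significance comes from permutation: the behavior–connectome
   correspondence is shuffled, the analysis re-run, and
   p = (#{ρ_null > ρ_observed} + 1)/(n_perm + 1), one-tailed. Competing
   models of the same behavior (frustration vs nonfrustration connectivity,
   child vs parent report) are compared with Steiger's z-test for dependent
   correlations.
4. **Localization.** The consensus network (edges selected in every fold of
   the median run) is summarized by node degree, hemisphere partition
   (ipsilateral left/right vs interhemispheric), long- vs short-range split
   with a χ² test, and 10×10 edge-count matrices over the canonical
   functional networks.
5. **Synthetic data.** Because such studies rarely deposit raw fMRI, the
   package ships a generator that emulates the study structure — ~69
   subjects, right-skewed bounded ARI scores (mean 1.79, SD 2.04),
   per-condition Fisher-z matrices, motion-like confounds, and a sparse
   planted edge set present only in the frustration condition — so every
   stage is verifiable against known ground truth.

## Worked example

```python
import cpmflow as cf

cfg = {
    "seed": 42, "out_dir": "readme_demo",
    "stages": ["simulate", "cpm", "permute", "localize"],
    "simulate": {"n_subjects": 69, "n_nodes": 60, "n_signal_pos": 40,
                 "effect_r": 0.4},
    "cpm": {"target": "child_ari", "condition": "frustration",
            "covariates": ["motion"], "n_iterations": 100},
    "permute": {"n_perm": 200, "perm_seed": 7},
}
cf.run_pipeline(cfg)
print(cf.report("readme_demo"))
```

prints

```
CPM prediction of child_ari from frustration connectivity
  n = 69 subjects analyzed
  median model of 100 iterations of 10-fold cross-validation:
  ρ = 0.81, RMSE = 1.36, p = 0.00498 (permutation testing, 200 iterations, one-tailed)
  consensus networks: 24 positive, 1 negative edges
  positive network: 24 edges — 4 ipsilateral right, 6 ipsilateral left, 14 interhemispheric; 96% long range at 60 mm (χ² = 2.36, p = 0.12)
  negative network: 1 edges — 0 ipsilateral right, 0 ipsilateral left, 1 interhemispheric; 100% long range at 60 mm (χ² = 0.18, p = 0.67)
```

Here a synthetic cohort of 69 subjects carries 40 planted edges whose
connectivity correlates 0.4 with the behavior score, only during
frustration. The cross-validated model recovers a strong out-of-sample rank
correlation (ρ = 0.81); the permutation p sits at its attainable floor
1/201 ≈ 0.005 because no shuffled dataset beat the observed model; and 24 of
the 40 planted edges survive the strictest consensus rule (selected in all
10 folds of the median run). Running the same config with
`"condition": "nonfrustration"` yields ρ near 0 — the planted
state-specificity the analysis is designed to detect.

The same workflow is available from the shell:

```bash
cpm simulate --seed 42 --out data/
cpm run --config pipeline.yaml
cpm report runs/demo
cpm compare runs/frustration runs/nonfrustration   # Steiger z test
```

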