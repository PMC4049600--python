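# nback-ica

Group spatial ICA analysis of n-back working-memory fMRI: functional
network decomposition, HRF-basis temporal regression with an
area-under-the-curve (AUC) activation statistic, behavioral
speed/accuracy cost indices, and the age × load × performance
statistical chain — exercised end to end on synthetic data with known
ground truth.

## The scientific problem

Healthy aging changes how functional brain networks respond to working
memory load, and in older adults the size of that response can predict
who performs well. A classic way to study this is a letter n-back task
(0-back / 1-back / 2-back) scanned with fMRI, analyzed not voxel by
voxel but at the level of spatially independent networks:

1. **Group spatial ICA.** All subjects' BOLD data are reduced by
   per-subject temporal PCA, concatenated, reduced again, and unmixed
   with the infomax algorithm into spatially independent component maps
   with associated time courses. Stability is assessed ICASSO-style, by
   re-running ICA with different seeds and clustering the pooled
   components; subject-specific maps and time courses are recovered by
   back-projection through the retained reduction operators.
2. **Temporal regression and AUC activation.** Each subject-level
   component time course is regressed on a GLM design built from the
   three task conditions convolved with a three-function HRF basis
   (canonical double-gamma h, its temporal derivative h', and its
   dispersion derivative h_d), plus motion nuisance regressors. The
   three betas per condition are collapsed to one activation value,

       AUC = (β₁·Σh + β₂·Σh' + β₃·Σh_d) / Σh ,

   and the *BOLD load effect* is AUC(2-back) − AUC(0-back).
3. **Behavior.** Responses faster than 200 ms or slower than 1500 ms
   count as incorrect; per condition the summary is accuracy and the
   median RT of correct responses, from which two cost indices follow:
   speed cost (RT₂ − RT₀)/RT₀ and accuracy cost (acc₀ − acc₂)/acc₀.
4. **Inference.** A mixed-design repeated-measures ANOVA (component ×
   age group) on load effects, post-hoc pooled t-tests, regressions of
   cost indices on effect-coded age, within-group z-scored load effect
   and their interaction, Spearman correlations between activation and
   accuracy, and the Fisher r-to-z comparison of two independent
   correlations, z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).

No real cohort is bundled; the `simulate` module generates BOLD volumes,
event/motion tables and trial-level behavior whose statistical structure
matches the design (sparse signed component maps, per-subject condition
amplitudes, subject- and age-varying HRFs, spontaneous network
fluctuations, drift, noise, and published young/old RT and accuracy
distributions with a tunable activation–accuracy coupling).

## Worked example

```python
import numpy as np
from nback_ica import (SimulationConfig, build_schedule_for, generate_ground_truth,
                       generate_subject_bold, GroupDataset, run_group_ica,
                       compare_correlations, cost_indices)

cfg = SimulationConfig(grid_dims=(14, 14, 10), n_sources=8,
                       n_subjects_per_group=6, trials_per_block=20,
                       scans_per_condition=40, noise_sd=1.0, seed=0)
schedule = build_schedule_for(cfg)
truth = generate_ground_truth(cfg)
volumes = [generate_subject_bold(truth, schedule, i, cfg)[0]
           for i in range(cfg.n_subjects)]
dataset = GroupDataset.from_volumes(volumes)
decomposition = run_group_ica(dataset, n_components=10, n_runs=10, seed=1)

match = np.abs(np.corrcoef(np.vstack([truth.source_maps,
                                      decomposition.maps]))[:8, 8:])
print("recovery per source:", match.max(axis=1).round(3))
print("min stability index:", decomposition.stability.min().round(3))

speed_cost, accuracy_cost = cost_indices(589.0, 866.0, 0.94, 0.73)
print(f"old-group costs: speed {speed_cost:.2f}, accuracy {accuracy_cost:.2f}")

z = compare_correlations(-0.017, 38, 0.534, 37)
print(f"accuracy-BOLD correlation difference: z = {z.z:.3f}, p = {z.p:.3f}")
```

Output:

```
recovery per source: [0.987 0.987 0.986 0.989 0.985 0.99  0.988 0.989]
min stability index: 0.716
old-group costs: speed 0.47, accuracy 0.22
accuracy-BOLD correlation difference: z = -2.545, p = 0.011
```

Every planted network is recovered with spatial correlation ≥ 0.985
from 12 simulated subjects at unit noise; the cost indices applied to
the published old-group means give a speed cost of .47; and the Fisher
comparison of the published 2-back accuracy–BOLD correlations (young
ρ = −.017, n = 38 vs old ρ = .534, n = 37) gives z = −2.545, p = .011.

A full pipeline (simulate → decompose → regress → behavior → stats)
is also available from the shell:

```bash
nback-ica --config configs/small.yaml --out out/ run
```

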