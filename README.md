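# fluctica

Component-level analysis of block-design fMRI for studies where the
interesting signal is *unstable*: group ICA decomposition, spectral
artifact screening, task-relatedness tests, a Fano-factor-style
trial-variability index, and residual-correlation coupling labels —
validated end to end on synthetic cohorts with known ground truth.

## The problem

In paradigms such as thought suppression, the process under study
fluctuates within a task block: subjects lose and regain control, so the
haemodynamic response is poorly described by the constant-amplitude boxcar
a conventional GLM assumes, and real effects can vanish under family-wise
correction.  A component-level route is more forgiving: decompose the data
into networks first, then ask of each network's time course (a) is its
baseline task-related, (b) how much does it fluctuate around its typical
response in each condition, and (c) how is that fluctuation coupled across
networks?

## What the package computes

- **Group spatial ICA** (`fluctica.gica`) — per-run PCA, temporal
  concatenation, group PCA + whitening, natural-gradient Infomax
  (logistic nonlinearity), ICASSO stability selection (bootstrap +
  random restarts, average-linkage clustering, centrotype
  representatives, quality index I_q), and dual-regression
  back-projection to per-subject time courses.
- **Artifact screening** (`fluctica.screen`) — low-frequency power ratio
  LFPR = Σ P(0.003–0.10 Hz) / Σ P(0.15–0.25 Hz) per subject, averaged;
  components with mean LFPR < 3 are spectral artifacts, < 3.5 suspicious;
  components whose suprathreshold (|z| > 2) voxels fall mostly outside
  the brain mask are spatial artifacts.
- **Task-relatedness** (`fluctica.taskstats`) — per-run OLS
  y = Xβ + ε against eight HRF-convolved regressors (four condition
  epochs + four cue-event trains), Δβ = β_imagery − β_suppression,
  one-sample t over subjects (Analysis 1); and a two-sample t between the
  condition phases of the grand-average cycle (Analysis 2).
- **Fluctuation index** (`fluctica.fluct`) — after 0.005–0.1 Hz
  band-passing, the sd of a subject's residuals around the grand-average
  condition response, divided by the grand-average response amplitude:
  an fMRI analogue of the Fano factor.  Conditions compared by paired t
  on log indices; association with a binary self-report by two-sample t
  on the log suppression/imagery ratio.
- **Residual coupling** (`fluctica.coupling`) — per-block Pearson r of
  band-passed, detrended time courses (first 8 s of each block dropped),
  Fisher Z = atanh(r) pooled over trials, per-condition one-sample t
  across subjects; a pair is `positive`/`negative` only if both
  condition tests agree in sign and significance, else `equivocal`.
- **Reference voxelwise GLM** (`fluctica.glm`) — one contrast regressor +
  cue nuisances per run, random-effects group t, Bonferroni over in-mask
  voxels; used to demonstrate the sensitivity gap against the
  component-level tests.
- **Synthetic cohorts** (`fluctica.cohort`) — 20 subjects × two 408-s
  runs of alternating 24-s imagery/suppression blocks with 2-s cues,
  spatially fixed Gaussian-blob networks, condition-dependent baselines,
  AR(1) within-block fluctuation with exact latent couplings, artifact
  components, NIfTI/BIDS-style rendering, and a ground-truth sidecar.

## Worked example

```python
import fluctica as fl

result = fl.run_pipeline(fl.RunConfig(master_seed=1))
print(result.summary[["component", "screen_label", "a1_t",
                      "fluct_ratio", "coupling_label"]])
```

The run decomposes the default cohort into ten components, screens out the
two injected artifacts, and identifies component 8 as the
suppression-related network (reference).  Key rows of the summary it
prints:

```
 component screen_label    a1_t  fluct_ratio coupling_label
         0 artifact_spatial  1.848       1.539      equivocal
         1 artifact_spectral -49.450     1.968       negative
         8 valid           -69.019       0.513      reference
         9 valid            42.841       0.682       negative
```

Read: component 8 has a strongly negative imagery-minus-suppression
contrast (suppression-related, t = −69), and component 9 (the imagery
network) is labelled negatively coupled to it — reciprocal activation.
On the ground-truth time courses the suppression network's
suppression/imagery fluctuation ratio comes out at 1.81–2.01 against an
injected 2.0, and the self-report association scan puts its minimum p
(2e-4) on the executive-control network whose injected ratio generated
the report flags.  The companion scripts print the same analyses step by
step:

```bash
python analysis/01_simulate_cohort.py   # render the cohort under scratch/
python analysis/02_group_ica.py         # ICASSO fit + recovery table
...
python analysis/07_sensitivity_gap.py   # GLM vs component-level contrast
```

The last one prints the sensitivity gap: Bonferroni-surviving GLM voxels
in the fluctuating network fall 92 → 83 → 1 as its within-block
fluctuation is scaled ×1, ×5, ×12 at a fixed mean effect, while the
component-level contrast test stays significant throughout (p ≤ 7e-6).

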