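# Methods

`fluctica` implements a component-level analysis of block-design fMRI built
around four ideas: decompose the 4-D data into spatial networks by group
ICA, screen the components for artifacts by their spectral content and
spatial extent, characterise each retained component's task engagement and
trial-to-trial variability, and label between-network coupling from the
residual (task-removed) correlation structure.  Because the analysis is
validated entirely on synthetic cohorts, the generator is a first-class,
tested part of the package: every downstream quantity can be checked
against the numbers that were injected.

## Experimental design model

A run is a lead-in rest followed by alternating *imagery* and *suppression*
phases.  Each phase consists of consecutive 24-s sub-blocks (two per phase
by default), every sub-block onset cued by a 2-s fixation flash.  The
default layout — 24-s lead-in, four pairs of 48-s phases, TR 2.0 s — gives
a 408-s run of 204 volumes; the first four volumes are discarded before
analysis, leaving 200.  Onsets are constrained to the volume grid, block
intervals are half-open `[onset, onset + duration)`, and time is measured
in seconds from run start.

The canonical haemodynamic response is the usual double-gamma difference
(peak ~5 s, undershoot ~16 s, undershoot ratio 1/6) sampled at the TR and
normalised to unit sum, so a sustained boxcar of amplitude *a* plateaus at
*a* and regression coefficients keep the units of the data.

## Synthetic cohort generator

Each component is a compact spatial map (a sum of 3-D Gaussian blobs,
sigma 1.4 voxels, truncated at 5% of peak, on a 16 x 16 x 8 grid with an
inscribed-ellipsoid brain mask of 816 voxels) plus a run-long time course

    y_k(t) = (baseline_k * boxcar)(t) ⊛ HRF + f_k(t),

where `f_k` is the within-block fluctuation process: an AR(1) chain
(coefficient 0.5) restarted at every block boundary, driven by
unit-variance innovations and scaled to the condition-specific stationary
sd `fluct_sd[condition]`.  The AR(1) choice concentrates fluctuation power
in the 0.005–0.1 Hz band the downstream index measures, which white noise
would not.  Coupling between components is built from shared latent
streams: a "spoke" component's innovations are
`w * z_hub + sqrt(1 - w^2) * z_own`, which makes the latent correlation
equal the signed weight *w* exactly (several spokes may share a hub; two
spokes coupled at w1 and w2 correlate at w1*w2).  Artifact components carry
band-limited noise (white noise masked to a frequency band in the DFT
domain) instead of task structure; one artifact additionally lives mostly
outside the brain mask.  Voxel data are the linear mixture
`maps x timecourses + white voxel noise`.

The default cohort is 20 subjects x 2 runs with ten components: a
suppression-related frontoparietal network (baseline 0 / 1 in imagery /
suppression, fluctuation sd 0.35 / 0.7 — a twofold increase under
suppression), an imagery network with the mirrored baseline and the same
twofold fluctuation, coupled at −0.6 to the suppression network; an
executive-control network coupled at +0.6 whose suppression-condition
fluctuation carries a log-normal between-subject spread (sd 0.4) — the
binary "could you suppress your thoughts?" report flag is a median split
on that injected ratio, which guarantees non-empty groups; a dorsal
attention network (+0.6), a posterior default-mode network (−0.6, with
*decreased* suppression fluctuation), and three uncoupled networks; plus a
0.15–0.25 Hz artifact and an out-of-mask low-frequency artifact.  Voxel
noise sd is 0.2 against baseline amplitudes of 0.25–1.0.  These levels were
chosen once so that the injected effects are recoverable at study scale
with the same qualitative pattern the analysis is meant to expose
(decisive suppression network, marginal task-equivocal networks); they are
not re-tuned per experiment.

Everything is a deterministic function of `(config, master_seed)` through
a spawned `SeedSequence` tree; re-rendering a cohort reproduces the
ground-truth sidecar byte for byte.  Rendered cohorts use NIfTI-1 volumes
(TR in the header), BIDS-style `events.tsv` / `participants.tsv`, and a
schema-versioned JSON sidecar sufficient to score recovery.

What the generator does *not* emulate: head motion, slice timing,
physiological cycles, scanner drift, spatial autocorrelation of the noise,
and nonlinear HRF variation.  Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes, not that it is
robust to real-scanner confounds.

## Group ICA

Temporal-concatenation spatial ICA in the GIFT tradition.  Each run is
voxel-wise demeaned and reduced over time to 1.5x the model order by PCA;
the reduced blocks are concatenated and reduced again to the model order
with whitening (whitened rows have unit population variance and zero
mutual correlation to 1e-6, asserted).  Infomax with a logistic
nonlinearity and natural-gradient updates unmixes the whitened matrix;
the learning rate anneals geometrically (0.97/pass), convergence is a
weight-change Frobenius norm below 1e-7 within 512 passes, and a weight
explosion halves the rate and restarts (at most five times).

Stability selection (ICASSO): the ICA is repeated ten times, each run
bootstrap-resampling the sample axis of the whitened matrix and drawing a
fresh random initialisation.  All estimates are pooled; similarity is the
absolute Pearson correlation between estimate time courses (obtained by
regressing the concatenated data on each run's maps; similarity between
maps is available as a configuration switch).  Average-linkage
agglomerative clustering cuts the pooled estimates into model-order
clusters; each cluster is represented by its centrotype (maximal average
within-cluster similarity) and scored by the cluster quality index
`mean intra-cluster similarity − mean extra-cluster similarity`.  In the
degenerate identical-runs case the intra term is exactly one and the index
approaches one up to the sampling correlation between distinct components'
time courses, which is why the degenerate test asserts 1.0 within 0.05
rather than exactly.

Back-projection is dual regression: subject time courses come from
regressing each volume on the group maps, subject maps from regressing the
data on those time courses.  Map signs are fixed by positive skewness, and
stored maps are z-scored over in-mask voxels.  The synthetic default runs
at model order 10 on the 16 x 16 x 8 grid, a deliberately scaled-down
setting (the configurable model order defaults to the conventional 30 for
real-sized data).

## Artifact screening

The low-frequency power ratio (LFPR) of a component time course is the
summed raw-periodogram power in 0.003–0.10 Hz divided by that in
0.15–0.25 Hz (no taper; band edges inclusive; a numerically empty
denominator returns an `inf` sentinel and a numerically empty numerator
returns 0, where "empty" means below 1e-12 of total power — pure-tone
inputs otherwise leak ~1e-29 of power into the far band).  LFPR is computed
per subject/run and averaged arithmetically.  A component is
`artifact_spatial` when more than half of its suprathreshold (|z| > 2)
voxels fall outside the mask — this screen takes priority, since an
out-of-mask component is an artifact regardless of its spectrum —
otherwise `artifact_spectral` below LFPR 3.0, `suspicious` in [3.0, 3.5)
(retained downstream, conservatively), and `valid` above.  At 200 samples
and TR 2 the two bands hold 39 and 41 periodogram bins, so white noise
scores near 39/41.

## Task-relatedness

*Analysis 1 (subject-level regression).*  The design matrix holds eight
HRF-convolved regressors: four condition epochs (imagery first/second
sub-block, suppression first/second) and four cue-event trains (zero-
duration impulses at each epoch type's onsets).  An intercept is added for
estimation only.  Betas are estimated per run by OLS, averaged across runs
within subject, contrasted as `mean(imagery betas) − mean(suppression
betas)`, and tested against zero with a two-sided one-sample t across
subjects.  The per-subject contrast equals a brute-force normal-equations
solution to 1e-8 (asserted), the null rejection rate is calibrated at the
nominal level, and all downstream statistics are invariant to component
sign flips up to the sign of t.

*Analysis 2 (pooled cycle).*  All imagery+suppression cycles from all
runs and subjects are averaged into one grand-average cycle; the imagery-
phase samples (24 at the default layout) are compared with the
suppression-phase samples by a two-sided two-sample t.  By default no
phase-onset volumes are excluded, matching the 24-vs-24 sample count of
the study design; an `analysis2_exclude` switch can drop the cue-overlap
volumes.  This analysis is descriptive (it ranks relative engagement) and
is reported alongside, never instead of, Analysis 1.

## Fluctuation index

For each component: band-pass the session time course (zero-phase
4th-order Butterworth, 0.005–0.1 Hz), extract the condition-phase
segments (dropping the first four volumes of each phase, matching the
coupling module's cue trim), grand-average them over trials and subjects
into the pooled condition response, subtract the pooled response
positionally from every raw trial, take the sd of a subject's pooled
residual time points, and divide by the grand-averaged response amplitude.
The amplitude normaliser is the peak-to-trough range of the component's
pooled response over the full imagery+suppression cycle — one normaliser
per component.  Normalising each condition by its own response amplitude
(available as `amplitude_scope="condition"`) makes the suppression/imagery
index ratio conflate fluctuation change with baseline amplitude change and
inverts it for strongly task-locked networks, so the shared normaliser is
the default.  The index is invariant to global scaling and to constant
offsets (via the filter's DC removal), equals an explicit two-pass-loop
recomputation to 1e-10, and recovers injected sd/amplitude with median
error under 10% at study scale.

The band-pass uses generous reflection padding (up to 150 samples):
the 0.005 Hz corner lies far below the run fundamental, and short padding
leaves position-dependent edge transients that alias into the per-block
residuals and bias the condition ratio toward one.

Conditions are compared per component by a paired two-sided t-test on
log indices across subjects (pairs with a zero index are excluded with a
warning).  At n = 20 the paired t on log-sd statistics is measured to be
slightly anticonservative (true level ~0.054 at nominal 0.05 over 8000
null replicates) — a property of the procedure, not of the
implementation.  Association with the binary self-report uses a two-sided
two-sample t on the log suppression/imagery ratio between report groups.

## Residual coupling

For a reference component (by default the retained component with the most
negative Analysis-1 t, i.e. the most suppression-related) against every
other retained component: band-pass both session time courses, cut each
24-s sub-block, drop its first four volumes (8 s) to skip the cue
response, linearly detrend the segment, and take the Pearson correlation
per block.  Correlations are Fisher-Z transformed (|r| = 1 clipped just
inside the domain with a warning count), averaged unweighted over a
subject's valid blocks per condition, and tested per condition with a
one-sample t across subjects plus a paired t for condition change.  A pair
is labelled `positive`/`negative` only when both per-condition tests are
significant (two-sided alpha 0.05, uncorrected; Bonferroni available) with
concordant sign, and `equivocal` otherwise — squaring the per-test level,
so null pairs are mislabelled at well under 1%.

On back-projected (rather than ground-truth) time courses, residual map
crosstalk can systematically inflate small correlations and occasionally
promote an uncoupled pair past the threshold; the label-recovery
guarantees are therefore stated for the statistical path given the
component time courses.

## Reference voxelwise GLM and the sensitivity gap

The model-driven baseline fits every in-mask voxel per run with one
condition-contrast regressor (imagery boxcar minus suppression boxcar,
HRF-convolved), two cue-onset event regressors, and an intercept (a
head-motion nuisance slot is accepted but unused — the synthetic data
contain none).  Per-subject contrast images (runs averaged) enter a
one-sample t across subjects, Bonferroni-corrected over in-mask voxels at
alpha 0.05.  Bonferroni is exact and conservative, which suits a
demonstration about *relative* sensitivity.

The sensitivity-gap demonstration scales the suppression network's
fluctuation sd by {1, 5, 12} at a fixed mean condition effect.  The grid
comes from a variance argument: the fluctuation's projection onto the
contrast regressor adds per-subject contrast noise of roughly 0.2 sd(f),
so Bonferroni detection (group t ≈ 5.8 over ~800 voxels at n = 20) fails
once sd(f) exceeds a few times the mean effect, while the component-level
test (t ≈ 2.1 needed) survives another factor of ~3.  Measured at seed 3:
92 → 83 → 1 surviving voxels in the network while the component-level
contrast p stays below 7e-6.

## Pipeline and reproducibility

`run_pipeline` chains generator → group ICA → screening → task tests →
fluctuation → coupling → GLM, writes every table as TSV/JSON plus a
provenance record (config hash, seed, stage timings, library versions),
and is deterministic given `(config, master_seed)` — asserted by hashing
the summary table.  The numbered scripts under `analysis/` run the same
stages one at a time on the default cohort, caching the decomposition
under `scratch/`.  Test and acceptance problem sizes (model order 10,
16 x 16 x 8 grid, 300-replicate null studies) are the package's scaled-
down defaults chosen to keep the full validation suite in the minutes
range; the statistical procedures themselves are size-agnostic.

## Known limitations

- The generator's omissions listed above; in particular, white voxel noise
  makes the spatial-screen margin easier than realistic structured noise.
- Back-projection crosstalk inflates weak couplings (see above).
- Infomax assumes supergaussian sources (logistic nonlinearity); purely
  subgaussian components would need the extended variant, not implemented.
- The ICASSO quality index is reported per component but no automatic
  reject-by-stability rule is applied.
- `load_cohort` reconstructs the block design from the events table and
  assumes the alternating two-condition layout this package generates.
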