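# Methods

## Scope and model

`microdfc` implements a microstate-conditioned dynamic functional
connectivity analysis for multichannel resting-state EEG, aimed at
discriminating two patient groups (labelled MCS and VS throughout, for
minimally conscious versus vegetative / unresponsive wakefulness
state). The pipeline is: microstate segmentation → per-state EEG
concatenation → 30-s windowed mutual-information (MI) connectivity →
statistical screening of channel-pair features → mRMR ranking →
nested-CV wrapper selection → cortical network export. Because no
clinical recordings ship with the package, a synthetic cohort generator
with planted ground truth is a first-class component: it defines the
conditions under which every downstream claim is tested.

## Microstate segmentation

**GFP and clustering items.** The global field power at sample *t* is
the spatial standard deviation of the average-referenced potentials,
`GFP_t = sqrt(mean_i u_i(t)^2)`. Topographies at strict local maxima of
the GFP curve (plateaus contribute their first sample) are the
clustering items; all other samples are never clustered, only
backfitted.

**Modified k-means.** Items are assigned to the template with maximal
absolute spatial (Pearson) correlation — polarity is ignored — and each
template is updated as the dominant eigenvector of its assigned raw
maps, which is the GFP²-weighted, sign-invariant centroid. Quality is
the global explained variance `GEV = Σ (GFP_j·C_j)² / Σ GFP_j²`; the
best of `n_restarts` (default 20) random initializations wins. Empty
clusters are reseeded from the worst-fit item. On tiny instances the
procedure attains the enumerated global GEV optimum (tested against an
exhaustive-assignment oracle).

**Choice of k.** The number of classes (searched in 4–6) maximizes a
split-half validated GEV: templates fitted on even-indexed peak maps
are scored on odd-indexed maps, and k grows from the lower bound while
an extra class adds more than `gain_threshold = 0.01` held-out GEV.
This deliberately simple criterion replaces the published meta-criteria
it stands in for, and it recovers the generating k on synthetic data
(10/10 seeds for k = 4 and k = 5 at default noise).

**Group templates.** Individual template maps (unit-norm, hence equal
weights) are pooled and re-clustered. By default both groups are pooled
together (`template_scope="pooled"`) so that state indices are shared
across groups; a `per_group` mode clusters each group separately and
matches states across groups by Hungarian assignment on absolute
correlation. Pooled is the default because every downstream feature
table compares the same state across groups, and a matching step is a
second point of failure with no benefit on cohorts that share a
template basis.

**Naming.** Group templates are matched (Hungarian, max total |corr|)
to built-in archetypes over the montage geometry: A and B the two
diagonal gradients, C the anterior–posterior split, D the central arc,
E the left–right-symmetric midline pattern; surplus templates get the
next free letters.

**Backfitting and smoothing.** Every sample takes the template with
maximal |corr| (ties → lowest index; zero-variance samples inherit the
previous label). Runs shorter than 20 ms (5 samples at 250 Hz) are then
rejected shortest-first: a short run is handed to its two flanking
states at the sample split that maximizes the summed per-sample
correlation with the flanking templates. The handover is kept
contiguous — a literal simultaneous per-sample reassignment oscillates
indefinitely on noisy label sequences — and each merge removes at least
one run, so termination and the minimum-duration invariant are
guaranteed. A sequence shorter than the minimum collapses to the single
best-fitting state.

## Windowed MI connectivity

The samples of one state are concatenated in temporal order and cut
into consecutive non-overlapping windows of `window_s = 30` s; the
trailing remainder is discarded, so the window count is
`floor(total/30)`. This floor rule reproduces 9 of the 10 published
total-length/window-count pairs exactly; the tenth published row is
internally inconsistent with any windowing rule (its printed count
corresponds to a total 60 s larger, an apparent misprint) and is
documented rather than matched.

Within each window, MI is estimated for all channel pairs. The default
estimator discretizes each signal into `b = 8` equiprobable (rank)
bins and applies the Miller–Madow correction
`(K_x + K_y − K_xy − 1)/(2n)` to the plug-in estimate, clipping at
zero. Quantile binning makes the estimate invariant under strictly
monotone rescaling; the correction cancels the independence bias almost
exactly (null ≈ 4·10⁻⁴ nats at n = 30 000, against a 0.02-nat bound).
Discretization necessarily loses information relative to the continuous
MI — at ρ = 0.9 a bivariate Gaussian's MI is underestimated by ≈ 0.13
nats with 8 bins — so a Kraskov–Stögbauer–Grassberger k-NN estimator
(k = 4, Chebyshev metric, deterministic tie-breaking jitter) is
provided behind the same `MIEstimatorConfig` interface and is the one
checked against the Gaussian closed form `−½ ln(1−ρ²)` (error ≈ 0.005
nats at n = 10⁵). Units are nats by default, bits optionally.

MI connectivity is computed on the same 2–20 Hz signal that was
microstate-labelled. The band for connectivity is not dictated by the
analysis itself; computing it on the labelled signal keeps one signal
path and is configurable.

Group-average difference matrices are `mean(MCS windows) − mean(VS
windows)`, entrywise, per state.

## Feature selection and classification

The 496 upper-triangle entries of each window's MI matrix form the
feature table of that state (rows = windows of both groups). Per
column, each group is Shapiro–Wilk tested at α = 0.05; two normal
groups are compared by an equal-variance t-test, otherwise by a
two-sided Mann–Whitney test. Columns with `p < 0.01/496` form the TFS
(the Bonferroni divisor stays at 496 regardless of the montage). Under
a global null the family-wise error measured over 200 replicates is
≈ 0.005–0.02, within the binomial envelope of the 0.01 bound.

The TFS is ranked by greedy mRMR in its mutual-information-difference
form: step one maximizes `I(f; c)`; step k maximizes
`I(f; c) − (1/|S|) Σ_{s∈S} I(f; s)`, ties toward the lower column
index. Feature MI uses the same 8-bin quantile estimator as the
connectivity stage; the class variable stays discrete. The
implementation agrees with a literal uncached double-loop forward
search on 100 random instances.

Wrapper selection is nested: a stratified outer 5-fold split (4:1); on
each outer-training fold, for every feature count x, a stratified inner
7-fold split (6:1) estimates validation accuracy. x* maximizes the
mean inner accuracy (smallest x on ties), and per-fold test metrics
come from models refit on each full outer-training fold and scored once
on the held-out fold. Outer-test rows never reach the inner loop
(asserted on the recorded index sets). Accuracy, TPR and TNR are exact
ratios of the confusion counts, with NaN when a denominator is empty;
the positive class defaults to MCS and is recorded in every report.
The default classifier is LightGBM gradient boosting (500 iterations,
depth 6, learning rate 0.1, deterministic single-thread mode);
`logreg` gives a fast linear alternative, used by the recovery
benchmark because its planted effects are linear in feature space.
The mRMR ranking is computed once on the full TFS before the CV by
default, mirroring the analysis design this package reimplements; when
ranking inside each training fold matters for a new study, rerun
`mrmr_rank` per fold on the fold's rows. Window-level splitting leaks
subject identity across folds; `CVConfig(unit="subject")` keeps each
subject's windows in one fold and is the defensible setting for real
cohorts (expect lower, more honest accuracies there).

## Cortical networks

Selected channel pairs are drawn on the cortex by direct
electrode-to-anatomy lookup, not source localization. The packaged
32-electrode 10–20 atlas carries, per electrode, the projected
anatomical structure, a gyrus + Brodmann-area code, MNI-style
coordinates and one of four lobes. Sixteen electrodes carry
literature-reported projection coordinates; the remaining sixteen carry
approximate standard projections (several mirrored from a reported
homologue) and are marked `provenance="approximate"`. Exports are
plain-text `.node` (x y z, lobe color class, constant size, label) and
`.edge` (square weighted adjacency) files plus a JSON edge report;
edge weights are the corresponding difference-matrix entries,
bit-for-bit, with positive = stronger in MCS.

## Synthetic cohort generator

The generator defines the study conditions: 32 channels at 250 Hz,
300 s per subject, 16 subjects per group, five template maps, segment
durations uniform on 80–120 ms.

* **Templates** are random orthonormal maps in the zero-sum subspace
  (average-reference consistent; at most `n_channels − 1` exist), so
  pairwise spatial correlations are exactly zero.
* **Segments** draw continuous uniform durations mapped to sample
  boundaries by cumulative rounding; states never repeat consecutively
  and each segment's polarity is a random sign, matching the
  polarity-invariance of the clustering.
* **Envelope.** Each segment's amplitude is a Hann bump with floor 0.25
  times a per-segment amplitude (U(0.5, 1.5)) times a smooth (15-Hz
  low-pass) modulation of depth 0.3. The bump guarantees at least one
  interior GFP maximum per segment — a bare low-pass-noise envelope
  does not — and keeps boundary samples nonzero.
* **Residual activity.** On top of the rank-1 template component each
  channel carries independent smooth residual activity at
  `residual_frac = 0.5` of its local signal (signed template weight ×
  envelope). Real scalp data are not rank-1 within a state; the
  residual also carries the planted couplings.
* **Coupling** correlates the residuals of a planted channel pair
  within the planted state's segments by variance-preserving mixing
  with a shared latent; `strength` is the resulting residual
  correlation. Because marginals are untouched, topographies, GFP and
  backfitting are identical in distribution across groups — the
  planted pair's joint dependence is the only group difference. Naive
  additive signal-scale latents were rejected: they distort coupled
  states' topographies and leak group differences into hundreds of
  unrelated channel pairs. `strong_effect_coupling` plants pairs on
  each state's highest-|weight| channels, since coupling channels
  without state signal has no effect by construction.
* **Heterogeneity and noise.** Per-subject amplitude (×U(0.8, 1.2)) and
  noise-level (×U(0.75, 1.3)) jitter model cohort variability; sensor
  noise is spatially white Gaussian at `noise_sd = 1.0` against a
  ~20 µV-scale signal, with an optional 1/f temporal coloring flag.
  "Noiseless" in oracle tests means `noise_sd = 0` **and**
  `residual_frac = 0`, i.e. every sample's topography is exactly
  proportional to its template.

What the generator does **not** emulate: ocular/myogenic artifacts,
volume-conduction forward models, realistic spectra beyond the optional
1/f flag, and non-stationary state prevalence. Passing recovery tests
therefore demonstrate correctness of the pipeline's inference under its
own model class, not clinical performance on real DOC recordings.

A note on realized label noise: the 2–20 Hz zero-phase filter smears
segment boundaries that are only 20–30 samples long, so even
well-recovered templates relabel only ~70 % of samples correctly at
default noise. This is faithful to the physics of the real analysis and
is the main dilution of planted effects at the window level.

## Numerical and procedural choices

* All band-passes are 4th-order Butterworth, zero-phase
  (forward–backward), order exposed; resampling is polyphase FIR with
  anti-aliasing.
* Reference tolerance: a recording counts as average-referenced when
  the per-sample channel mean is below 1e-9 relative to the data scale.
* k-means determinism: every restart draws its initialization from one
  seeded generator; templates get a deterministic sign convention
  (largest-|value| channel positive).
* Master seeds fan out to stages via `numpy.random.SeedSequence`
  spawning; re-running a pipeline config with the same seed reproduces
  every numeric output exactly.
* Recovery benchmark sizes: 16 + 16 subjects × 300 s at 250 Hz per
  master seed, 20 master seeds; the k for clustering is fixed at the
  generating value in this benchmark (its data-driven selection is
  validated separately), and the wrapper stage uses the logistic
  classifier since the planted effects are linear in feature space.

## Known limitations

* Window-level CV splitting (the default, matching the reimplemented
  design) leaks subject identity; subject-grouped mode exists but the
  reported synthetic accuracies use window mode.
* The binned MI estimator is biased downward for strongly dependent
  continuous signals; comparisons across conditions are unaffected,
  absolute values are estimator-specific.
* The electrode atlas is a lookup table, not a head model; coordinates
  for half the montage are approximate.
* `select_optimal_k`'s split-half criterion assumes peak maps are
  exchangeable between half-splits; strongly nonstationary recordings
  may defeat it.
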