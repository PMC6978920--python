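# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic generators do and do not emulate, and the
design decisions taken where the procedure was genuinely open.

## Synthetic resting-state signals

A subject/session is simulated by drawing latent signals from a
multivariate normal whose correlation matrix is assembled from three
planted ingredients: a partition of ROIs into modules with within-module
correlation targets, a hub set whose members receive elevated hub–hub
(`hub_r`) and hub–periphery (`hub_out_r`) correlations (the planted rich
club), and optional per-pair overrides (`seed_pair_r`) used to plant group-
and session-specific seed connectivity such as an ACC–DS increase. The
assembled matrix is projected to the nearest valid correlation matrix by
eigenvalue clipping and diagonal renormalization, which guarantees a
sampleable model at the cost of slightly perturbing targets when the
requested pattern is not positive semidefinite (for the default block/hub
patterns the perturbation is zero). Latent draws are band-limited to
0.01–0.1 Hz with a second-order zero-phase Butterworth so the planted
structure lives where the preprocessing chain preserves it; filtering every
ROI with the same kernel leaves cross-correlations unchanged in
expectation, and identical target rows yield exactly identical series, so
degenerate r = 1 plants survive exactly.

Contaminants are then added per ROI: linear + quadratic drift with random
coefficients (`drift_amplitude`), shared nuisance components — two slow
(< 0.01 Hz) sinusoids standing in for ventricular and white-matter signals
and six smooth motion-like regressors (sums of slow sinusoids plus a small
random walk) with random per-ROI loadings (`nuisance_amplitude`) — and
white noise (`noise_sd`, default 0.5 against unit-variance signal). The
generated confound matrix rides along as ground truth for nuisance
regression. Defaults mirror the acquisition being emulated: 150 ROIs in
bilateral `_L`/`_R` pairs, 300 volumes at dt = 2 s (a 10 min scan). The
generator does not emulate voxel-level MRI physics, realistic noise
spectra, or anesthesia-depth effects; empirical noise parameters are free
knobs, not calibrated values. Passing tests therefore demonstrate that the
analysis chain recovers known structure under plausible contamination, not
that it is robust to every artifact of real scanners.

## Preprocessing

The chain is detrend → nuisance regression → band-pass, in that order.
Detrending removes a least-squares intercept + linear + quadratic fit per
ROI and rescales to unit variance; an ROI left constant is set to zeros and
flagged (`zero_variance`) rather than propagating NaNs. Nuisance regression
takes the OLS residual against intercept plus all confound rows, using the
pseudoinverse with a warning when the confound matrix is rank-deficient
(duplicated confounds change nothing). The band-pass is a fourth-order
Butterworth applied forward–backward (zero phase), with the contract gain
≥ 0.9 mid-band and ≤ 0.1 at ≤ low/2 and ≥ 2·high; the filter family and
order are this package's choice — standard rs-fMRI practice — since only
the band itself is inherent to the method. Spatial blurring belongs to the
optional voxel path only; at ROI level the averaging already pools voxels.
Slice timing, despiking and motion-parameter estimation are out of scope:
the module accepts motion regressors as inputs.

## Graph construction and metrics

Correlation matrices drop the first nine volumes (non-steady-state frames),
cap |r| at 1 − 1e−7 before atanh so perfect synthetic correlations stay
finite, and flag constant ROIs as invalid rather than zeroing them.
Proportional thresholding keeps the floor(density · n(n−1)/2) largest
signed z values — one ranking, so strong negative correlations are never
preferred — breaking ties by ascending (row, column) index, and divides by
the largest retained z; edge weights therefore span (0, 1] with max exactly
1, and the retained-edge count is within one edge of the requested density
by construction. Weighted clustering uses the Onnela geometric-mean-of-
triangle-weights formula with the binary degree in the denominator. Path
length maps weights to lengths 1/w; unreachable pairs are excluded from the
mean and their fraction reported, avoiding infinite means on sparse graphs.
Small-worldness uses Maslov–Sneppen degree-preserving rewiring (10 swap
attempts per edge) with the original weights shuffled onto the rewired
topology; the number of nulls is a runtime knob (the library default for a
single call is explicit `n_nulls`; the demonstration pipeline uses 0 and
exposes `n_smallworld_nulls`). Rich-club curves are computed on the binary
skeleton — φ(k) is the density of the subgraph induced by nodes of degree
> k, flagged undefined below two surviving nodes — matching k-indexed
curves; a weighted variant (subgraph weight over the sum of the same number
of top weights) is provided but off by default, and normalization by random
nulls is likewise available but not default. Seed connectivity pairs
like-hemisphere instances (seed_L–target_L, seed_R–target_R) and averages
them, reflecting the absence of systematic hemisphere differences.
High-strength subnetworks threshold either the across-subject mean
(`mode="mean"`, default) or any-subject exceedance (`mode="any"`), since
either reading of a per-subject strength cutoff is defensible.

## Behavior

The response-bias denominator counts object-choice trials only:
working-memory errors are, by definition, not logged as trials, and the
first free-choice trial of a day is an object-choice trial and is included.
Multi-day aggregates are means of daily bias values over a selectable day
set. The trial generator alternates turn directions, inserts same-direction
WME records with probability `p_wme` (carrying no object choice), and draws
each choice onto the preferred side with probability `side_bias`, giving
the analytic expectation E[bias] → |2·side_bias − 1| at large trial counts.

## catFISH

Inclusion takes a centered window of round(0.2 · n_planes) planes (planes
9–12 of a 20-plane stack); a cell qualifies when its visible range
*intersects* the window (a `covers` mode is available) and it is not
edge-cut. Nuclear positivity requires a run of ≥ 4 consecutive planes each
showing exactly one or two foci — a plane with > 2 foci does not count,
though an `at_least_one` rule is available — and cytoplasmic positivity a
run of ≥ 2 adjacent planes with perimeter coverage ≥ 1/3. Fractions are
computed per image and averaged per rat, so animals (not images or cells)
are the statistical unit; duplicating a rat's image set leaves its mean
unchanged. Task attribution assigns cytoplasmic label to the first epoch
and nuclear to the second under the per-rat counterbalanced order; double-
labelled cells count toward both tasks' activity (required for the
similarity score's event algebra; an `excluded` mode exists because some
summaries drop them). The similarity score
(p_AB − p_A·p_B)/(min(p_A, p_B) − p_A·p_B) is the standard overlap
normalization — 0 at independence, 1 at maximal overlap — and is flagged
undefined when the denominator is not positive. Upstream image segmentation
and foci detection are out of scope; the module consumes per-plane
measurements.

The cell generator allocates class counts exactly (largest-remainder
rounding) so the configured fractions are population ground truth;
negatives receive only sub-threshold patterns (foci runs ≤ 3 planes,
isolated high-coverage planes), which makes the planted labels decodable
with zero error by the rules above and exercises the run-length boundaries.
In the cohort simulation, per-animal lognormal variation (σ = 0.2) on the
planted rates supplies the between-subject variance real populations have.

## Group statistics

Within-group z-scoring (sample SD) removes between-group offsets before
pooling, the guard against spurious pooled correlations driven purely by a
group difference. The pooled correlation reports R with
F = R²(n−2)/(1−R²) on (1, n−2) df. The mixed ANOVA uses the classical
sums-of-squares decomposition: the between-factor F is tested against the
subject-within-group mean square, the within factor and interaction against
the residual within-subject mean square; balanced designs only, with
unbalanced input an explicit error rather than a silent Type-III fallback.
No sphericity correction is applied by default (the reported df are the
classical ones); a Greenhouse–Geisser flag scales the within-subject df by
an epsilon computed from the pooled within-group covariance. A degenerate
zero error term yields F = ∞ when the effect is real and 0 when it is
absent. Subject-relabelling permutation p-values are available as a
distribution-free cross-check, and Bonferroni-corrected per-session
contrasts (α/m) as post hocs. The per-k rich-club comparison runs the
mixed ANOVA independently at each degree threshold, flags underpowered k
levels undefined, reports uncorrected significance with contiguous-band
labels — mirroring shaded-band presentation — and offers Benjamini–Hochberg
FDR across k as an option.

## Pipeline study conditions and problem sizes

The demonstration cohort is 2 groups × 5 subjects × 3 sessions at 150 ROIs
and 300 volumes. Planted conditions: ACC–DLS/DMS correlation trajectories
(0.35, 0.28, 0.20) in young and (0.20, 0.45, 0.65) in aged — the young
decrease accompanies their falling response bias, the aged increase their
persisting bias — hub correlations (0.45 flat young; 0.35, 0.55, 0.65
aged) over 16 hub ROIs, side-bias trajectories (0.70, 0.60, 0.50 young;
0.80, 0.85, 0.90 aged), and Arc rates elevated in the aged dorsal striatum
(~4% vs ~2% positive) but matched in ACC. Validation suites run reduced
sizes chosen as the smallest configurations at which the planted effects
are unambiguous: 60 ROIs with 10 hubs for the 100-replicate recovery suite,
and curve-level Gaussian nulls with subject random effects for type-I
calibration of the per-k procedure (the parametric F is exact under that
model, making it the appropriate null).

## Known limitations

Sessions are simulated independently (no within-subject stability across
sessions beyond the planted structure), so subject-by-session covariance is
weaker than in real longitudinal data. The ANOVA machinery requires
balanced designs; missing cells need upstream handling. The similarity
score is the standard overlap normalization; published variants of this
statistic differ slightly, and no other form is implemented. Voxelwise seed maps, cluster-extent correction
and 3D rendering are out of scope.
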