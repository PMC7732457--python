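# Methods

## Problem and model

`connanomaly` locates *where* an individual brain's connectivity deviates
from a healthy cohort, rather than classifying the subject. Both cohorts are
represented on a fixed 379-region atlas (the HCP-MMP1 cortical parcellation,
180 parcels per hemisphere, plus 19 subcortical structures: 9 per hemisphere
and the brain stem). Each subject contributes two symmetric region-by-region
matrices: structural connectivity (streamline counts from diffusion
tractography) and functional connectivity (Pearson correlations of regional
BOLD time series; for 379 regions the full square matrix holds
379² = 143,641 correlations).

The normative model is per-edge. For each of the n(n−1)/2 = 71,631 unordered
edges e, the control cohort yields a mean μ_e and sample standard deviation
σ_e (ddof = 1) on a *detection representation*:

* **Structural** — log1p of the streamline count. Streamline counts are
  heavy-tailed over several orders of magnitude; the log stabilizes variance
  and keeps zero counts representable. A raw-count option is retained in
  configuration.
* **Functional** — tangent-space coefficients. Correlation matrices live on
  the SPD manifold; each subject matrix S is shrunk toward the identity
  (C ← (1−λ)C + λI, λ = 10⁻³, guarding against rank deficiency from finite
  or censored runs), the cohort's affine-invariant (Karcher) geometric mean
  C̄ is computed, and the subject is embedded as
  T = logm(C̄^{−1/2} C C̄^{−1/2}) — whitening by the reference followed by
  the matrix logarithm. Tangent coefficients are Euclidean, so per-edge
  moments are well defined; at the geometric mean the cohort's tangent
  coefficients average to ≈ 0 edge-wise (Karcher stationarity), which the
  tests verify.

**Variance exclusion.** The one-third of edges with the highest
between-subject variance in controls is excluded from detection — these
edges are too variable across healthy subjects for an individual deviation
to mean much, and dropping them is the model's false-discovery control (no
multiple-testing correction is applied beyond it). Exactly
⌊f·n_edges⌋ edges are masked (f = 1/3 default ⇒ 23,877 of 71,631), ties
broken by ascending edge index so the mask is reproducible. Variance is
ranked on the *detection representation* for both modalities — the
representation detection actually uses is the one whose stability matters.

**Detection.** A subject edge is scored z_e = (x_e − μ_e)/σ_e and flagged
anomalous when |z_e| > k (k = 3 default), with the direction recorded
(anomaly_low / anomaly_high). The boundary |z| = k is *normal* (strict
inequality — arbitrary but fixed). Edges with σ_e = 0 are *degenerate*:
a 0/0 z-score is undefined and such edges are never flagged. Patients never
contribute to the reference they are scored against. Functional subjects
are embedded with the stored C̄, never re-fit.

**Reporting directions.** Structural fingerprints count the low tail only
(fiber *loss*); functional fingerprints count both tails. Both are
configurable.

## Fingerprint surfaces

* **Burden table** — per region: each flagged (subject, edge) pair
  increments both endpoint regions once; `n_low_variance` is the region's
  count of retained (non-excluded, non-degenerate) incident edges, capped
  by construction at n−1; `total_potential = n_low_variance × n_subjects`;
  the percentage is 100·n_anomalies/total_potential, displayed half-up to
  two decimals (full precision kept internally and used for sorting). This
  counting convention — at most one count per subject per incident edge —
  is the one under which the percentage is a true fraction of its
  denominator.
* **Edge-frequency table** — one row per edge flagged in ≥ 1 subject,
  sorted by subject count descending then region names; annotated with each
  endpoint's network affiliation and the edge class below.
* **Network submatrices** — a subject's per-edge status restricted to one
  network's members, rendered as a text grid in which excluded, degenerate
  and normal edges are background and anomalies stand out.

## Edge classification

Laterality: left/right when both endpoints share a hemisphere, bilateral
when they differ, midline-involved when either endpoint is the brain stem
(the only midline region). Anatomical relationship, in priority order:
both endpoints subcortical → subcortico-subcortical; one subcortical
endpoint → corticobasal (basal ganglia or accumbens), corticothalamic,
corticohippocampal, or cortico-subcortical (other), by the structure;
purely cortical → interhemispheric when hemispheres differ, intralobar
within one lobe, long-range otherwise. "Long range" operationalized as
same-hemisphere-different-lobe is this package's definition; published
usage of the label is informal. Subcortical classes rank above hemisphere
tests so that, e.g., a caudate–orbitofrontal edge is corticobasal
regardless of laterality.

The lobe and network columns of the bundled atlas table are
*configuration*, not ground truth: no canonical lookup is published for
this atlas, and users can supply their own table (same layout) everywhere
an atlas is accepted. The bundled assignment groups the cingulate belt and
medial wall as one lobe and uses conventional large-scale networks (DMN,
CEN, DAN, VAN, Salience, Sensorimotor, Visual, Auditory, Language, Insula,
Orbitofrontal, DLPFC, DMPFC, Lateral parietal, SPL, Limbic, …).

## Synthetic cohorts

No imaging data ships with the package; a generator emulates the study
design (41 controls, 21 patients by default) with exact ground truth.

* Structural: per-edge population log-means drawn once uniformly from
  (0, 5) — counts from ~1 to ~150, matching sparse, right-skewed
  streamline matrices — and subject counts lognormal(m_e, 0.25), rounded.
* Functional: one population covariance from a rank-10 factor model plus
  diagonal noise; subject covariances are Wishart draws with df = 2·n
  degrees of freedom (between-subject spread ≈ df^(−1/2) ≈ 0.036 at
  n = 379, a realistic cohort tightness), converted to correlations.
* Patients are drawn from the *same* generative model; effects are planted
  afterwards so ground truth lists exactly the modified (subject, edge,
  modality) entries. Planted structural edges are multiplied by 0.3
  (fiber loss) and rounded; planted functional edges are shifted by −4
  per-edge control standard deviations of the raw correlations, clipped to
  [−1, 1], symmetry and unit diagonal restored. Effect sizes are
  configurable; the defaults are detectable but not trivial.

`choose_planted_edges` samples plants from retained, non-degenerate edges
of a control-fitted reference, and for structural plants requires a
normative mean of ≥ 5 streamlines: a 70% loss on a 1–2-streamline edge is
erased by integer rounding and does not represent a lesion. This mirrors
the analysis target, whose reportable anomalies are on retained edges by
construction.

What the generator does **not** emulate: spatial autocorrelation of edges,
distance-dependent connection probability, hemispheric asymmetries,
age/sex covariates, scanner effects, motion artifacts. Passing tests
therefore demonstrate the pipeline's statistical behavior under its own
assumptions, not performance on real MRI data.

## Numerical choices

* Geometric mean: fixed-point iteration on the geodesic update with
  backtracking step halving (tolerance 10⁻⁸ on the Frobenius norm of the
  tangent-space mean, max 50 iterations, arithmetic mean start); the step
  control is needed for ill-conditioned inputs (heavily shrunk
  rank-deficient correlations). A log-Euclidean mean is available as a
  cheaper option.
* Matrix functions go through symmetric eigendecompositions; tests
  cross-check against scipy's generic `logm`/`fractional_matrix_power`.
* Subject matrices entering the tangent transform are eigenvalue-clipped at
  10⁻⁶ if indefinite (possible for edited or planted matrices); SPD inputs
  pass through unchanged. Control matrices at fit time must be genuinely
  SPD after shrinkage — violations are errors, not silently repaired.
* Matrix readers symmetrize by averaging when the maximum asymmetry is
  ≤ 10⁻⁶ and reject larger asymmetry; in-memory constructors use 10⁻⁸.
* Exclusion count uses ⌊f·m + 10⁻⁹⌋ to guard the product against binary
  round-off.
* Display rounding of percentages is decimal half-up, matching printed
  tables; sorting uses full precision.

## Parcellation module

The voxel-assignment component is a deliberately simplified, synthetic-data
re-implementation of connectivity-driven parcellation: each voxel's feature
vector is its termination counts to every atlas region; an XGBoost
classifier (60 trees, depth 4, learning rate 0.3, histogram method —
recorded in the model sidecar) learns parcel labels; at assignment,
candidates are restricted to parcels whose training centroid lies within a
radius of the voxel, and a voxel with no candidate in range stays
unassigned. The radius defaults to twice the mean within-parcel RMS
coordinate spread and is logged. Atlas registration, NIfTI I/O and
tractography are out of scope; the contract is
classification-with-centroid-constraint, exercised on planted parcels with
distinctive sparse Poisson signatures.

## Problem sizes used by the validation runs

The planted-recovery experiment runs at 100 regions with 20 seeds
(41 controls / 21 patients / 10 planted edges at multiplier 0.3 each);
the null calibration uses 144 regions × 10 subjects ≈ 1.03 × 10⁵ Gaussian
edge draws; the full-scale pipeline demonstration uses the default
379-region, 41 + 21 cohort. These sizes give stable medians while keeping
each run to seconds-to-minutes on a single core.

## Known limitations

* The normative model is per-edge and Gaussian; with 41 controls the tail
  calibration of extreme z-scores is approximate, and the empirical flag
  rate on null edges slightly exceeds the asymptotic 2Φ(−3) because σ_e is
  estimated.
* Tangent embedding assumes a common manifold location for the cohort;
  strong subgroup structure in controls would bias C̄.
* Edge exclusion is a hard mask; edges near the variance cut switch status
  under resampling.
* The synthetic generator's independence assumptions (see above) make
  false-positive-rate estimates optimistic relative to spatially
  correlated real data.
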