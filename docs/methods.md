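# Methods

`fcgraph` analyzes resting-state functional connectomes in a two-group,
two-timepoint (intervention vs. non-intervention, pre vs. post) design: it
builds region-by-region functional-connectivity (FC) matrices from ROI
time series, summarizes them over intrinsic-connectivity-network blocks,
derives weighted graph topology across proportional density thresholds,
and tests group-by-time interaction effects by covariate-adjusted
permutation. A synthetic-cohort generator with planted effects provides
ground truth for every stage. This note records the model, the defaults,
and the choices made where several defensible options existed.

## Preprocessing and motion scrubbing

Input is the per-session ROI time-series matrix (frames x regions; default
141 regions over 7 cortical systems — SVN, DAN, DMN, ECN, SMN, Visual,
Limbic — plus a subcortical system) together with a 6-parameter motion
trace (3 translations in mm, 3 rotations in radians; a config switch
accepts degrees).

- **Volume discard.** The first 5 volumes of each acquisition run are
  dropped (steady-state magnetization); the default acquisition is 246
  frames at TR = 2 s in two equal runs, leaving 236 frames.
- **Framewise displacement.** FD(t) = Σ|Δtrans_i| + r·Σ|Δrot_i| with
  r = 50 mm (arc length on a head-sized sphere); FD(1) ≡ 0. Censoring
  threshold 0.8 mm.
- **DVARS.** Root-mean-square across ROIs of the frame-to-frame signal
  change, divided by the grand-mean signal of the raw (post-discard,
  pre-filter) series so that the 0.05 threshold reads "5% of mean signal";
  DVARS(1) ≡ 0. The divisor must be positive — ROI series are expected
  grand-mean-scaled, as conventional pipelines produce; for other data the
  divisor can be overridden.
- **Flag rule.** A frame is censored when *either* FD or DVARS exceeds its
  threshold (union — the conservative reading; an intersection rule is
  configurable). No augmentation of neighbouring frames is applied by
  default.
- **Order of operations.** discard → FD/DVARS on the raw series →
  censored-frame interpolation → detrend + band-pass → frame removal.
  Computing the metrics before filtering matters: temporal filtering
  attenuates and smears exactly the transient artifacts scrubbing is meant
  to find. Interpolating censored frames (linear over kept frames) before
  filtering prevents the filter's impulse response from bleeding a
  high-amplitude spike into neighbouring kept frames; the interpolated
  values are placeholders that are removed when the mask is applied.
  DVARS-on-filtered is available as a config option for comparison.
- **Filtering.** Polynomial detrending of orders 1 and 2 (with the mean),
  then a zero-phase band-pass at 0.009–0.1 Hz. The default filter is an
  ideal FFT mask (sharp band edges); a 4th-order Butterworth applied
  forward-backward is available. Tests assert response bounds (in-band
  RMS ≥ 0.9, stop-band ≤ 0.1), not a specific filter identity.
- **Exclusion.** A session with fewer than 100 surviving frames flags the
  subject for exclusion; the pipeline drops such subjects listwise (both
  sessions) before group statistics and logs the count. This is a soft
  signal distinct from validation errors.

## Connectivity

Pairwise Pearson correlation on surviving frames, Fisher-transformed
(z = atanh r, with |r| clipped at 1 − 1e-7 so z stays finite), zero
diagonal. A zero-variance ROI is an error naming the region. Block
summaries average z over all ROI pairs of each system pair — intra-system
cells over the off-diagonal within-system pairs, inter-system cells over
all cross-pairs — giving 8 intra + 28 inter = 36 outcomes. Negative z
values are retained here; the positive-only rule belongs to graph
construction only. A system with fewer than 2 ROIs has an undefined intra
cell, reported as missing rather than zero. Two acquisition runs are
concatenated before correlation.

## Graph topology

The z matrix is thresholded proportionally: negatives are zeroed and the
round(d·R(R−1)/2) strongest positive connections are kept as weighted
edges (round half away from zero; ties at the cutoff resolved in
row-major upper-triangle order so runs are reproducible). The grid runs
d = 15%…35% in 1% steps (21 densities) so no conclusion hinges on a
single threshold. If a matrix has fewer positive entries than the target
count, all positives are kept and the graph is flagged.

Per density:

- **strength** s_i = Σ_j w_ij (primary "degree centrality" on a weighted
  graph), with binary degree emitted alongside;
- **Onnela clustering** C_i = (k_i(k_i−1))⁻¹ Σ_{jh} (ŵ_ij ŵ_jh ŵ_hi)^{1/3}
  with ŵ = w / max(w) and C_i = 0 for k_i < 2 — the variant used by the
  standard brain-connectivity toolbox;
- **shortest paths** with edge length 1/w (stronger = closer), Dijkstra;
  unreachable pairs are +∞;
- **harmonic closeness** (R−1)⁻¹ Σ_{j≠i} 1/d_ij — finite on disconnected
  graphs, which proportional thresholds at 15% can produce; an isolated
  node scores 0;
- **global efficiency** = mean inverse distance over ordered pairs
  (equals mean harmonic closeness); **characteristic path length** = mean
  finite distance over reachable pairs, with the unreachable fraction
  reported;
- **small-worldness** σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩), where the null
  ensemble is 100 Maslov–Sneppen rewired graphs (10 double-edge-swap
  attempts per edge, degree sequence preserved exactly, original weight
  multiset reshuffled onto the rewired topology). σ ≈ 1 for random-like
  topology, σ ≫ 1 for small-world organization. When no legal swap exists
  (e.g. a complete graph) the null equals the graph and σ = 1 exactly.

Each metric's curve is summarized by a trapezoidal integral over the
density grid divided by the grid range, keeping integrated values on the
per-density scale (a constant curve integrates to itself, a linear ramp
to its midpoint).

## Statistics

For a 2x2 repeated design, the group-by-time interaction is exactly the
between-group difference of the within-subject change Δ = time2 − time1,
so every outcome (36 FC blocks, integrated global metrics, integrated
nodal metrics per region) reduces to a two-sample problem on Δ.

Age and scanner are nuisance covariates. Without covariates the test is
the classical two-sample permutation test (pooled-variance t; group
labels permuted over whole subjects, preserving within-subject pairing;
exact enumeration whenever C(n, n_A) ≤ n_perms). With covariates the
Freedman–Lane scheme is used: fit the reduced (intercept + covariates)
model once; the observed statistic is the partial t of the group
indicator with *both* Δ and the indicator adjusted for covariates; each
permutation shuffles the reduced-model residuals, re-projects them, and
recomputes the statistic. The partial-t form matters: simply permuting
labels over residualized values is anti-conservative or conservative
whenever a covariate is unbalanced across groups (the default synthetic
cohort plants exactly such a scanner imbalance), whereas the full scheme
stays calibrated (empirical type-I error 0.046 at α = 0.05 over 500 null
cohorts in the validation suite). Sampled p-values use the add-one
estimator p = (1 + #{|t*| ≥ |t|})/(1 + n_perms), two-sided; the default
permutation count is 5000.

Raw p-values are reported with flags at α = 0.05 (FC/global convention)
and α = 0.01 (nodal convention); no familywise correction is applied by
default, with an optional Benjamini–Hochberg column available.

Brain–behavior association: both the metric change and the behavior
change are residualized on the covariates, then Pearson r with a
two-sided p from the t distribution on n − 2 − k degrees of freedom
(one df charged per covariate). Behavior scales are symptom scores, so
improvement is a score *decrease*; the Δ sign convention is recorded in
the stats manifest.

## Synthetic cohorts

The generator emulates the input bundle of a small pediatric
intervention study: two groups (defaults 18 and 11 subjects), two
sessions each, 246 frames at TR 2 s in two runs, 141 ROIs.

- **Signal model.** Frames are i.i.d. draws from a zero-mean multivariate
  normal whose correlation structure realizes a target block-z table
  (entry tanh(z_ab) for every ROI pair of block (a,b); unit diagonal). If
  the assembled matrix is not positive definite it is repaired by
  clipping eigenvalues at 1e-6 and rescaling the diagonal to 1; the
  repair is recorded, and a spec whose block means move by more than a
  tolerance (default 0.2) under repair is rejected naming the offending
  blocks. The series is scaled to a grand mean of 1000 with 1%
  fluctuation (signal_scale 10), a realistic mean-scaled BOLD regime in
  which baseline DVARS (≈0.014) sits far below the 0.05 threshold.
  Baseline blocks default to intra-network z = 0.3 and inter-network
  z = 0.1 — plausible resting-state magnitudes stated as assumptions, not
  measurements. No temporal autocorrelation is modelled (frames are
  white): all downstream statistics are correlation-based and permutation
  operates at the subject level, so AR structure would change effective
  sample size but not validity; this is the main deliberate departure
  from real BOLD, along with the absence of spatial noise structure and
  of any volumetric/hemodynamic forward model. Passing tests therefore
  demonstrate correctness of the estimators and calibration of the
  inference, not robustness to autocorrelated or spatially structured
  noise.
- **Planted effect.** The default cohort raises the intra-SVN block by
  Δz = 0.15 in the non-intervention group at time 2 only — a
  group-by-time interaction confined to one block. Arbitrary per-(group,
  session) additive block effects are supported.
- **Motion spikes.** A spike is a transient out-and-back head movement
  spanning two consecutive frames: one translation steps by exactly the
  configured FD magnitude (default 1.6 mm) and back, with the smooth
  baseline increments zeroed there, so FD equals the magnitude to
  machine precision at both frames; the signal simultaneously receives a
  one-frame global offset of 10% of the grand mean, so DVARS exceeds
  threshold at the same two frames and nowhere else. The artifact is
  wholly confined to the censored frames — which is what makes exact
  scrub recovery a meaningful test. Spike starts avoid each run's first
  discard+1 frames and last frame so spikes remain recoverable after
  volume discard. The spike rate (default 5% of frames) counts affected
  frames.
- **Behavior.** The standardized behavior change is
  coupling·standardize(ΔFC) + √(1−coupling²)·noise, scaled and shifted by
  per-group means; the driving ΔFC is each subject's *empirical*
  coupling-block z change measured on the clean signal and stored in the
  ground truth. Default coupling 0.4 on the internalizing scale.
  Baseline means/SDs and per-group changes for the inattention and
  internalizing scales default to the target study population's values.
  Scores are continuous (no integer rounding). With equal group offsets
  the population correlation equals the coupling exactly.
- **Covariates.** Age ~ N(9.2, 1.4²) clipped to [6, 13]; scanner is a
  binary label with a deliberately unbalanced mix across groups
  (P(old scanner) = 5/18 vs 9/11) and an optional additive effect on FC
  (default 0).
- **Determinism.** Every random element derives from the master seed via
  fixed spawn keys; identical seeds give byte-identical bundles.

## Pipeline

`RunConfig` (YAML, unknown keys rejected) toggles stages and carries all
thresholds; each stage draws its seed from the master seed by a fixed
offset, so stage toggling does not perturb other stages. The manifest
echoes the config and records per-stage wall-clock, warnings (e.g.
excluded subjects) and SHA-256 hashes of every output table; deterministic
stages reproduce identical hashes under identical configs. Tabular
outputs are TSV with fixed float formatting; matrices are square TSV with
ROI headers; manifests are JSON.

## Validation studies and problem sizes

The validation suite (and `scripts/acceptance.py`) runs:

- brute-force oracle equivalence (Floyd–Warshall distances, triangle
  enumeration) on 50 random weighted graphs of ≤ 30 nodes, tolerance
  1e-10, plus closed-form values on canonical graphs;
- small-world regimes: Watts–Strogatz (100 nodes, degree 6, rewiring
  0.05) vs. Erdős–Rényi (100 nodes, density 0.15), 100 nulls each;
- type-I calibration: 500 null cohorts (groups 18/11) at a reduced
  per-cohort scale of 32 ROIs and 120 frames, 1000 permutations;
- power/specificity: 200 replicate cohorts with the Δz = 0.15 planted
  block at 32 ROIs and 240 frames;
- coupling recovery: 500 replicates at n = 29;
- scrub exactness and the FC round trip at the full 141-ROI scale
  (5000 frames for the round trip);
- end-to-end determinism on a compact two-run configuration.

The reduced simulation scales are the package's own choice of
desk-scale validation conditions; the planted-effect and calibration
results reported by the script are computed fresh at run time.

## Known limitations

- White-noise temporal model (see above); no AR(1) option is currently
  exposed even though the design allows one.
- The default 141-ROI partition is a stand-in layout (111 cortical over 7
  systems + 30 subcortical); real atlas identities must come from a
  partition file.
- Harmonic closeness and the reachable-pair path length make σ
  well-defined on disconnected graphs, but σ comparisons across graphs
  with very different unreachable fractions should be read with care.
- The permutation engine assumes subjects are exchangeable under the
  null given the covariates; family structure or site clustering would
  require restricted permutation schemes that are not implemented.
- No partial correlation, dynamic FC, community detection, or
  mixed-effects longitudinal modelling.
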