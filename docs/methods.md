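# Methods

This note records the modeling assumptions, parameter defaults and numerical
choices behind `meiotrack`, and what the synthetic-data generators do and do
not emulate.

## Data model and units

A track is one centromere's time-ordered 3D positions (µm) with explicit
per-frame times (s) and provenance: anther, cell, compartment
(meiotic/somatic) and prophase stage.  Coordinates are physical, frame indices
are 0-based, and the nominal frame interval of an acquisition is the modal
time step — but every rate computation uses the actual per-step Δt, so mildly
irregular sampling is handled exactly.  Tracks need at least two frames (one
step); shorter ones are dropped at load time with a warning.

## Track filtering and drift correction

Tracks shorter than 15 s carry too few steps for meaningful per-track
statistics and are excluded by default; the boundary-exclusion margin for
tracks touching the image border is exposed as a parameter (default 0, i.e.
off, since an appropriate margin depends on the acquisition).

Drift correction subtracts the average somatic trajectory: at each frame
transition the mean displacement over the somatic tracks observed at both
frames is accumulated into a drift curve that is subtracted from every track.
Somatic tracks may have different lengths and coverage; at frames with no
somatic observation the drift estimate is carried over unchanged (zero
increment).  After one pass the somatic mean per-frame displacement is exactly
zero, so the operation is idempotent, and it commutes with any rigid
translation of the whole acquisition.

## Motion metrics

- Instant speed: step length / step duration, in nm/s.
- Average speed: total displacement / track duration (time-weighted mean of
  instant speeds; identical to the plain mean under uniform sampling).
- Turning angle: deflection between consecutive steps in [0°, 180°]; steps
  shorter than 1e-9 µm are skipped because the angle is undefined.
- Outreach ratio: OR = (MD/TD)·√duration with MD the maximal pairwise distance
  (all O(n²) pairs; n ≤ a few hundred frames in practice) and TD the summed
  path length.  Fully stationary tracks get OR = 0 with a warning.
  OR ≤ √duration always, since MD ≤ TD.

## MSD estimation and model fits

Per track the MSD is the time average over all overlapping pairs at each
multiple of the frame interval; the ensemble curve averages per-track values
at common lags and reports the s.e.m. across tracks.  When no maximum lag is
given, lags are restricted to 25% of the longest track duration — long-lag
estimates average few pairs and are dominated by noise.  An explicit
`max_lag` is honored as given.

Fits:

- Power law: ordinary least squares of log MSD on log lag (zero MSD values are
  excluded; at least 3 lags required).
- Brownian: weighted linear fit MSD = 6·D·τ + offset with weights 1/sem² when
  the s.e.m. is available.  The proportionality constant 6 is the 3D
  convention; `dimensionality=2` switches to 4.  Negative slopes floor D at 0
  and clear the convergence flag.
- Confined: nonlinear least squares over (R, D, a, b) of
  MSD(t) = R²{1 − a·exp(−bDt/R²)}, initialized at R₀ = √(tail mean),
  D₀ = early slope/6, a₀ = 1, b₀ = 6, with bounds 0 < a ≤ 1.2 so R² keeps its
  plateau interpretation.  Only the product b·D is identifiable together with
  R and a (the exponent depends on them only through bD/R²); R and the plateau
  are therefore the quantities to interpret, and both a and b are kept free
  because no canonical values are imposed.  A fit pushing R to its upper bound
  (10× the square root of the largest MSD) indicates an effectively unconfined
  curve and is flagged non-converged.
- Plateau oscillation period: the plateau segment is detrended with a cubic
  polynomial (the smooth approach to the plateau would otherwise mask the
  oscillation) and the first autocorrelation peak above the white-noise band
  2/√n gives the period; segments shorter than two putative periods return
  nothing.

## Coordination

Speed cross-correlation uses Kendall's tau at lag 0 on instant-speed
sequences aligned at shared step times (tolerance: one tenth of the frame
interval; no interpolation, so nothing is fabricated for unshared frames), and
requires at least 5 common steps.  The centroid size is the RMS distance of
the co-observed centromeres from their mean position; time steps with fewer
than two centromeres are absent from the series.  Because the centroid size is
invariant under rigid motion, a flat delta-from-start series is exactly what a
purely rotating nucleus would produce — temporal variation demonstrates
relative motion.

## Nuclear organization

The envelope and nucleolus are idealized spheres, matching how they are drawn
on immunostained preparations (radii ~4.5–5.5 µm and 2–2.5 µm respectively).
Signed distance to the periphery is positive inside; a telomere is peripheral
within ε = 0.5 µm of the surface (the published classification is visual, so ε
is exposed).  Clustering marks telomeres whose average distance to their 9
nearest neighbors is below 4 µm; marked telomeres are then grouped by single
linkage at the same 4 µm radius (the grouping rule is not prescribed by the
marking statistic, so the linkage radius is exposed, and an alternative
`cluster_metric="pairwise"` single-links all ends directly).  A bouquet
requires ≥ 6 of the 16 non-NOR ends in the largest group; without a bouquet
the cluster size is reported as 0.  The bouquet's envelope-area fraction
projects the cluster radially onto the periphery sphere and divides the area
of its spherical convex hull (angle-sum formula on the gnomonic-projection
hull) by 4πR²; clusters of fewer than 3 ends fall back to the minimal
enclosing cap with a warning.  The nucleolus is peripheral when its surface
comes within ε of the envelope.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not the
microscopy itself:

- Motion models: free Brownian (per-axis step variance 2DΔt), confined
  Brownian with mirror reflection of the out-of-bounds excess at a sphere
  (simple, and preserves step-length statistics to first order), fixed-speed
  random walks (uniform directions, exact step length), stationary jitter and
  directed motion.  Stage defaults use the measured constants: mean speeds
  55/106/100/62 nm/s (leptotene/zygotene/pachytene/diplotene), apparent
  diffusion coefficients 0.045/0.016/0.002 µm²/s, confinement radius 4.01 µm,
  somatic baseline D = 5×10⁻⁴ µm²/s (inside the measured 3.0–6.2×10⁻⁴ range),
  and a 2.4 s frame interval.  An optional sinusoidal radial modulation of the
  confining domain (default period 150 s, amplitude 0 — its amplitude is not
  constrained by any measurement) can emulate plateau oscillations.
- Hierarchy: log-normal multiplicative speed factors per anther and per cell
  (speeds are positive, so a multiplicative model is the natural choice;
  diffusion coefficients scale as the factor squared), low-mobility somatic
  tracks per anther, and one rigid drift velocity shared by all tracks of an
  anther.
- Nuclei: wild-type kinds place non-NOR ends at the envelope (93% attachment
  by default, cluster of 10/9/8 ends for zygotene/pachytene/diplotene in a
  1 µm-geodesic cap) with a tangent nucleolus and NOR ends at the
  nucleolus-envelope interface; the `sun1sun2_like` kind draws peripheral
  attachment per end (default expectation 40%), parks detached ends near the
  nucleolus at least 1 µm clear of the envelope, and makes the nucleolus
  internal with probability 0.5.  Non-clustered peripheral ends are spread by
  best-candidate (farthest-point) sampling, so a requested mutual separation
  is met whenever geometrically feasible.
- Image stacks: isotropic Gaussian spots over Poisson background at a
  requested SNR, for exercising the detection/linking stage.

All generators are pure functions of (config, seed).  What passing tests on
these simulations show is that the estimators recover their generating
parameters and honor their invariants — not that real chromatin follows these
models: the generators contain no polymer mechanics, no photobleaching or
anisotropic PSF, no synapsis, and no alternation between paused and directed
episodes.

## Detection and linking

Detection smooths each volume with a Gaussian (default σ = 0.2 µm), finds
local maxima above median + 8 robust (MAD-based) standard deviations with
non-maximum suppression at 1 µm (the approximate spot diameter), and refines
centers to the intensity centroid of a 0.5 µm-radius neighborhood.  Linking is
greedy mutual-nearest-neighbor between consecutive frames, gated at a maximum
displacement (default 0.5 µm ≈ 3× the expected step at 160 nm/s and 2.4 s),
with distance ties resolved to the lower track id.  When two tracks converge
on one spot, the nearer continues and the other ends; a spot splitting in two
continues the original track on the nearer spot while the other seeds a new
track.  Gap closing across missing frames and motion-model (Kalman-style)
tracking are out of scope; single-detection tracks carry no step and are
dropped.

## Hierarchical statistics

The mixed model uses random intercepts only (anther, plus a variance component
for cell within anther), fitted by maximum likelihood so the likelihood-ratio
test between the models with and without the fixed factor is valid; REML
likelihoods are not comparable across fixed-effect structures.  Zero variance
components are flagged as singular but the p-value is still reported.  Metrics
are analyzed on their natural scale by default with a log-scale option.
Pairwise stage comparisons are reported unadjusted by default, with an
optional Benjamini–Hochberg correction.  The permutation alternative uses the
anther as the exchangeable unit (difference of group means of per-anther
means, labels permuted across anthers, p = (1+#{null ≥ obs})/(1+n_perm)),
which is valid by construction under the nesting but requires at least two
anthers per group.

## Problem sizes and numerical conventions

Simulation-based tests and the acceptance computations use ensembles of
100–200 tracks of 50 steps at Δt = 2.4 s (recovery runs averaged over 20
seeds), 300–500 nuclei for attachment-fraction checks, and 500 replicates for
permutation type-I calibration — sizes at which the estimators' sampling noise
is comfortably below the tolerances being checked.  Zero-length steps use a
1e-9 µm threshold; CSV round-trips write doubles with 17 significant digits
and parse with round-trip precision.

## Known limitations

- The confined-model parameters b and D are reported as fitted but only their
  product is meaningful; comparisons across datasets should use R and bD/R².
- Bouquet calling on ideal spheres ignores envelope deformations and treats
  detection completeness as given; the per-stage detected-telomere averages
  (19/20/16 for zygotene/pachytene/diplotene) are packaged as constants for
  report generation only.
- The linker reproduces merge/split bookkeeping but no appearance model, so
  tracks may switch identity when unrelated spots cross within the gate —
  inherent to indistinguishable centromeres.
- Windowed (short-interval) coordination analysis is deliberately not
  implemented; the lag-0 Kendall tau summarizes a whole track pair.
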