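# Methods

## Face-space

The face-space is spanned by 11 inter-landmark distances `d_0 .. d_10`
over 18 landmarks (4 midline: top, nose end, mouth centre, chin; 7
bilateral pairs). `d_1..d_4` are the vertical segments top→eye line,
eye line→nose end, nose end→mouth line, mouth line→chin; they partition
the face height, hence the normalization constraint `h = Σ_{i=1..4} d_i
= 1` that absorbs overall scale and makes every coordinate a proportion
of the facial length. `d_0` is the vertical eye-line→zygomatic offset
and `d_5..d_10` are the six bilateral widths (face, inter-eye, mouth,
eye, nose, jaw). The schema (landmark roster, pairings, bounds) is a
data object — an alternative pairing is a configuration change, not a
code change.

**Frame convention.** In the face frame, x points rightward from the
midline and y *downward* from the top landmark (image convention): a
"higher" feature has a smaller y. Correlation signs must be read with
this in mind.

**Cartesian chart (14 → 10).** The constrained space is
10-dimensional. Its Cartesian chart uses 7 landmarks: nose end
(midline) plus the six left-side lateral landmarks (zygomatic, eye
centre, eye outer corner, nose wing, mouth corner, jaw). Each of the
six horizontal widths needs one lateral x, so at most one midline
landmark can contribute — the four omitted coordinates are the nose-end
x (midline), and the eye-outer / nose-wing / jaw y's (tied to the eye,
nose and jaw lines). The resulting map distances↔coordinates is a
bijection (tested by random round trips at 1e-12).

**Constraint projection.** After arbitrary arithmetic (initialization,
DE mutation), vectors are made feasible by rescaling the four
constraint coordinates by 1/h — preserving their proportions — then
clamping to bounds, iterating (≤100 times) until the clamp is a no-op.
The map is idempotent and exact to machine precision. Default bounds
are ±50 % of the reference values; anything wider stops looking like a
face.

## Image deformation

Warps are moving-least-squares with weights `w_α = |p_α − v|^(−2α)`
(α = 1 by default) and the local transform restricted to the
*similarity class*: for each evaluation point the rotation+uniform-scale
matrix `[[a, −b], [b, a]]` minimizing the weighted control-point
residual has the closed form `a = Σ w (p̂·q̂)/μ_s`,
`b = Σ w (p̂⊥·q̂)/μ_s`, `μ_s = Σ w |p̂|²`. MLS is exact on global
similarities (tested to 1e-9 px). The map is evaluated only at the
vertices of a ≤15 px grid; each cell is split along the top-left→
bottom-right diagonal and each destination triangle is filled by
inverse-affine bilinear sampling (hole-free, intensity-range
preserving, deterministic). Destination pixels outside the mapped mesh
are filled with the nearest covered value. Rendering a face anchors
the face frame on the reference portrait's top→chin length and midline.

## Sculpting engine

DE/rand/1/bin with the standard study conditions N = 28, T = 10,
μ = 0.15, ρ = 1. Partners a, b, c are drawn without replacement
excluding the target; with ρ = 1 the trial vector is the full projected
mutant, and with ρ < 1 one uniformly chosen coordinate is always taken
from the mutant. Presentation sides are randomized; choosers are
side-blind by contract. Deterministic simulated choosers break exact
ties in favour of the first option shown. The renderer is optional in
the loop: simulated subjects act on vectors directly, so large
simulation studies skip imaging.

**Choice model.** A simulated subject holds an attractor f\* and picks
option a over b with probability
`σ(β·(d_b − d_a)/(d_a + d_b))`, where d_x is the metric distance of x
to f\*. The *relative* (Weber-fraction) form makes β dimensionless and
the chooser invariant to the face-space's overall distance scale;
β = 0 reduces to the uniformly random null model and β → ∞ to greedy
nearest-to-attractor choice. β = 6 is the default: choices near the
attractor stay noisy while gross differences are picked reliably.

**Known dynamics.** At these parameters the engine is in a slow-search
regime. Two quantitative facts, established by the test battery:

* selection (β = 6) contracts the intra-population distance from
  ≈0.134 to ≈0.050 over 10 generations and moves the population
  centroid toward the attractor;
* *neutral drift*: with purely random choices the intra-population
  distance still contracts by ≈2 %/generation (≈0.134 → 0.110),
  because each slot is replaced with probability ½ by a mutant cloned
  off a random member and the resulting coalescence (~1/N per
  generation) slightly exceeds the mutation-noise expansion (2μ² per
  mutant). The null is therefore *nearly* flat relative to selection
  (a 4.4 σ drop versus 15.3 σ), but not statistically flat over many
  seeds. Flatness would require μ ≳ 0.19.

Per-coordinate convergence is heterogeneous: Euclidean choice
distances are dominated by wide-range coordinates (face width, jaw
width), so attractor structure on narrow coordinates (eye width, mouth
width) is transmitted only partially within T = 10 generations. This
matters when planting correlations (below).

## Metrics

`euclidean` is the per-coordinate RMS ‖u−v‖₂/√D (the alternative
‖·‖₂/D normalization is a config switch). `mahalanobis` pseudo-inverts
the covariance on its top-k eigenspace (default k = 7, the most varying
directions — the low-variance directions are dominated by noise).
`angle` is the angle between standardized fluctuation vectors,
optionally truncated to the top-k PCs. `byatt_rhodes` is implemented as
the angle in the whitened (Mahalanobis) frame — a clearly-labelled
fallback for the norm-based identity metric of the face-perception
literature, swappable through the metric name in `MetricContext`. Population comparisons
use the mean cross-pair distance (a *pseudo*-distance:
pseudo(P,P) = intra(P)·(N−1)/N > 0); centroid-to-centroid is available
as an alternative.

## Statistics

* **Separation**: t = (μ_i − μ_sc)/√(σ_i² + σ_sc²) with sample sds
  (n−1); under Gaussian histograms the overlap probability is
  p₁₂ = Φ(t). The empirical p₁₂ is exhaustive when |same|·|diff| ≤ 10⁶
  and seeded Monte-Carlo beyond (ties count ½).
* **Bootstrap correlations**: one population vector drawn uniformly
  per subject per realization — removing within-attractor correlations
  — re-standardized within the realization; element-wise mean, sd and a
  two-sided p from z = mean/sd are reported, plus the empirical
  sign-flip fraction. The bootstrap resamples member indices with the
  cohort held fixed, so its p-values do not include cohort-level
  sampling noise and run mildly anti-conservative on null pairs.
* **Group tests**: Welch's t by default (pooled-variance Student
  available); subjects, not vectors, are the sampling units (one
  subject-mean vector each), standardized with the *pooled* mean/sd of
  both groups so genuine location shifts survive. No multiple-testing
  correction by default; Benjamini–Hochberg via flag.
* **PCA**: eigenvalues ascending (the most varying component is the
  last), deterministic sign convention (largest-magnitude entry
  positive). On raw distance vectors the constraint produces one exact
  zero eigenvalue whose eigenvector weights d_1..d_4 equally — a useful
  self-check, verified in the tests.

## Synthetic cohorts

The generator emulates the statistical structure of a sculpting study:
attractors drawn from a multivariate Gaussian around the schema
reference and projected to the constraint, two balanced gender-like
groups with an optional mean offset, logistic choosers, m replicate
runs per subject, and tagged conditions whose attractors are shifted on
designated coordinates (emulating a change of reference portrait while
leaving "robust" coordinates untouched).

Defaults, chosen once: attractor sd_i = 0.25·reference_i —
proportional, so wide coordinates vary more, as anatomy does, and the
spread is comparable to the plausible (±50 %) range. Against the
engine's per-coordinate run noise at T = 10 (≈0.045 facial lengths)
this reproduces the qualitative regime of real sculpting data: the
ordering intra < self-consistency < inter-subject holds with clear
separation (p₁₂ ≈ 0.82 in the README's worked example). Planted
correlations for recovery studies are placed on the wide coordinate
pair (d_5, d_10) (face/jaw width) because narrow coordinates
under-transmit at T = 10 (see above); that pair is also the
scientifically expected one — wider faces go with wider jaws.

The portrait fixture is a deterministic cartoon face (shaded ellipse
head, eyes, nose, mouth, jaw line at the schema's reference landmark
positions, plus a low-amplitude smooth texture so warps are detectable
everywhere), with optional burned-in fiducial dots for warp round-trip
tests.

**What passing tests do not show.** The synthetic chooser is
stationary, noiseless in criterion (no drift over sessions), and its
attractor is exactly representable in the face-space; real subjects
drift, fatigue, and judge texture as well as geometry. Image-free
simulation also bypasses any rendering-induced perceptual effects.
Recovery results therefore validate the machinery, not human
behaviour.

## Problem sizes and numerics

Simulation studies in the test battery use S = 20–60 subjects, m = 1–3
replicates, and the standard engine (N = 28, T = 10); warp tests use a
150×200 px fixture with an 8–15 px grid. Constraint feasibility is
exact to machine precision; round-trip identities are asserted at
1e-12, MLS exactness at 1e-9 px, rasterized fiducial accuracy at 1 px.
Degenerate inputs (collinear control points, zero face height,
zero-variance coordinates, singleton populations, infeasible bounds)
raise `ValueError` with a named cause.
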