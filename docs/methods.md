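# Methods

This note describes the models and numerical procedures implemented in
`ryrflux`, the choices made where several designs were defensible, and what
the synthetic-data tests do and do not establish about real data.

## Data model and reduction

A MINFLUX DNA-PAINT acquisition yields a table of raw localizations, each
carrying a trace ID (TID) that groups the repeated localizations of one
continuous imager binding event.  All coordinates are nm in a right-handed
frame with z up.

The reduction is two-level:

1. **Traces to sites.**  All localizations of a TID are collapsed to their
   unweighted per-axis mean (`combine_traces`); this is the maximum-likelihood
   position under isotropic Gaussian error.  The per-axis sample standard
   deviation is kept as a spread estimate (0 for singleton traces), and
   `precision_summary` reports the per-axis median spread over traces with at
   least two localizations.  No trace-length filter is applied by default
   (`min_locs = 1`).
2. **Sites to subunits.**  A marker can be visited by several imagers over the
   acquisition, producing multiple sites within about a nanometre.  DBSCAN
   with `eps = 1 nm` and `min_pts = 1` — exactly the connected components of
   the 1 nm adjacency graph — merges these; each component collapses to its
   localization-count-weighted mean.  With the visit statistics observed in
   practice (mean close to 1, see below) this merge is nearly the identity.

Note a deliberate property of the synthetic pipeline: when each visit yields a
single raw localization, repeat visits of the same site produce sites a few
localization errors apart, which a 1 nm merge radius does not join.  The
subunit count then carries the same mild visit-multiplicity inflation
(~ mean visit count) that the real reduction carries; the visit-rate assay
below quantifies it.

## Synthetic data generators

The generators produce the study conditions used by every recovery test.

**NPC fields.**  Each nuclear pore contributes 32 tag sites: two parallel
8-fold rings (ring diameter 107 nm, axial spacing 50 nm, the established
Nup96 geometry), two sites per segment placed at ±6° along the ring (~11 nm
apart at the default radius).  Poses are random: azimuth and spin uniform on
[0°, 360°), tilt uniform on [0°, `max_tilt_deg`] (default 30°; the tilt
distribution of real pores in the curved nuclear envelope is not known, so it
is configurable).  Pores sit on a 400 nm jittered grid so that candidate
detection is not confounded by overlaps.  Each site is labeled independently
with probability `p_le`; each labeled site receives a zero-truncated Poisson
number of visits with conditional mean 1.18 (the observed regime: a detected
site is typically visited once); each visit yields a zero-truncated Poisson
number of raw localizations (default mean 1) perturbed by per-axis Gaussian
error (default σ = 2 nm per axis) with an optional uniform outlier fraction.

**Tetramer fields.**  A `ClusterLayout` places receptor centers, in-plane
angles and optional plane poses; `expand_layout_to_tag_sites` produces 4 tag
sites per receptor on the corners of a square — side 16 nm rotated 45° to the
receptor outline for the GFP tag, side 20 nm aligned with the receptor
corners for the TagRFP tag (the tilde in "~16 nm" / "~20 nm" is absorbed by a
configurable side).  `make_lattice_layout` provides close-packed ground truth
(default pitch 30 nm, matching the ~27 nm receptor footprint).  Sites are
retained with probability `p_su` and expanded to localizations as above.

What the generators do *not* emulate: photon-level localization physics,
drift and fiducial residuals, unspecific background binding (beyond the
uniform outlier fraction), chromatic or depth-dependent aberrations, and the
irregular, curved cluster morphologies of real ER membranes.  Passing
recovery tests therefore demonstrate correctness of the estimators under the
stated noise model, not robustness to every systematic error of a microscope.

## NPC labeling-efficiency assay

**Candidate detection** groups subunit locations with DBSCAN
(`group_eps = 100 nm`, `min_samples = 1`), discarding groups with fewer than
5 points or a bounding-box diagonal above 250 nm.  The 100 nm radius bridges
up to three consecutive unlabeled segment columns (98.9 nm chord at diameter
107 nm) without linking neighbouring pores at realistic pore spacings.
External ROI JSON (boxes or seed points) can replace auto-detection.

**Template fit.**  For each candidate the rigid double-ring template is fitted
by maximum likelihood: each point is modelled as drawn from an isotropic
Gaussian (σ = 3 nm) centered at its nearest template *tag site* (the 32
site-level positions, not the 16 segment anchors — using segment anchors
creates spurious in-plane-rotation optima because the two sites of a segment
sit ~5.6 nm off the anchor), mixed with a uniform outlier component (weight
0.1 over a 300 nm box).  Free parameters are the center (3), the symmetry
axis (2; sign fixed to non-negative z, which is not identifiable from
geometry), and the in-plane rotation (1); diameter and ring spacing are fixed
to the template unless `free_geometry` is set, which stabilises sparsely
labeled pores.  The search is deterministic: a grid of starts
(tilt × azimuth × in-plane = 15° × 30° × 5.625°) is scored with a broadened
Gaussian (2σ) after two ICP-style center re-alignment sweeps per start, and
the three best starts are polished with Nelder–Mead.  On synthetic fields at
p ∈ {0.4, 0.5, 0.6} this recovers the pose to a median axis error below 1.5°
with 97–100 % exact segment counts.

**Segment counting** assigns each point to its nearest segment anchor in the
fitted frame; a segment is labeled if it received at least one point within
`tol = 15 nm` (safely below half the 40.9 nm inter-anchor chord).
Cytoplasmic and nucleoplasmic rings are counted separately and concatenated.

**Efficiency model.**  With `s = 2` independent sites per segment, a segment
is labeled with probability q = 1 − (1 − p)², so the number k of labeled
segments among m = 16 follows Binomial(m, q).  Pores with no labeled segment
are undetectable, so the law is left-truncated at `kmin = 1` by default
(configurable); the estimate p̂ maximises the truncated multinomial
log-likelihood of the pooled histogram (0.001 grid then bounded scalar
minimisation), with the standard error taken from the numerical curvature of
the profile log-likelihood (nonparametric bootstrap over pores as fallback).
The estimator is exact to 1e-3 on expected histograms, and the full
generator → reduction → assay chain recovers p to within ±0.03 at 150 pores.
Note that what p_LE measures is the *product* of chemical labeling and
photo-detection probability per site; the assay cannot separate the factors.

**Geometry and visit rate.**  With `free_geometry`, per-pore fitted spacing
and diameter are summarised by their median with a bootstrap standard error.
The visit rate divides the mean trace count of labeled segments by the
expected number of labeled sites per labeled segment, s·p/(1 − (1 − p)^s)
given an efficiency estimate (it reduces to the conventional "divide by s"
at complete labeling; without the correction the rate is biased low whenever
p < 1).

## Functional cluster analysis

Receptors coupled by calcium-induced calcium release are grouped with DBSCAN
at `eps = 100 nm` (the fire-diffuse-fire distance from diffusion modelling)
and `min_pts = 1`, so isolated subunits form genuine singleton clusters and
the partition equals the 100 nm connected components.  Cluster sizes are
counted in subunits; the efficiency correction divides by p_LE and the
conversion to receptor counts divides by 4.  "Large" clusters hold at least
50 subunits (≥ 12.5 receptors at the default threshold).  Report-time
rounding is to one decimal, half away from zero.  Whether the correction
should use a per-dataset or a pooled efficiency estimate is left to the
caller — both are plain arguments.

## Tetramer orientation fitting

Given 3 or 4 candidate subunit positions (pairwise distances below 40 nm,
largest triangle area at least 1 nm² to exclude degenerate configurations),
the fit enumerates all injective assignments of points to template corners
(24 or 4!/(4−3)! = 24 candidates) and solves each by closed-form Kabsch
superposition restricted to proper rotations; the assignment with the
smallest rmsd wins.  For 3 points the position of the missing corner is
predicted.  Because the four corners are unlabeled and coplanar, the
orientation is identifiable only modulo the proper symmetry group of the
square — order 8 (the four in-plane rotations plus four 180° flips), computed
numerically from the template — and all angular-error metrics minimise over
that group.

The noise benchmark perturbs corners with a 3D localization error of
magnitude 3 nm, i.e. σ = 3/√3 nm per axis, matching a total 3D error budget
of 3–4 nm with per-axis precision near 2 nm.  Under that condition the median
symmetry-reduced angular error is below 10°; with 3 nm *per axis* the
rotational information content of four points 11.3 nm from center caps the
achievable median near 15°, independent of the estimator.

The counting algebra links the per-subunit efficiency p to receptor
detection: P(detect) = 1 − (1 − p)⁴ (≈ 94 % at p = 0.512), the number of
labeled subunits of a detected receptor is zero-truncated Binomial(4, p), and
`estimate_ple_from_subunit_counts` inverts observed count fractions by
maximum likelihood — the in-situ alternative to the pore-based calibration.
A greedy mutual-nearest-neighbour candidate proposer is included but marked
experimental: in densely stained data the assignment of subunits to receptors
is ambiguous, and automatic proposals must be reviewed.

## Rendering and puncta analysis

`render_2d` bins points on a pixel grid and convolves with a unit-integral
Gaussian (default σ = 4 nm), so the image integral equals the point count;
this Gaussian rendering stands in for both rendering dialects (the jittered
triangulation used for widefield data is implementation-specific, and only
the puncta positions are consumed downstream).  `find_puncta` pre-blurs with
a Gaussian of `blur_size = 2` pixels, thresholds at `threshold = 1` robust
(MAD-based) background standard deviations above the background median —
the original object finder applies a comparable SNR threshold whose exact
background model is not documented; the choice only matters at low SNR —
labels connected components and returns intensity-weighted centroids.
Nearest-neighbour distances use a KD-tree and match brute force exactly;
group comparisons use one-way ANOVA plus Tukey HSD on all pairs.

The resolution-ordering experiment renders the *same* half-labeled lattice
(p_SU = 0.5, σ = 3 nm) at high resolution (3 nm pixels, σ_render = 4 nm) and
with a widefield-like blur (5 nm pixels, σ_render = 10 nm): the high-
resolution branch must give a smaller median puncta NN distance.  Only this
ordering is asserted — the absolute published medians depend on real and
EM-traced cluster morphologies that are not reproduced here.

## Problem sizes and numerical conventions

Recovery studies use 150 pores per ensemble and 20 ensembles (the scale at
which the binomial sampling error of p̂ is ≈ 0.012, so a ±0.03 criterion is a
2.5 σ test), 100 seeds for the tetramer benchmark, and a 50 × 50 lattice
(2500 receptors) for the puncta comparison, chosen so a full run completes in
minutes on one core.  All randomness flows through
`numpy.random.Generator` seeded per run; identical configuration and seed
give bit-identical outputs.  Ties in the template-fit multi-start are broken
by grid order; the truncated-binomial boundary case (all pores fully labeled)
returns p̂ = 1 with a zero standard error and an explicit boundary flag.

## Known limitations

* The template fit assumes the nominal 8-fold double-ring geometry;
  structural plasticity of real pores enters only through the free-geometry
  diameter/spacing parameters, not through ring ellipticity or segment
  displacement.
* Refractive-index z-rescaling, a known cross-study confounder of the ring
  spacing, is out of scope; fitted spacings are in the instrument's frame.
* The candidate proposer for tetramer fitting does not resolve dense regions;
  candidate selection there is ROI-driven by design.
* The blob finder's background model is a global robust estimate; strongly
  non-uniform backgrounds would need a local model.
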