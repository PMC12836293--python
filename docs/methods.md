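# Methods

This note documents the models implemented in `csieval`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the package's known limitations.

## Dose model and DVH

Dose grids are regular 3-D arrays in Gy with per-axis spacing and origin;
axes are ordered (x = left–right, y = anterior–posterior, z =
superior–inferior) with voxel centers at `origin + index·spacing`.
Structures are boolean voxel sets under voxel-center-in-region semantics;
volumes are whole-voxel counts times the voxel volume, with no
partial-volume weighting (a documented approximation that matters only for
structures a few voxels across).

The cumulative DVH is **bin-free**: the sorted vector of in-structure voxel
doses is the primary representation, and every D_x% query is a linear
interpolation between sorted voxel doses (numpy's linear quantile). D_x% is
read at the high-dose end — the smallest dose received by the hottest x% of
the volume, the standard ICRU convention. D_x cc converts the absolute
volume to a percentage of the structure volume first; V_xGy is the fraction
of voxels at or above x Gy. This removes the binning tolerance entirely:
uniform-dose and scaling identities hold exactly, which the unit tests
exploit. Ties between equal voxel doses are broken by a stable sort; this
cannot affect any metric but fixes the representation bit-for-bit.

The homogeneity index is (D_2% − D_98%)/D_50%, the Paddick conformity index
is V_t,ref²/(V_t·V_ref); both are plain arithmetic on the caller's volumes
so they compose with any isodose definition.

## Radiobiological models

All models are forward evaluations; no fitting is performed.

* **EQD2** — linear-quadratic conversion `D·(d + α/β)/(2 + α/β)` with
  d = D/n_fractions. A schedule at exactly 2 Gy/fraction is a fixed point
  for any α/β. Cross-checked in tests against per-fraction BED summation.
* **gEUD** — the power mean `(Σ vᵢ Dᵢ^{1/n})^n` over the differential DVH
  (equal per-voxel weights). Computed in ratio space against the maximum
  dose for numerical stability at small n; n = 1 is the mean exactly, and
  the n → 0⁺ limit of a finite sample is `D_max·(1/N)^n`, so "approaches
  the maximum" holds at rates governed by ln N.
* **LKB probit** — Φ((D_eff − TD50)/(m·TD50)) via the error function; no
  tables, no quadrature. A trapezoid integration of the Gaussian integrand
  serves as the in-test oracle at 10⁻⁶.
* **Hippocampus** (neurocognitive impairment): LKB on the EQD2 of the
  hippocampal D40%, defaults TD50 = 14.88 Gy, m = 0.54, α/β = 2 Gy.
* **Scalp** (acute grade-2 alopecia): LKB on gEUD with n = 0.14,
  TD50 = 22 Gy, m = 0.54.
* **Hypothalamic–pituitary axis** (endocrine dysfunction): with dose = the
  mean of the hypothalamic and pituitary D50%,
  φ = exp(−(const + β_age·age + β_age²·age² + β_dose·dose)) and
  NTCP = 1 − 1/(1 + (φ·t)^{1/γ}); defaults γ = 0.56, const = 3.13,
  β_age = −0.106, β_age² = 0.007, β_dose = −0.049, t = 5 years. Age is age
  at treatment in years (continuous); t = 0 gives NTCP = 0.
* **Cochlea** (hearing loss): logistic in the median cochlear dose with
  b₀ = −5.3, b₁ = 0.085.
* **Tumor EUD/TCP**: EUD is gEUD with tumor exponent a (n = 1/a); TCP uses
  the logistic form 1/(1 + (TCD50/EUD)^{4γ₅₀}). The tumor parameters are
  deliberately **not** defaulted — they vary by histology and protocol — and
  must be supplied by configuration; a missing parameter raises an error
  that says so.

Parameter sets ship in `src/csieval/data/ntcp_params.yaml`, a YAML registry
keyed by organ, overridable per call or per file.

A caveat on cohort reporting: evaluating an NTCP model at cohort-mean
inputs is not the same as averaging per-patient NTCPs; over typical cohort
spreads the probit's mild nonlinearity moves the value by a few tenths of a
percentage point. The pipeline computes per-patient values and aggregates;
the closed-form acceptance quantities use cohort-mean inputs, and the
tolerance in the tests (≤ 0.5 pp) absorbs the difference.

## Robustness

Thirty rigid scenarios: ±2, ±3, ±5 mm translations on each of the three
axes (18) and ±1°, ±2° of pitch, yaw and roll (12), grouped by magnitude
(six scenarios per group). The perturbed dose is the static grid rigidly
resampled (trilinear) relative to the structure frame — the standard
isocenter-shift surrogate for a planning-system recomputation. This ignores
surface-curvature and path-length changes; it captures exactly the
geometric miss that dominates steep-gradient structures, which is the
effect the λ index is designed to rank.

Conventions, all overridable: rotations are intrinsic, applied
roll→pitch→yaw about the grid center (standing in for the cranial
isocenter); pitch is about the LR axis, yaw about AP, roll about SI.
Voxels sampling outside the grid take the nearest-edge value (zero-fill
would fabricate cold spots at the couch edge); the fraction of out-of-field
samples inside each evaluated structure is reported and flagged above 5%.

λ = (best − worst)/nominal × 100% with the extremes taken **within one
magnitude group**, nominal excluded; an `across_all` flag computes the
single-band alternative. The evaluated indices follow the clinical mapping:
D95% for the target, D40% for the hippocampus, D50% for the HPA structures,
cochlea and scalp.

## Plan complexity

A control point's aperture is jaw-clipped first; a leaf pair is closed when
its gap is ≤ 1 mm (the practical minimum of 5-mm-leaf MLCs; both
thresholds configurable). The aperture of a run of consecutive open pairs
is a staircase polygon whose perimeter is `gap_first + gap_last +
2·width·n_pairs + Σ(|Δleft| + |Δright|)`.

* **PI**: aperture irregularity AI = perimeter²/(4π·area), computed per
  connected component and area-weighted (avoids perimeter/area cross-talk
  between disjoint islands), then MU-weighted over CPs and beams. A square
  scores 4/π. Note that under the staircase perimeter a rasterized disc
  tends to AI = 16/π² ≈ 1.62, not 1: the staircase perimeter of a smooth
  convex shape converges to the Manhattan length (8r for a disc), which is
  the correct behaviour for an MLC aperture, not a discretization error.
* **MCS**: per CP, the leaf-sequence variability LSV (product of the two
  banks, computed over that CP's open leaves, defined as 1 for a
  single-leaf or perfectly aligned bank) times the aperture-area
  variability AAV (area over the aperture formed by each pair's maximal
  openings across the beam), combined over adjacent CP pairs with
  mean-segment-MU weights. A static field open to its own maximum scores
  exactly 1; lower is more modulated.
* **SAS10**: MU-weighted fraction of open pairs with gap < 10 mm.
* **MFA / MLG**: MU-weighted mean aperture area (cm²) and mean open-pair
  gap (cm).
* **MLT**: per beam, the total |position change| accumulated over CPs,
  averaged over all leaves (cm). At group/plan scope all per-beam metrics
  are MU-weighted means (MLT aggregation is a documented choice; a
  summed-travel variant is trivially available from the per-beam table),
  while MU and CP counts are summed.

Leaf width defaults to 5 mm at isocenter; configurable for other MLCs.

## Gamma analysis

Global normalization to the reference maximum; points below 10% of that
maximum are excluded (both conventional defaults, configurable). For each
evaluated reference point, γ is minimized over a lattice of offsets with
step DTA/10 out to a radius of 3·DTA, sampling the evaluated distribution
by linear interpolation. Offsets are visited nearest-first with a global
early exit once the geometric term alone exceeds the worst running minimum,
which makes the search deterministic with bounded discretization error
(≤ the lattice step in the distance term). Gamma is asymmetric in its
arguments by construction; both directions are computable. One behavioural
consequence worth knowing: on a grid whose spacing is small relative to the
DTA, an isolated one-voxel dose spike in the evaluated distribution is
*rescued* by correctly dosed neighbours within the DTA and passes — this is
a property of the gamma definition, not of the implementation.

## The synthetic phantom generator

The generator exists so every pipeline stage has inputs with the right
statistical structure. It emulates:

* geometry — an 80 mm-radius head with a 5 mm scalp shell, paired
  hippocampi (~2–4 cc), hypothalamus, pituitary and paired cochleae inside
  the cranial target; a spinal target cylinder and a vertebral slab
  abutting it anteriorly; small per-seed center jitter for inter-patient
  variation. Default grid 2 mm isotropic, 100×100×250 voxels, chosen to
  keep a full robustness study at desk scale; most tests use 4 mm.
* dose — 23.4 Gy in 13 fractions. The base field is the prescription inside
  the target union dilated by 12 mm (2× the 6 mm penumbra sigma, so the
  Gaussian penumbra cannot erode target coverage), Gaussian-blurred, plus
  0.05 Gy noise. A linear anterior–posterior ramp inside the vertebrae
  imposes the configured D2%−D98% spread (4.7 Gy functional-sparing,
  8.7 Gy standard); with whole-voxel levels the spread of a linear ramp
  equals its full span, which is how the ramp is calibrated.
* avoidance dips — subtractive wells whose kernel is the Gaussian-blurred
  structure indicator normalized to unit peak. Because every structure's
  mean dose is *linear* in the well amplitudes, the amplitudes solve a
  small exact linear system over all avoidance structures simultaneously
  (neighbouring wells — hippocampus, hypothalamus, pituitary — couple);
  dose is clipped at zero afterwards. Defaults steer the hippocampus to
  12.4 Gy, hypothalamus 14.7, pituitary 15.4 and cochlea 21.4 Gy.
* plans — VMAT-like control-point sequences where a single per-seed jitter
  field is *scaled* by the modulation level, and a modulation-proportional
  number of leaf pairs per CP is forced to a 5 mm gap. This makes
  PI/SAS10/MLT non-decreasing and MCS non-increasing in the modulation
  level at fixed seed by construction, which is the property the
  complexity tests need. Bank ordering and a 50 mm per-CP travel limit are
  enforced.
* logs — planned values plus zero-mean Gaussian noise per leaf and per CP.

What it does **not** emulate, and hence what passing tests do not show
about real data: no CT/heterogeneity or beam transport physics (the dose is
a constructed field, not a transport solution); no surface build-up, so the
scalp sits at penumbra-attenuated levels rather than clinical build-up
doses — consequently the scalp carries no avoidance well (a subtractive
well on a 5 mm surface shell would necessarily dig into the cranial target
rim and violate the D95 ≥ 95% coverage the recipe guarantees); no field
junctions or arc geometry in the dose; plan control points are statistical
surrogates, not optimizer output, so complexity *magnitudes* are not
clinical, only orderings are; the delivered-dose surrogate for the QA layer
applies a log-scaled rigid shift plus a smooth perturbation rather than
re-computing dose from logged apertures. Cohort-scale numeric tables from
clinical studies are therefore reproduced structurally (same metrics, same
directions of effect), not numerically.

## Numerical and degenerate-input choices

* DVH of an empty mask, shape mismatches, D_cc beyond the structure volume,
  zero D50 in HI, zero denominators in CI, nominal = 0 in λ, crossed leaf
  banks, CP-count mismatches in log comparison: all raise `ValueError`
  naming the offending quantity; nothing is silently skipped. Goal sheets
  list missing structures as not-evaluated rows.
* All-zero paired differences in the cohort comparison return p = 1 with a
  `degenerate` flag instead of NaN.
* Random number use is confined to explicitly passed
  `numpy.random.Generator` objects; identical seeds reproduce phantoms,
  doses, plans, logs and pipeline CSVs byte-for-byte.
* The pipeline's demo cohort uses 2 patients at 4–5 mm grids; the
  acceptance-grade checks run the 2 mm default phantom. Problem sizes are
  stated in the tests and examples themselves.

## Interchange formats

Text-first formats so that fixtures are generated, not stored: dose grids
as a JSON header plus C-order little-endian raw array; masks as
run-length-encoded JSON; plans as a JSON control-point schema; logs as CSV
(one row per beam/CP/leaf pair). DICOM import/export is intentionally out
of scope for this version; the interchange formats cover every pipeline
path and round-trip losslessly (dose to float32).
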