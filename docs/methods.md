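# Methods

## Dose model

The package estimates skin dose for fluoroscopically guided interventions
on a per-irradiation-event basis. Each event contributes, to every skin
point its collimated field covers,

D_skin = K_a,r · β · (d_ref/d_skin)² · BSF(HVL, field side) ·
(μen/ρ)_tissue/air · AF,

and nothing to points outside the field. The model's assumptions:

- **Primary beam only.** No scatter from adjacent fields, no collimator
  penumbra, no skin-depth gradient. Dosimeters therefore systematically
  read *above* the map near and outside field edges; the comparison code
  flags map-zero/reading-nonzero points as `scatter_only` instead of
  treating them as errors.
- **Point evaluation at grid centers.** `d_skin` is the source-to-grid-point
  distance, not a ray/surface intersection; with the 1.5 cm dosimeter pitch
  the difference is negligible against the inverse-square scale (~60–80 cm).
- **Narrow-beam slab attenuation.** Table and pad are uniform horizontal
  slabs; transmission is kerma-weighted Beer–Lambert with oblique path
  thickness/cos θ and no buildup factor.
- **Multiplicative separability.** BSF, the μen/ρ ratio, and AF are
  evaluated independently; the cross terms (backscatter hardening under the
  pad, for instance) are absorbed into whichever correction-factor tables a
  site supplies.

## Geometry conventions

Patient frame: +x patient-left, +y anterior, +z cranial. The phantom is a
32-cm-diameter, 17.5-cm tissue cylinder; the irradiated flat face lies in
the y = 0 plane with the dosimeter lattice (1.5-cm pitch, row-major (i, j)
indexing, 0-based) facing the under-table source. At gantry (0, 0) the
source is at (0, −sod, 0) aiming +y; the primary gantry angle rotates about
+z, the secondary about +x, both right-handed. Table offsets
(lateral, height, longitudinal) move the patient; the beam is translated by
the negated offset in the phantom frame. The field is a rectangular pyramid
with tan(half-angle) = (field side/2)/sod; the collimation boundary is
inclusive, and grazing incidence (normal · ray = 0) is classified
out-of-field.

## Beam-quality machinery

The default spectrum is a Kramers-form bremsstrahlung model on a 1-keV grid
from 10 keV to the tube potential, hardened by 2.5 mm Al inherent
filtration (a typical C-arm port), with no characteristic lines; any object
satisfying the `EnergySpectrum` contract can replace it, and none of the
validation arithmetic depends on the spectral shape. Photon coefficients
(μ/ρ, μen/ρ for Al, Cu, air, water-equivalent soft tissue, carbon-fibre
composite, low-density foam) are bundled on the standard 10–150 keV grid
and interpolated log-log; queries outside the grid raise rather than
extrapolate. Soft tissue uses water cross sections at 1.06 g/cm³ — within a
couple of percent of average soft tissue over this range.

HVL is the aluminium thickness halving the air-kerma-weighted narrow-beam
transmission, found by bracketed Brent root search on [0, 30] mm to
10⁻³ mm. HVL-matching bisects added aluminium until the bracket is below
10⁻³ mm and verifies the matched HVL within 0.01 mm. For the nine bundled
beam qualities ({50, 80, 100} kVp × {0, 0.2, 0.6} mm Cu) the model gives
HVLs from ≈1.5 to ≈8.8 mm Al; at 80 kVp/0.2 mm Cu it is ≈5.0 mm Al. These
depend on the spectrum backend and are treated as sanity bands, not
reference values.

## Parameters and defaults

| Parameter | Default | Why |
|---|---|---|
| β (KAP calibration) | 1.0 | site-specific; never published for the benchmarked unit; scalar or keyed by (kVp, mm Cu) |
| inherent filtration | 2.5 mm Al | IEC minimum total filtration for this class of tube |
| sod / d_ref | 75 / 60 cm | typical C-arm isocenter distance; entrance reference point 15 cm toward the source |
| table slab | 1.5 mm Al-equivalent, 10 cm below face | common tabletop equivalence; fully configurable (YAML) |
| pad slab | 70 mm foam at 0.03 g/cm³ | typical mattress pad |
| BSF table | bundled HVL × field-side grid (1.15–1.56) | editable package data shaped like published water BSF compilations; bilinear interpolation, out-of-hull errors |
| grid | r = 16 cm, pitch 1.5 cm | the benchmark phantom's dosimeter lattice |

Out-of-hull table lookups always raise (`ExtrapolationError`): silent
clamping is the classic dosimetry failure mode.

## Correction-factor algebra

`CF_measured = D_IC,air/D_OSL,air` converts OSLD readings into the
ion-chamber domain the dose map is calibrated to; `CF_montecarlo =
F6(geometry)/F6(air)` predicts on-phantom response from free-in-air
response and, algebraically, packs BSF · (μen/ρ) · AF of the dose product
into one factor — an identity the tests verify against the engine exactly.
Tally values, free-in-air doses and CF tables are *inputs* (CSV); tallies
with relative error ≥ 5% are rejected. Angle-dependent CFs are characterised
at 0/30/60° and linearly interpolated between (clamped outside, since no
other angles were characterised).

## Validation arithmetic

Percent error is 100·(predicted − measured)/measured — denominator fixed by
fitting the bundled benchmark rows, whose printed measured/predicted doses
and percent errors ship as package data. Report rounding is
half-away-from-zero to one decimal, applied only at presentation; summaries
(min/max/mean/mean-absolute) use unrounded values. Recomputing every
benchmark row from its printed doses reproduces 10 of the 27
constant-angle rows exactly at one decimal; the rest agree within the
precision the 0.05-mGy printed dose rounding can support (for the ~1.6-mGy
rows that rounding alone permits several percentage points of slack, which
the tests bound by explicit error propagation rather than a fixed
tolerance). The recomputed range over the three constant-angle tables is
−16.2% to +3.2% with mean ≈ −6.3%.

The modular-alignment check formalises when point-by-point map/dosimeter
agreement can even be expected: a field displacement that is an exact
multiple of the 1.5-cm lattice pitch (6 cm → remainder 0) lands field
centers on dosimeter centers; 4 cm (remainder 1.0 cm) cannot.

## Synthetic scenarios

`ripsa.fixtures` fabricates the six benchmark-shaped scenarios
(`table2/3/4_grid`, `table5_angles`, `fig7_two_fields`, `fig8_two_fields`)
with per-quality reference air kerma sized to the published measured doses.
The fig7 pattern (6-cm displacement, 5×5 cm² fields, bare phantom) yields
two spatially separate fields; fig8 (4-cm diagonal displacement through
table and pad) yields intersecting fields whose overlap carries the peak.
Correction factors are generated to be exactly consistent with the engine's
own BSF/μ-ratio/AF (so the loop closes), while `CF_measured` is a smooth
synthetic stand-in near 0.95–1.0 (the real detector pair was never
published).

Synthetic OSLD readings emulate two features of real data and nothing else:
a multiplicative `1 + scatter_fraction` in-field excess plus
`scatter_fraction` × brightest-neighbour dose on the one-point out-of-field
border (default 0.05 — reproduces the sign and rough size of the real
map-under-reads-dosimeter effect), and multiplicative lognormal read noise
with unit mean (default CV 0.02, an assumption; OSL repeatability for this
campaign was not reported). They do **not** emulate energy-dependent OSLD
response, fading, depletion, angular response, or heel effect — so passing
closed-loop tests demonstrates internal consistency of the pipeline, not
detector physics. All randomness flows from the single `ScenarioSpec.seed`.

## Numerical choices

- Exact, order-fixed accumulation; the cumulative map equals the ledger sum
  bit-for-bit, and peak ties resolve to the first row-major index.
- Equivalent-square field side (geometric mean of width × height at the
  entrance) keys the BSF lookup.
- Brent for HVL (tol 10⁻³ mm), bisection for filtration matching
  (bracket < 10⁻³ mm, HVL verified to 0.01 mm).
- Comparison skips points where both map and reading are zero; duplicate
  reading indices are schema errors.

## Problem sizes

The bundled scenarios and test oracles run at the benchmark's own scale
(357-point grid, ≤ 9 events per scenario, 10⁵-sample ray-tracer oracle,
10⁻⁴-mm HVL scans, 10³ random dose products), which keeps the whole suite
in tens of seconds.

## Known limitations

- No scatter, penumbra, heel effect, or patient-specific surface meshes —
  the skin lattice is the cylinder-phantom face.
- Spectrum model is semi-empirical; absolute HVLs carry model error (the
  machinery, not the spectrum, is the tested contribution).
- Coefficient tables are 10-point log grids per material; adequate for
  kerma-weighted averages, not for fine spectroscopy.
- DICOM RDSR parsing is out of scope; event logs use the documented
  JSON/CSV schema.
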