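# Methods

## Setting and model

A dried serum film's mid-IR absorbance spectrum is, to first order, a
Beer–Lambert superposition: each absorption band contributes an amplitude
proportional to the concentrations of the solutes that absorb there, on
top of contributions (film, substrate, free-OH region above ~3700 cm⁻¹)
that do not track solute concentration. `seraquant` quantifies a certified
38-analyte panel from such spectra through a single scalar composite
feature K and per-analyte scale coefficients:

    B̂ᵢ = Cᵢ · K · (1 − δ),   i = 1…38.

K is a convex combination (optionally rescaled) of monomial "ratio terms"
in band features, where a band feature is either the peak absorbance H
(AU, maximum of the preprocessed spectrum inside the band's frozen window)
or the band area S (AU·cm⁻¹, trapezoidal integral over the same window).

The calibration design is a dilution series of one stock control serum:
factors 2, 3, 5, 7 and 10, each measured in triplicate. Crucially, this
design is *lockstep* — every analyte is diluted by the same factor, so all
concentration vectors across samples are exactly proportional. A single K
can then carry all 38 analytes at once; the per-analyte information lives
entirely in the Cᵢ. This is a strength (one number calibrates a whole
panel) and the method's central limitation (see below).

## Preprocessing

Fixed order, recorded in output metadata:

1. **Replicate averaging** — pointwise mean over spectra sharing a grid.
2. **Two-point baseline** — the line through the spectrum at two anchor
   wavenumbers (defaults: first and last grid points; absorbances read at
   the nearest grid point, ties toward lower wavenumber) is subtracted.
3. **CO₂ excision** — the 2280–2400 cm⁻¹ window (atmospheric CO₂
   asymmetric stretch; the canonical window, since the calibration
   procedure names the operation but not its bounds) is replaced by the
   chord between its edges.
4. **Vector normalisation** — division by the Euclidean norm over a
   range, default the full span.

All four are linear maps of the absorbance vector (normalisation up to the
sample-dependent scalar norm), which is what makes the downstream ratio
algebra exact.

## Why ratio terms work on normalised spectra

Write a noiseless spectrum as A(ν) = d·P(ν) + Q(ν), with d the dilution
scale, P the solute part and Q the concentration-independent background.
After normalisation every analyte-band feature is d·p/‖A‖ and every
background-band feature is q/‖A‖. A monomial term with solute-degree 1 and
*total* signed degree 0 — e.g. H_analyte/H_background — is exactly
proportional to d: the unknown norm cancels. The search space (signed
integer exponents, per-feature magnitude ≤ 2, total absolute degree ≤ 5 by
default) contains many such terms, and on noiseless synthetic studies the
pipeline recovers held-out concentrations to machine precision because it
finds them. This is also why the screen must keep features of *both*
response classes: bands that fall and bands that rise with dilution after
normalisation.

## Calibration stages

**Stage 1 — feature screening.** Features need |r| ≥ 0.75 (Pearson,
against every analyte; on a lockstep design all analytes give the same r).
The loose default is deliberate: after vector normalisation a feature's
dilution response is monotone but curved, which bounds |r| well below 1
regardless of data quality — observed stage-1 correlations on real
dried-film series span roughly 0.77 to 0.999. Candidates split by
correlation sign into the two response classes; within a class they are
ranked by a replicate-derived signal-to-noise score (cross-level spread of
the averaged feature over its pooled replicate standard error) because |r|
itself, being curvature-limited, cannot distinguish clean bands from noisy
ones. Up to 8 features are kept, at least half slots offered to each
class.

**Stage 2 — term screening.** Every enumerated monomial whose sample
vector has signed r > 0.999 with every analyte is retained. The threshold
is strict here, where it belongs: exact ratio terms achieve r = 1 by
construction, and the screen's job is to discard everything that merely
trends.

**Stage 3 — weight fitting and subset choice.** Retained terms are
normalised to unit sample mean (their raw scales are arbitrary and are
absorbed by the Cᵢ, so comparisons must be scale-invariant), ranked by
residual to the unit-mean target, deduplicated, and searched exhaustively
over subsets of up to 3 terms from the top 15. For each subset, weights
solve

    min ‖Σₜ wₜ uₜ − τ‖²  s.t. w ≥ 0, Σ wₜ = 1

by a reduced-gradient active-set iteration: on the current working set the
equality-constrained problem is solved exactly through its KKT system,
infeasible steps are cut at the first blocking bound, and bound
multipliers decide re-entry — finitely convergent for this convex QP, and
checked in the tests against a 2-simplex grid search and closed-form
cases. Subsets are scored by leave-one-out prediction error plus a
delta-method estimate of the variance that feature measurement noise
propagates into K (computable because the replicate scatter estimates
each feature's standard error). The pure in-sample objective is not used
for selection: with three free weights on five samples it rewards fitting
noise, and it is blind to the noise a high-exponent term will inject into
future predictions. Both penalties vanish on noiseless data, so exact
recovery is untouched. The target τ is the reference analyte's
concentration (default: first panel entry) rescaled to unit mean — on a
lockstep design any analyte gives the same τ up to scale. The unit-mean
normalisations are folded back into the returned composite's weights and
positive `scale` field, so `CompositeFeature` can represent both a true
weighted average (scale 1) and a plain unit-weight sum of terms (equal
weights, scale = number of terms), the form the packaged reference
composite uses.

**Stage 4 — scaling and bias.** Cᵢ = Σ K·Bᵢ / Σ K² is the closed-form
minimiser of the per-analyte quadratic; no iteration. δ is one global
scalar: 1 minus the factor f minimising Σ((f·pred − true)/true)², i.e.
relative least squares, so analytes measured in large units (e.g.
cholinesterase, U/L, ~10³) do not dominate analytes near 0.3 mmol/L.
Negative estimates (net underprediction) clamp to 0; the packaged
reference calibration fixes δ = 0.054. Predictions implying
concentrations outside the panel's calibration ranges are produced but
warned about — the model is only claimed valid inside them.

## Band detection

Peaks are local maxima with a prominence threshold (pipeline default:
0.5% of the median spectrum maximum), matched across spectra within
±8 cm⁻¹ (two 4 cm⁻¹ resolution elements) and kept if present in ≥ 80% of
spectra. Windows are the flanking local minima of the mean spectrum,
frozen into the band table so every sample — including future prediction
samples — is measured identically. Indices count 1…n by ascending centre;
H is the raw window maximum of the globally baseline-corrected spectrum
(no local chord subtraction), the simplest reading consistent with the
preprocessing order.

## The synthetic study generator

Emulates the calibration experiment: 500–4000 cm⁻¹ at 4 cm⁻¹ (876
points), Gaussian bands (chosen over Voigt so band areas have closed
forms for oracle tests), amplitude = constant + Σ loading·concentration,
linear baseline drift, additive white Gaussian noise with per-(sample,
replicate) seeded substreams. The 49-band library places 15 fixed
templates at positions typical of serum films — 616 (phenyl ring), 1080,
1171, 1242 (phosphate), 1394, 1453, 1536 (amide II), 1650 (amide I, the
spectrum's maximum at 1.0 AU stock), 1717 (C=O), 2872/2920/2957 (CH),
3280 (OH/NH stretch), plus the free-OH background pair 3750 and 3903 —
and seeds fillers so the named bands land on the indices the reference
composite uses (2, 20, 42, 49). Eight bands above 3700 cm⁻¹ are
background: fixed amplitude, no concentration loadings. Band widths σ are
drawn from 4–30 cm⁻¹, capped by neighbour gaps and by distance to the
grid edges so that peaks stay resolvable and cross-talk between solute
and background regions stays below the noiseless-recovery tolerance.
Every analyte receives at least one positive loading; loadings are
normalised so a band's amplitude at stock concentration equals its
template amplitude.

Defaults are the study conditions: factors (2, 3, 5, 7, 10), triplicate,
noise 10⁻⁴ AU (clean), drift 0. The noisy-recovery experiments use
10⁻³ AU — 0.1% of the stock amide-I maximum. The held-out evaluation
predicts an unseen, in-range 4× dilution from its own triplicate.

What the generator does *not* emulate: water-vapour rotational structure,
scattering and film-thickness optics, instrument line-shape, detector
drift correlated across wavenumbers, and — most importantly — independent
biological variation of analytes. Passing the recovery tests therefore
shows the pipeline is correct and noise-stable *under the calibration
design's assumptions*, not that the accuracy transfers to real sera.

## Numerical choices

- Anchor/boundary lookups use nearest grid point, ties toward lower
  wavenumber; band windows snap to grid points.
- Weight solver: KKT systems via least squares (min-norm on degeneracy);
  bound tolerance 10⁻¹², multiplier tolerance 10⁻¹⁰; iteration cap
  10·t² + 200 for t terms.
- Term enumeration order is canonical (features sorted, exponent vectors
  lexicographic) and the whole search is deterministic — seeds only enter
  through the synthetic generator.
- Δ% reporting rounds half away from zero to 2 decimals, matching the
  reference validation table's convention.
- Constant feature columns are dropped with a warning before screening;
  zero denominators in term evaluation raise with the term and sample
  named.

## The packaged reference calibration

Shipped as two CSVs (38 coefficients; panel names, units, ranges and
validation true/found/Δ% values) plus the canonical three-term composite.
Its internal-consistency checks: the implied per-analyte
Kᵢ = foundᵢ/(Cᵢ·0.946) has a coefficient of variation of 0.352% across
the panel (2-decimal table rounding dominates), and a single K fitted by
relative least squares to the true test concentrations printed with ≥ 4
units reproduces each of those 27 analytes within 0.1% relative error.
Some published Δ% entries are not self-consistent with their own rounded
true/found pair (e.g. rows where both printed values coincide yet
Δ% > 0); the validation asserts only the five rows that recompute exactly
(B1, B4, B5, B29, B33) and reports the rest as rounding artifacts. No raw
spectra accompany the reference calibration, so band tables, feature
values and stage-1 correlation figures for it cannot be reconstructed and
are not shipped; all spectrum-level results in this package come from the
synthetic generator.

## Known limitations

The method presumes the lockstep design. With 5% per-analyte
concentration jitter the 0.999 term screen finds no admissible term, and
even a relaxed screen leaves errors orders of magnitude above the
noiseless bound — the sub-0.1% figures are properties of proportional
calibration solutions, not of arbitrary sera. Other limits: no
uncertainty quantification on predictions; a single global δ rather than
per-analyte bias; prediction outside the calibration ranges is warned,
not refused; and the JCAMP-DX reader covers only uncompressed AFFN
XYDATA/XYPOINTS blocks.
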