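# Methods

## The assay being modelled

Each library plate is a 384-well plate: rows A–P, columns 1–24. Cells
are seeded into columns 1–23 (450 cells/well); column 24 receives media
alone and serves as the lactate-assay background. Every plate carries
16 non-targeting siOTP wells (the normalization reference), 8 siPLK1
wells (kill control, defines the bottom of the viability dynamic range)
and 8 siPDK1 wells (lactate control, defines the glycolysis dynamic
range); the remaining 336 wells each hold one library reagent. Each
library plate is assayed in duplicate in three arms: T0 plates fixed at
the start of treatment (cell counts only), and 48 h vehicle (DMSO) and
drug arms, from which both cell counts and spent-media A490 are read.
The control positions are configurable; the package's default places
siOTP in column 1 and siPLK1/siPDK1 in column 2. The true screen
scattered controls differently, but since all normalization is
per-plate and position-free, layout only matters through the per-class
well counts.

## Normalization

Per assay plate (plate × replicate × arm):

1. background: mean A490 of the plate's column-24 wells, subtracted
   from every experimental well. Negative corrected values are kept
   and flagged (clamping would bias genuinely low-lactate wells).
2. concentration: corrected A490 inverted through a least-squares
   linear standard curve (`scipy.stats.linregress`); the fit refuses
   non-monotone (slope ≤ 0) curves. Because FCs are ratios, any linear
   curve through the origin cancels out of downstream results; the nM
   scale matters only for the per-well intermediate table.
3. lactate per cell = concentration / T48 count; NaN with a flag when
   the count is 0 (no error — empty wells are data).
4. ΔT48 = T48 − T0, paired by plate/replicate/well. ΔT48 FC is taken
   against the control wells' own ΔT48 mean so all three metrics share
   the same denominator convention; a plate whose control ΔT48 mean is
   not positive fails QC outright rather than silently flipping signs.
5. FC = metric / mean(plate's siOTP wells), computed per replicate,
   then FCs are averaged across replicates (normalizing first removes
   plate offsets; averaging raw values would not).

The low-count flag (T48 FC < 0.2, per arm) marks wells where lactate
quantitation is unreliable; the glycolysis hit predicate applies the
vehicle-arm flag because hits are called in the vehicle arm.

## Hit calling

Robust z uses median and MAD with the 1.4826 consistency constant —
the standard screening choice where heavy phenotype tails would inflate
a mean/SD z. The population is all library genes screen-wide (controls
excluded), on replicate-averaged FCs; the published thresholds are
single global cutoffs per metric, which implies one population. All
inequalities are strict: boundary values are non-hits. Negative ΔT48
FCs (net death) satisfy the viability bound — death is the strongest
viability phenotype. A population with exactly zero spread (an
idealized noise-free screen) yields z = 0 for every gene rather than an
error: no gene deviates, and the FC bounds alone then decide (they
cannot fire at FC ≡ 1), so the null screen produces zero hits.

Enhancer binning uses the vehicle-vs-drug FC quadrants. The default
("methods") lactate-enhancer bin is ΔT48 FC > 0.3 in both arms, DMSO
lactate FC > 0.4 and drug lactate FC < 0.5: knockdowns that leave
vehicle-treated cells growing and glycolytic but collapse lactate
output under drug. An alternative "figure1c" scheme with the lactate
directions reversed (DMSO < 0.5, drug > 0.5) is selectable because both
wordings circulate for this analysis and they cannot both describe
enhancement; which matches the deposited enhancer list can only be
decided against that list. The viability-enhancer contrast has no
published threshold; the package default (ΔT48 FC > 0.5 in vehicle,
< 0.5 under drug) is an explicit, overridable choice.

## Deconvolution validation

A duplex confirms a phenotype when its replicate-averaged FC falls
strictly below the plate's control band, median(siOTP FCs) − 2·SD
(sample SD; the band mixes a median centre with an SD width because
that is how the rule is stated for this assay — a MAD-based width is
available as an option). All primary phenotypes are suppressions, so
the default direction is "decrease"; "increase" is retained for
generality. Bands are computed per library plate per arm per metric
from control FCs pooled over the replicate assay plates. A gene
validates with ≥ 2 of 4 confirming duplexes; validation rates are
percentages over the genes actually flagged for that phenotype.
Drug-enhancement is confirmed as suppression in the drug arm, and
DMSO/drug FC ratios are reported per duplex (ratio > 1: stronger
suppression under drug; an exactly zero drug-arm FC yields a flagged
infinite ratio).

## Synthetic screens

The generator's defaults mirror the screen design: 384-well layout with
the control complement above, duplicate plates, three arms, 450
seeded cells grown to a T0 baseline of 900, neutral growth factors 2.0
(vehicle) and 1.4 (drug — a sub-maximal dose that slows but does not
stop growth), neutral lactate 0.5 nM per cell on the assay's
concentration scale, background A490 0.08 and a curve slope of
8×10⁻⁴ A490/nM over a 0–2000 nM standard series. Effect classes are
parameterized as target FCs versus control: lethal −0.5 on ΔT48 in both
arms; glycolysis-low 0.3 on lactate in both arms; lactate-enhancer 1.0
(vehicle) / 0.25 (drug); viability-enhancer 1.0 / 0.2 on ΔT48.

Noise: counts are multiplied by median-1 log-normal factors (default
CV 10% — typical plate-to-plate imaging noise); absorbance gets
additive Gaussian noise (SD 0.01) plus one additive offset per assay
plate (SD 0.02) that background subtraction must remove; standard-curve
points get SD 0.005. The lactate actually produced in a well tracks the
realized cell count, so lactate-per-cell noise is dominated by
absorbance noise — deliberately, since dividing by the same measured
count cancels count noise in the real assay too. What the generator
does **not** emulate: row/column gradients and edge effects, batch
effects across plate batches, siRNA efficacy variation within a class,
transfection toxicity, or count/absorbance outliers from imaging
artefacts. Passing recovery tests therefore demonstrates the pipeline's
correctness and calibration under well-behaved plate noise, not
robustness to spatially structured artefacts (which the per-plate
normalization only partly addresses).

The deconvolution generator gives each duplex its gene's effect with a
configurable concordance probability, else neutral — a deliberately
simple off-target model that makes the ≥2-of-4 rule analytically
checkable against the binomial tail P(Bin(4, q) ≥ 2). Plates are filled
to their 84-gene capacity with neutral filler genes, marked in the
truth table and excluded from rate summaries.

## Numerical and scale choices

Desk-scale defaults (4 plates ≈ 1,344 genes, and 504 genes for the
binomial deconvolution check) keep the full test suite and the
acceptance script in the seconds range while leaving multinomial and
Monte-Carlo errors small against the 0.95 recovery bars; the 58-plate
full-scale mode runs the identical code path and is exercised by a
dedicated test. Counts are rounded to integers (they are object
counts); A490 values are floored at 0 (absorbance is non-negative).
CSV round-tripping uses pandas' round-trip float parser so written
datasets are byte-stable. Degenerate statistics (MAD = 0, control SD =
0, < 3 control wells, non-monotone curves) raise typed errors instead
of propagating silent NaNs/infs, with the single documented exception
of the zero-spread z population above.

## Known limitations

* The patient-upregulation tabulation requires an explicit fold-change
  threshold; published per-patient "upregulation" calls rarely state
  one, so cross-study comparisons depend on that choice.
* Validation-rate summaries treat duplexes as exchangeable; real
  duplex-level efficacy differences (seed-sequence effects) are not
  modelled.
* No spatial (B-score/loess) correction is implemented; the per-plate
  control normalization assumes spatially unstructured noise.
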