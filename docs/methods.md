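# Methods

## The measurement model

Body water containing a D₂O fraction *p* is the precursor pool for the
hydrogens added during de novo glucose synthesis. The monitored glucose
penta-acetate fragment (m/z 169) has `n = 6` exchangeable positions; a
molecule of gluconeogenic origin carries deuterium at each position
independently with probability *p*, while glucose released from pre-label
glycogen is unlabeled at those positions. With gluconeogenic fraction *f*,
the fragment's isotopologue distribution is the mixture

    f · Binomial(n, p)  +  (1 − f) · δ₀            ("binomial" mode)

The estimator inverts the first-order version of this model:

    E_frag = (I_{M+1}/I_M − b) / n ,   fGNG = E_frag / p

where *b* is an optional unlabeled-baseline M+1/M ratio (default 0). The
"linear" forward mode generates the two-point distribution with
M+1/M = f·n·p exactly, so the estimator inverts it exactly (the round trip
is tested to 1e-10); it is the default simulation mode because it isolates
estimation behavior from model truncation error.

**Truncation bias.** Applied to exact binomial isotopologues the linear
estimator gives est = f·(1−p)⁵ / (1 − f·(1−(1−p)⁶)): multiply-labeled
molecules drain M+1 (negative bias, dominant at mid-range *f*) while label
also drains M (positive bias, dominant as f → 1), with cancellation near
f ≈ 0.85. At p = 0.06 the net bias spans about −6.6 to +6.4 fGNG points
over f ∈ [0, 1]; it shrinks roughly linearly in *p* and stays within
±2 points only for p ≲ 0.02. `examples/estimator_bias.py` prints the
characterization; the test suite checks it against the brute-force
expectation over the isotopologue distribution to 1e-9. Within one study
run at a fixed enrichment the bias largely cancels in group comparisons,
but absolute levels from different enrichments are not directly comparable.

**Natural abundance.** The M+1/M background ratio of an elemental
composition is Σ nₑ·(a₁/a₀)ₑ — exact, since only single heavy substitutions
shift mass by one — with abundances pinned in
`src/fgng/data/isotope_abundances.json` (IUPAC representative values).
The composition of the m/z 169 ion is not established, so the default
fragment model carries an empty composition (background disabled) and the
defining equations are applied to raw ratios; any composition can be
supplied and is handled by full polynomial convolution. Which convention
underlies published fed-state baselines (~35 %) is unknowable from group
summaries, so the package exposes both paths and asserts neither.

**QC conventions.** All enrichments are fractions internally; percent
appears only in reports. Background oversubtraction floors at 0 with a
`negative-after-background` flag. fGNG in (1, 1.05] clamps to 1 with a
`superunity` flag (noise past the physical bound); beyond 1.05 the inputs
are inconsistent and the estimator raises. Feeding-state bands are closed
on the right: fed [0, 0.15], indeterminate (0.15, 0.40], unfed (0.40, 1],
overfed sub-band [0, 0.10] — the 15–40 % range has no established clinical
label and is reported as indeterminate.

## Calibration

The analyzer standard curve is an OLS line `reading = slope·fraction +
intercept` (≥ 2 distinct standards). The default assumes standards and
samples pass through the same 1:300 dilution (`curve_includes_dilution =
True`), so inversion needs no rescaling; set it false to multiply by the
dilution factor. Back-calculated enrichments in (−1e−4, 0) are clamped to
zero and flagged as instrument noise around a blank; anything more negative
is treated as a pipeline bug and raises. Per-injection M+1/M ratios are
computed first and the per-site enrichments averaged per sample afterwards
(ratio-then-average), which keeps each injection's QC independent.

## The synthetic cohort

The generator emulates a 2 × 2 between-subjects design — feeding (ad
libitum vs 50 % caloric restriction) crossed with injury (sham vs
closed-head TBI) — with unbalanced cells 3/6/6/5 and two sampling
timepoints (pre/post intervention). Defaults:

* **True fGNG per cell** (mean, between-animal SD, percent): pre — AL-Con
  35.6, AL+TBI 35.2 (SD 3.30), CR cells 36.62 (SD 5.67); post — AL-Con
  62.64 (6.33), AL+TBI 59.85 (5.01), CR-Con 79.83 (4.43), CR+TBI 79.10
  (4.52). Draws are truncated-normal on [0, 1] (truncation is negligible at
  these parameters; a config warning fires if it would remove > 50 % mass).
  The pre-intervention dispersions are standard errors scaled by √n while
  the post values are used as SDs directly: only that reading reproduces
  the reference cohort's own reported p-values (pre feeding comparison
  p ≈ 0.58 rather than 0.07; post CR-Con vs CR+TBI p ≈ 0.79; pooled
  injury comparison p ≈ 0.45), so it is adopted as the package's default.
* **Body water** 5.5 % ± 0.3 % — slightly below the 6 % drinking-water
  level, reflecting unlabeled water from food and metabolism; the exact
  value cancels in the round trip and only scales signal size.
* **Measurement noise**: independent mean-one lognormal factors per channel
  and injection with CV 2 % (positive support, standard for MS signal
  chains), 3 injections per sample; analyzer reading noise SD 2×10⁻⁴ on
  the diluted-fraction scale; simulated curve slope 1, intercept 0,
  standards 0–8 % in 1 % steps.
* One documented consequence of ratio-then-average under multiplicative
  channel noise: E[M+1/M] is inflated by (1 + CV²) ≈ 1.0004, i.e. ≈ +0.03
  fGNG points at fGNG 0.8 — negligible against between-animal spread but
  visible to Monte-Carlo means over many hundreds of replicate cohorts,
  and accounted for analytically where tests average at that scale.

Weight and food-intake trajectories are optional columns: cell means at
pre/24 h/13 d with Gaussian noise, plus the ration rule for restricted
animals (half the pre-intervention daily intake rounded **up** to the
nearest half gram — e.g. 25.0 g → 12.5 g, 21.9 g → 11.0 g) applied from
24 h onward.

All randomness flows from one `numpy.random.default_rng(seed)` (PCG64)
stream per bundle; identical seeds give byte-identical CSV output.

**What the simulator does not emulate:** D₂O equilibration kinetics (a
plateau is assumed from day 1), label recycling through TCA/pentose
pathways, positional exchange differences among the six sites, drift or
saturation in the mass spectrometer, and any correlation between an
animal's pre and post values (timepoints are drawn independently).
Passing recovery tests therefore demonstrates the estimator and statistics
are correct *given* this measurement model, not that the model captures
every feature of real GC-MS data.

## Statistics

The battery mirrors common SPSS-style practice for this design:

* **Two-way ANOVA**, Type III sums of squares with sum-to-zero contrasts
  (the GLM default; Type I available via `ss_type=1`). With n = 3/6/6/5 the
  types genuinely differ, and Type III tests each effect adjusted for the
  others. Zero residual variance is reported as the boundary case F = ∞,
  p = 0.
* **Independent t-tests**: pooled-variance Student by default, Welch behind
  a flag. Zero variance in both groups returns t = 0, p = 1 when means are
  equal and raises otherwise.
* **Tukey HSD** across the four cells, Tukey–Kramer form for unequal n
  (statsmodels' implementation). The degenerate all-constant design returns
  p = 1 for coincident cells.
* **`anova_from_summary`** rebuilds the identical Type III table from
  per-cell (mean, SD, n) alone via the weighted cell-means closed form:
  effect SS = β_J' [(X'WX)⁻¹]_JJ⁻¹ β_J with W = diag(n), residual
  SS = Σ(nᵢ−1)sdᵢ². It shares no code with the raw-data route, so their
  agreement (tested to 1e-9 on random unbalanced designs) is a genuine
  cross-check, and it lets printed tables be analyzed directly.
* Significance threshold 0.05, inclusive; no multiplicity control beyond
  Tukey. Pre-vs-post contrasts are reported unpaired — a fidelity caveat,
  since per-animal pairing information would support a stronger paired
  analysis.

Under the default post-intervention parameters the injury main effect has
noncentrality ≈ 0.77 (df 16), i.e. a true false-positive-style significance
rate of ≈ 11 % — the injury-effect "non-significance" of any single cohort
is itself a noisy event, which the replicate-based checks make explicit.

## Problem sizes

Replicate-cohort checks use 250–500 cohorts of 9–20 animals (seeded,
a few tens of seconds); the acceptance script uses 300–500 replicates per
recovered mean and 100 cohorts for the p-value bound. Large-sample bias
checks pool 2,000 simulated animals. These sizes put Monte-Carlo error
well below the tolerances being tested while keeping runs desk-scale.
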