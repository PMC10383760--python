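# Methods

## Assay model

The hexokinase/G6PDH assay converts glucose and fructose stoichiometrically
into NADPH, read at 340 nm. Each cuvette yields two optical densities: A1
before the enzyme reagent, A2 after the reaction completes. Adding the
second reagent changes the cuvette volume, so the pre-read is scaled by the
kit's correction factor before subtraction:

    R = A2 − 0.84·A1            (corrected response, OD)

Quantification is single-point against a certified standard of
concentration C (default 4.0 g/L):

    conc = (R_sample − R_blank) / (R_standard − R_blank) · C    (g/L)

The formula is linear in the blank-subtracted sample response; negative
results (sample response below blank) are reported with a flag, never
clamped, so replicate statistics remain unbiased. Reagent blanks exceeding
the manufacturer limit (0.300 OD on the automated analyzer, 0.500 OD for
the manual kit; limits inclusive — only readings *exceeding* the limit
fail) invalidate the run. The decision absorbance is A1 by default and
configurable to A2, since analyzer firmware differs on which read it gates.

Samples above the 8 g/L linearity limit are auto-diluted once using the
analyzer's factor table — [0,8)→0 (none), [8,16)→2, [16,32)→4, [32,88)→11,
[88,160]→20 — and the diluted read-back is multiplied by the factor.
Intervals are half-open (lower-inclusive) with the top bound inclusive, the
only non-ambiguous tiling of the declared 0–160 g/L range; a single pass
that still lands off-scale is an error rather than a loop, matching how the
instrument behaves. Replicate reads of one cuvette are averaged
(arithmetic mean of A1 and A2) before correction; the correction being
linear, the order is immaterial.

## Calibration

The calibrator carries five certified levels (0.90, 1.80, 3.60, 5.40,
7.20 g/L) read in triplicate. All 15 replicate points enter an ordinary
least-squares fit of response on concentration individually — not as level
means — so the intercept standard error Sₐ reflects true replication and
the detection limits LOD = 3·Sₐ/b, LOQ = 10·Sₐ/b (slope b) are meaningful.
LOQ/LOD = 10/3 identically.

Residual diagnostics use four flavors: absolute eᵢ, normalized eᵢ/Sₑ,
internally studentized ("standardized", leverage-adjusted) and externally
studentized (leave-one-out Sₑ₍ᵢ₎, distributed as Student's t with n−3
degrees of freedom under a correct model, hence requiring n ≥ 4). The fit
and influence measures come from statsmodels; the test suite independently
verifies them against hand-written normal equations and leave-one-out
refits.

The linearity verdict combines: (i) ≥ 98 % of standardized residuals inside
±2; (ii) no externally studentized residual beyond ±3 (gross-error screen);
(iii) the mean observed response at every level within 10 % (relative) of
the fitted value; (iv) a homoskedasticity screen implemented as a two-sided
t test (α = 0.05) of the slope in the regression of |eᵢ| on concentration —
a quantitative stand-in for visual inspection of the absolute-residual
plot. Note that criterion (i) at n = 15 tolerates zero violations, so the
verdict on a well-behaved noisy calibration is itself a random variable
with a non-trivial false-fail rate; routine users should read the component
fields, not only the boolean.

A numerically perfect fit leaves Sₑ at rounding level; the scaled residual
flavors would be 0/0 noise and are defined as zero (threshold 10⁻¹² of the
response scale).

## Precision and equivalence

For one wine, two series of n = 10 replicate concentrations (automated and
manual procedures) yield:

| quantity | formula | note |
|---|---|---|
| mean, SD | n−1 denominator | per procedure |
| repeatability limit | r = 2√2·s_manual | 95 % bound on a replicate pair difference |
| method repeatability | r_M = 0.056·C | C = manual-series mean |
| method reproducibility | R_M = 0.12 + 0.076·C | affine in C |
| holistic uncertainty | U = √2·R_M | = k·S_R, k = 2, S_R = R_M/√2 |
| expanded uncertainty | 2·SD | per method |
| t statistic | \|x̄_m − x̄_a\| / √((s_a²+s_m²)/(n−1)) | df = 2(n−1) |

The concentration C entering the method limits is the manual (reference)
series mean by default (configurable), since the method limits describe the
reference procedure's permitted dispersion at the true level.

The t denominator divides by n−1 rather than the textbook n: this is the
convention of the validation protocol whose reports this package
reproduces, kept deliberately for fidelity. It relates to the classical
equal-n pooled statistic by the exact factor √((n−1)/n) and is therefore
mildly anticonservative: at n = 10 the true type-I rate at nominal
α = 0.05 is 2·P(T₁₈ > t₀.₉₇₅·√(9/10)) ≈ 0.062, which the test suite
verifies by simulation. `convention="classical"` selects the textbook
statistic.

All chained statistics use unrounded intermediates (rounding r and r_M
first would give r/r_M = 0.778 instead of the correct 0.779 for the dry
red wine), with one deliberate exception: the per-method expanded
uncertainties are computed from the SD at reporting precision (3 dp),
matching how summary certificates quote them (2×0.013 = 0.026 where the
unrounded SD would give 0.027). One reference summary cell (moderately
sweet wine, manual) prints 4×SD = 0.356; the package computes the
consistent 2×SD = 0.178 and the test suite documents the discrepancy.
Similarly, the reference report prints "P 0.000" for the dry white wine
although its own t = 2.684 at df = 18 implies p = 0.015; the package
reports the computed value.

**Suitability.** The automated procedure is fit for purpose on a wine iff
|x̄_auto − x̄_manual| < U and s_auto ≤ s_manual. Statistical significance of
the mean difference is reported alongside but does not block suitability:
with tight automated repeatability, even an analytically irrelevant bias is
statistically detectable. On the bundled data all four wines are
significant *and* suitable.

Reported values are rounded half-away-from-zero (3.776 → 3.78, 4.224 →
4.22), the certificate convention. Because the replicate inputs are decimal
values, the printed summaries follow decimal arithmetic; binary floats can
land an exact decimal tie at 1.65049999…96, so the rounding routine snaps
to a guard precision ten decimals past the target before applying the
half-away rule — indistinguishable from decimal arithmetic for any
physically meaningful input.

## Control charts

Routine sessions measure the certified 4.0 g/L standard; the chart center
is the nominal concentration and the default limits are the acceptability
band C ± 0.056·C (rendered 3.78–4.22 g/L), which the protocol uses as its
chart limits; σ-based limits can be passed explicitly. Four rules flag loss
of control: a point beyond the limits; seven consecutive points strictly
one side of center; seven strictly ascending points (6 increases); seven
strictly descending. A point exactly on the center line breaks a same-side
run and equal neighbors break a monotone run (strict inequalities — ties
are evidence of neither side nor trend). A run longer than seven flags
once, at the point completing its first window, matching the "check the
eighth point" escalation language. Each flag carries the prescribed cause
and corrective action.

## Synthetic data

Generators emulate the study's statistical structure, not its chemistry:

- **Replicates** — independent Gaussian draws per procedure at per-wine
  means/SDs. Bundled profiles are the four reference wines (2.623/0.026,
  2.417/0.037; 1.651/0.013, 1.695/0.048; 6.996/0.052, 7.249/0.089;
  31.364/0.485, 32.495/0.874 g/L). Gaussian noise matches the residual
  normality the replicate data support; no heavy-tail option.
- **Calibration** — true line plus additive read noise. Defaults (slope
  0.05 OD/(g/L), intercept 0.01 OD, σ = 0.002 OD) put R² near 0.999 on the
  default design, a realistic photometric precision for this assay.
- **Control series** — noise at σ = 0.04 g/L (1 % of the standard, the
  automated analyzer's typical replicate CV) with optional spike, shift, or
  drift faults, each constructed to trigger exactly its rule. The
  false-flag rate of a clean series is scale-free (it depends only on
  signs/orderings): the exact same-side-run recursion gives a clean-series
  probability of ≈ 0.88 at length 20, which the tests assert against that
  analytic value rather than a round number.
- **Absorbances** — blank/standard/sample A1–A2 pairs built by inverting
  the quantification formula (standard span 0.40 OD over C = 4 g/L, so the
  error-propagation factor is 10 (g/L)/OD); the σ = 0 round-trip is exact
  to 10⁻⁹.

One integer seed governs everything; each generator derives a child stream
from (seed, operation tag, index) via `numpy.random.SeedSequence`, so
outputs are bit-reproducible and substreams are mutually independent.

What the generators do *not* model: matrix effects, instrument drift within
a run, inter-day components, correlation between procedures measuring the
same bottle, or fermentation chemistry. Passing tests on synthetic data
therefore demonstrate the correctness of the computations and decision
logic, not the field performance of any instrument.

## Problem sizes

The golden reproduction runs on the bundled 80 replicates (< 1 s).
Simulation-based checks use 100–1000 seeded repetitions each (oracle
equivalence over 100 designs, LOD scaling over 2×200 calibrations,
run-rule oracle over 1000 series, rejection-rate over 500 pairs), sizes at
which Monte-Carlo error is comfortably inside the asserted bands; the whole
suite completes in a few seconds.

## Known limitations

- The decision limits sometimes quoted alongside LOD/LOQ for this assay
  have no closed formula in the source protocol and are not implemented.
- Printed reference values LOD = 0.05 and LOQ = 0.08 g/L are mutually
  inconsistent with the 10/3 identity and their raw calibration absorbances
  are unavailable; the package implements the formulas and validates them
  by property (Sₐ ∝ σ scaling, oracle equivalence) instead of against those
  two numbers.
- Inter-laboratory (ring-test) scoring is out of scope; only
  intra-laboratory statistics are computed.
- Weighted or nonlinear (e.g. 4PL) calibration is out of scope; the assay's
  working range is deliberately restricted to where the straight line
  holds.
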