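# Methods

This note documents the models implemented in enzkit, the unit conventions
and numerical choices behind them, what the synthetic generators do and do
not emulate, and the known limitations — including the internal
inconsistencies of the bundled CelC307 reference record that the package
flags rather than reproduces.

## Activity units and profiles

A linear standard curve (absorbance = slope·µmol + intercept) is fitted by
ordinary least squares; at least three standards with non-degenerate
concentrations are required. One enzyme unit is 1 µmol of product per
minute; specific activity divides by enzyme mass (U/mg), volumetric activity
by reaction volume (U/ml). An absorbance below the calibration intercept
clamps the inferred product to zero with a warning instead of reporting
negative units — blanks and baseline drift produce such readings and a
negative unit has no physical meaning. Relative profiles map the maximum to
100% with a first-occurrence tie-break; replicates are averaged before
normalization and their standard deviation is carried as metadata.

## Michaelis–Menten fitting

The rate law v = Vₘₐₓ·S/(Kₘ+S) is fitted by bounded nonlinear least squares
(Levenberg–Marquardt via trust-region reflective with positivity bounds),
with starting values Vₘₐₓ⁰ = max(v) and Kₘ⁰ = the substrate level at
half-maximal velocity (linearly interpolated), parameter tolerance 1e-8 and
an iteration cap of 500 (×10 function evaluations). Standard errors come
from the local quadratic approximation (the Jacobian-based covariance).
Uniform weighting is the default; a relative (1/v) weighting is available
for data whose error scales with signal. A fit whose Kₘ collapses more than
four orders of magnitude below the smallest tested substrate concentration
is reported as degenerate ("invalid kinetics"): such a Kₘ is not
identifiable from the design.

Units are never converted implicitly. Kₘ stays in the unit of the substrate
axis; conversion to molar happens only in k꜀ₐₜ/Kₘ and requires a
molar-convertible unit (mM, µM, M) — a mass-concentration axis (mg/ml)
yields a warning and no efficiency. k꜀ₐₜ is an input by default; deriving it
from a specific-activity Vₘₐₓ and molecular weight
(k꜀ₐₜ[min⁻¹] = Vₘₐₓ[U/mg]·MW[kDa], since 1 kDa = 1 mg/µmol) is optional
because published Vₘₐₓ/MW/k꜀ₐₜ triples are frequently mutually inconsistent
— they are in the bundled reference record.

The Lineweaver–Burk transform (OLS of 1/v on 1/S) is provided for plots and
for the classical inhibition-mode geometry, not as an estimator: reciprocal
space inflates low-velocity noise, so all parameter inference uses the
nonlinear fit.

## Inhibition-mode classification

Each inhibitor level (including the 0 mM control) is fitted independently.
The mechanism is read from the shifts of apparent Kₘ and Vₘₐₓ relative to
the control at the highest inhibitor concentration:

| call            | apparent Kₘ | apparent Vₘₐₓ | reciprocal lines      |
|-----------------|-------------|----------------|-----------------------|
| competitive     | up          | unchanged      | cross on the y-axis   |
| non-competitive | unchanged   | down           | cross on the x-axis   |
| uncompetitive   | down, proportional | down, proportional | parallel |
| mixed           | both shift, non-proportional | | cross off both axes |

"Changed" requires the relative shift to exceed **both** a 10% relative
tolerance **and** twice its delta-method standard error (propagated from the
two fits' covariances). The significance gate matters: at realistic noise
the Kₘ estimate of a 6-point design carries a ~10–15% sampling error, so a
plain 10% threshold misreads noise as mechanism. Proportionality
(uncompetitive vs mixed) is judged by the constancy of the reciprocal-line
slope Kₘ/Vₘₐₓ within max(2%, 2 SE). A significant opposite-sign shift at an
intermediate level marks the series non-monotone and the verdict
"indeterminate"; a failed sub-fit likewise yields "indeterminate" naming the
level. Pairwise line intersections are solved in closed form and labelled
(y-axis / x-axis / general / parallel) as corroborating evidence.

On synthetic series generated under each canonical mechanism (triplicate
readings at 3%-of-Vₘₐₓ noise, 100 seeds each) the classifier returns the
generating mechanism in 94–98% of cases, as measured by the test suite.

## Activation thermodynamics

Arrhenius regression (ln k on 1/T) gives Eₐ = −slope·R and A = exp
(intercept); two points are solved exactly, three or more by OLS. For a
temperature–activity profile, only the ascending limb (temperatures up to
the activity optimum) enters the fit — beyond the optimum the signal is
inactivation-limited and no longer reports the catalytic barrier.

The Eyring decomposition uses the reduced rate k‡ = k·h/(k_B·T), so
ΔG‡ = −RT·ln k‡, ΔH‡ = Eₐ‡ − RT, ΔS‡ = (ΔH‡ − ΔG‡)/T. Two deliberate
conventions, both switchable:

- **Rate unit.** k_B·T/h is a per-second frequency, so the standard choice
  expresses the rate in s⁻¹ (`per_second`). A `per_minute` mode feeds a
  min⁻¹ number in unconverted — a convention some published tables use; it
  shifts ΔG by RT·ln 60 (≈10.7 kJ/mol at 313 K).
- **Kₘ scale in the binding energy.** ΔG‡(E–S) = −RT·ln(1/Kₘ) is evaluated
  with Kₘ in molar by default (`km_unit_mode="M"`, the thermodynamically
  standard state); an `"mM"` mode reproduces tables that quote Kₐ = 1/Kₘ
  with Kₘ in mM. The sign and magnitude of the result depend on this
  choice; both the signed and absolute ΔS are reported because published
  tables often print the magnitude only.

Temperatures are accepted in °C at every interface boundary and converted
once via T(K) = T(°C) + 273.15. R = 8.314 J mol⁻¹ K⁻¹; k_B and h are the
CODATA exact values. Avogadro's number is declared among the constants for
completeness but no implemented equation uses it.

An externally supplied ΔG‡ can be passed as `dG_override` for the entropy
step, which is how a published ΔG‡ that does not derive from its own printed
k꜀ₐₜ can still be combined with a published ΔH‡ (the bundled reference
record needs exactly this; see Known inconsistencies).

## Thermal inactivation

First-order decay is fitted per temperature by zero-intercept OLS of
ln(fraction) on time — the model pins ln(fraction) = 0 at t = 0, so the
closed form is k_in = −Σt·ln f / Σt². A free-intercept diagnostic fit is
reported alongside; a large intercept signals a fast initial phase the
single-exponential model misses. Non-positive fractions are dropped with a
warning; a negative fitted k_in (activity rising in time) is flagged as
activation rather than inactivation. Half-life and decimal-reduction time
follow exactly: t½ = ln2/k_in, D = ln10/k_in, hence D/t½ = ln10/ln2 ≈ 3.32
always. The Eₐ# of inactivation reuses the Arrhenius engine on the k_in
panel, and the state functions reuse the Eyring expressions with the same
`per_second`/`per_minute` switch. Biphasic (Lumry–Eyring) inactivation and
pressure effects are out of scope.

## Screening and response-surface methodology

The 12-run Plackett–Burman matrix comes from the classical cyclic generator
row (+ + − + + + − − − + −) plus an all-minus run; all 11 columns are
pairwise orthogonal and balanced for any factor count up to 11. Main
effects are mean(+) − mean(−); their error is estimated from the unassigned
(dummy) columns' apparent effects (the Minitab-style pseudo-error, t-tested
on the dummy degrees of freedom at α = 0.05), with Lenth's pseudo standard
error available as an alternative.

The central composite generator places 8 factorial corners, 6 axial points
at ±α = 8^(1/4) ≈ 1.682 (rotatable for 3 factors) and configurable center
replicates, optionally split into the orthogonal two-block layout
(factorial + 4 centers / axial + 2 centers). A 3-factor Box–Behnken
generator (12 edge midpoints + centers) is provided as well.

The second-order model is fitted by OLS simultaneously on the coded and the
natural scale (identical fit, two parameterizations); the block enters as a
fixed two-level effect and reported natural-unit coefficients refer to the
block-averaged response. The ANOVA mirrors the Design-Expert layout: block
SS sequentially (fit of intercept+block), model SS as the remainder to the
corrected total, per-term partial (drop-one) SS on the coded scale, and the
residual split into pure error (replicate groups of identical coded rows
within a block) and lack of fit. The SS and df partitions are asserted as
identities in the test suite. Optimization solves the stationary point of
the quadratic in closed form and falls back to a dense grid (50 points per
axis) plus bounded local ascent when the stationary point is a saddle or
lies outside the box.

Refitting the bundled 20-run CelC307 expression experiment reproduces the
reported ANOVA landmarks (model F 15.31 vs 15.34 reported; lack-of-fit F
0.659 vs 0.657; block SS 0.6135; pure-error SS 5.07 on 4 df). The reported
predicted optimum of 58.4 U/ml is *not* reproduced by the reported
polynomial itself, which tops out near 55.7 U/ml over the stated bounds;
both numbers are surfaced and neither is asserted.

## Protein physicochemistry

Translation uses the standard genetic code (Biopython), stopping at the
first stop codon; N-containing codons give X. Indices follow the Expasy
ProtParam definitions: average-isotopic molecular weight; isoelectric point
on the Bjellqvist pKa set, located by bisection on the net-charge function
until |charge| < 1e-4 (the charge is strictly decreasing in pH, so the
bracket is valid); the Guruprasad instability index from the DIWV dipeptide
table; the Ikai aliphatic index X(A) + 2.9·X(V) + 3.9·(X(I)+X(L)) in mole
percent; and the Kyte–Doolittle GRAVY. X residues are excluded from all
indices with a warning and the length renormalized. The reference protein's
own record (491 aa, 56.86 kDa, pI 5.85) can only be verified against the
GenBank entry MN105992.1, which is not redistributable here; the
corresponding check in the test suite therefore requires a locally provided
copy of that record.

## Synthetic generators

Every generator is a pure function of its parameters and a seed. Velocities
are generated as means of triplicate readings by default (per-replicate
Gaussian noise, truncated at zero), matching the standard practice of
assaying in triplicate and analyzing the means; the inhibition generator
scales the noise SD with the apparent Vₘₐₓ of each level, since measurement
error tracks the observed signal. Truncation at zero introduces a positive
bias only where the true velocity is within ~2 SD of zero, which the default
designs avoid. Mechanisms: competitive Kₘ(1+I/K_i); non-competitive
Vₘₐₓ/(1+I/K_i); uncompetitive both /(1+I/K_i); mixed with a secondary
binding factor α = 2 by default. Default magnitudes mirror the reference
enzyme (Kₘ ≈ 0.5–2 mM, Vₘₐₓ ≈ 50–60 U, inhibitor levels 0.5 and 1 mM,
Eₐ# ≈ 60 kJ/mol, and the reference polynomial for DOE responses).

What the generators do **not** emulate: systematic (non-Gaussian) assay
error, substrate depletion during the assay, product inhibition, biphasic
inactivation, or block-by-condition interactions in DOE responses. Passing
tests therefore demonstrate correctness of the estimators under the stated
error model, not robustness to every artifact of real bench data.

## Problem sizes in the test suite

The suite exercises parameter recovery at 20–100 seeds per property
(classifier accuracy uses the full 100 seeds × 4 mechanisms), grid oracles
at 400×400 resolution, and a 2-million-point brute-force check of the
line-intersection algebra; the complete run takes well under a minute on a
single CPU.

## Known inconsistencies of the reference record

The consistency audit (`enzkit.diagnostics.consistency_report`) recomputes
every derivable quantity of the bundled CelC307 record from its own inputs
and flags disagreements; these are reported, never silently "fixed":

- **ΔG‡ = 58.60 kJ/mol** is not obtainable from the reported
  k꜀ₐₜ = 0.1043 s⁻¹ under any standard unit choice (the Eyring value at
  313.15 K is 82.7 kJ/mol). The package computes ΔG‡ by the standard
  formula and accepts the reported ΔG‡ as an override for the entropy step.
- **t½ and D columns** are ≈10× larger than ln2/k_in and ln10/k_in from the
  same rows' k_in, and mutually inconsistent (D/t½ between 3.7 and 4.4
  instead of ln10/ln2 ≈ 3.32). The package reports the internally
  consistent values (t½ = 42.79 min at k_in = 0.0162 min⁻¹).
- **Eₐ# = 59.29 kJ/mol** is not the Arrhenius slope of the reported k_in
  values (OLS gives ≈ 67.9 kJ/mol); both are surfaced.
- The reported decimal-reduction relation "D = RT/k_in" is dimensionally
  inconsistent; the standard D = ln10/k_in is implemented.
- The reported ΔS# values are printed unsigned although (ΔH − ΔG)/T is
  negative at every temperature; signed and absolute values are both
  emitted.

## Design choices and limitations

- Classification thresholds (10% shift tolerance, 2% parallelism floor,
  2-SE significance gate) are calibrated for 2-level inhibitor series with
  6-point substrate designs in triplicate; sparser designs will push more
  series into "indeterminate", which is the intended failure mode.
- The ANOVA's per-term SS are partial (drop-one); on an orthogonal coded
  design they coincide with sequential SS except for the slight
  non-orthogonality introduced by rounded natural levels.
- The PB screen assumes negligible interactions, as the design itself does.
- Single-substrate, single-enzyme initial-rate kinetics only: no Hill or
  substrate-inhibition models, no progress-curve (integrated rate) fitting,
  no global K_i estimation, no IC₅₀.
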