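# Methods

## Quenching model and fitting

Fluorescence quenching of a protein by a ligand is reduced to the ratio
F₀/F, where F₀ is the emission intensity without ligand and F the intensity
at quencher concentration [Q].  Two conventions for F are supported:

* `peak` (default) — the refined peak intensity I_max.  The peak is located
  by fitting a parabola through the brightest sample and its two neighbours
  (coordinates centred on the peak sample for conditioning) and taking the
  vertex, clamped to the neighbour interval.  This makes λ_max independent of
  the generator's band shape; a maximum on the scan edge falls back to the
  grid value and is flagged.
* `integral` — the trapezoidal integral over the scanned band.  Because it
  averages per-sample noise over ~100 wavelength samples, it is the
  recommended mode for noisy spectra (see *Known limitations*).

**Stern–Volmer.** F₀/F = 1 + K_SV[Q] is fitted by ordinary least squares
with a *free* intercept; the deviation of the intercept from 1 is reported
as a diagnostic rather than constrained away.

**Mechanism call.** K_SV estimates at ≥ 2 temperatures are regressed on T;
the slope is reduced to z = slope/SE, with the SE propagated from the
per-temperature standard errors when available (otherwise taken from the
regression residuals).  Verdicts: `static` (z ≤ −z*), `dynamic` (z ≥ +z*),
else `ambiguous`, with z* = 2 by default.  Setting z* = 0 reproduces a
sign-only call.  The call is invariant to the input ordering.

**Binding constant.** The modified Stern–Volmer double-log form
log₁₀((F₀−F)/F) = log₁₀ K_a + n log₁₀[Q] is used (base-10 logs).  Points
with F ≥ F₀ carry no binding signal and are excluded (and counted); at
least three usable points are required.  Note that a double-log form with
the response printed as log F alone cannot produce a positive association
constant from a decreasing F; the (F₀−F)/F numerator is the standard form
and is what this package implements.

**Hill cooperativity.**  The fractional quench y = (F₀−F)/F₀ (default;
(F₀−F)/F selectable) is fitted to

    y = B_max [Q]^h / (K_d^h + [Q]^h)

by `scipy.optimize.curve_fit` with bounds B_max ∈ (0, 1.5], K_d > 0,
h ∈ [0.05, 20], multistarted from h ∈ {0.5, 1, 2, 4}; ties are broken by
lowest residual sum of squares, then lowest h.  Non-convergence across all
starts is reported via a `converged` flag, never an exception.  B_max can be
fixed (e.g. at 1) when the saturation amplitude is known, which is the
appropriate setting when estimating the Hill slope of a narrow-range
isotherm segment.  The (F₀−F)/F₀ default keeps B_max in (0, 1] and makes
K_d = 1/K_a directly interpretable.

## Van 't Hoff thermodynamics

ln K_a is regressed on 1/T (natural log); ΔH = −R·slope, ΔS = R·intercept,
R = 8.314 J/(mol·K).  ΔG is computed by two routes — (i) −RT ln K_a per
temperature and (ii) ΔH − TΔS — and both are always reported.
`thermo_consistency` quantifies per-temperature discrepancies and flags sign
conflicts; published thermodynamic tables are not always internally
consistent, and the package surfaces such conflicts instead of choosing a
side.  The (sign ΔH, sign ΔS) → dominant-force label table follows the
Ross–Subramanian convention (ΔH > 0, ΔS < 0 ⇒ hydrogen bonds and
hydrophobic interaction) and is data, not code.  Internal unit is J/mol;
reports print kJ/mol, the only scale on which lectin–sugar ΔG magnitudes of
a few units are meaningful.

## Denaturation analysis

Per condition (denaturant concentration), λ_max and I_max are extracted per
replicate and compared across conditions by one-way ANOVA and Tukey's HSD
(`scipy.stats.tukey_hsd`); Shapiro–Wilk normality p-values are reported as
diagnostics only.  Significance defaults to α = 0.1.  Zero within-group
variance (noise-free synthetic replicates) makes the studentized range
undefined, so that case is decided exactly: p = 0 where means differ, 1
where they do not.  "Red shift significant" requires both Tukey p ≤ α *and*
a positive mean shift — sign and significance are separate checks.

**Three-state rule.**  Each non-reference condition gets four flags:
A = significant I_max increase vs the reference, B = significant red shift,
C = CD218 magnitude increase vs the reference, D = significant I_max decline
relative to an already-identified intermediate (conditions processed in
ascending denaturant).  The verdict is a pure, total function of the flags:

* intermediate monomer — A ∧ (¬B ∨ C): dissociation of the oligomer raises
  the fluorescence of the still-folded monomer;
* unfolded — B ∧ (D ∨ ¬A): a red shift with the intensity gain lost (or
  never present) marks solvent exposure of the aromatic residues;
* intermediate monomer — B ∧ A otherwise (a red shift while intensity keeps
  rising is the monomer persisting, not unfolding);
* native otherwise.

Without CD data the same rules run with C = False and the result is flagged
fluorescence-only.

**Hemagglutination.**  A plate is an ordered two-fold dilution series; the
titer is the reciprocal dilution of the last well in the leading contiguous
positive run (0 if the first well is negative), and positives after a
negative are flagged as plate anomalies.  Activity loss per condition is
classified against the 0 M reference: `partial` (0 < titer < reference),
`none` (equal), `full` (0); a titer above the reference is impossible under
the model and flagged.

## Synthetic data generator

The generator emulates the study conditions end to end and is the fixture
for every recovery test.

*Titration.*  Emission bands are Gaussian in wavelength (no lineshape is
implied by the analysis — the peak refinement is shape-agnostic), centred at
344.3 nm, width 18 nm, on a 1-nm grid over 300–400 nm.  Quencher grid:
12 final cuvette concentrations spanning 2–11 mM; temperatures 298/303/308 K.
The quenching constant is anchored at K_SV = 28.47 M⁻¹ at 298 K and follows
a Van 't Hoff law with ΔH = −53.24 kJ/mol — the enthalpy implied by the
anchor constant's own temperature trend — so the default dataset carries the
static-quenching signature (K_SV falling with T).  Isotherms: `static` and
`dynamic` use F = F₀/(1 + K_SV(T)[Q]); `hill` and `concerted` scale F₀ by
1 − B_max[Q]^h/(K_d^h+[Q]^h) (h fixed at 2 for `concerted`).  Noise is
Gaussian, relative to signal, applied per wavelength sample after scaling;
the integer seed makes output bit-exact.  Spectrum metadata carries the
generating truth.

*Denaturation.*  Three states with (λ_max, I_max, CD218) =
(344.3 nm, 53.82, −8), (346.3 nm, 64.5, −12), (346.3 nm, 56.11, −3), mixed
by two sequential two-state linear-extrapolation transitions with midpoints
2.5 M and 7.5 M urea and m-values of 10 kJ·mol⁻¹·M⁻¹ (populations sum to 1
by construction; at 0/5/10 M the mixtures are pure states to ~10⁻⁴).  The
default relative noise of 0.005 reproduces replicate scatter of ~0.3 a.u.
in I_max and ~0.6 nm in λ_max, the realistic scale for triplicate
spectrofluorometer readings.  Hemagglutination activity is
titer₀·(p_native + p_intermediate/8), rounded to the nearest power of two,
which yields the 64 → 8 → 0 pattern (partial, then full loss).  CD traces
are smooth bands whose 218-nm value equals the population-weighted state
value; urea-treated scans start at 210 nm (poor signal-to-noise below).

*What the generator does not emulate:* inner-filter effects, fluorophore
dilution over the titration (final concentrations are taken as given),
FRET, pH effects, instrument drift, or correlated (non-white) noise.
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated statistical model, not robustness to those systematic
effects.

## Sequence tools

Global percent identity uses Biopython's Needleman–Wunsch implementation
with BLOSUM62, gap open 10, extend 0.5.  The identity denominator defaults
to the query length (alternatives: alignment columns, shorter sequence);
with a 101-residue query, 82 identical aligned positions give 81.2%.  The
simple pH-7 net charge counts +1 per Arg/Lys and −1 per Asp/Glu with His
neutral and termini cancelling — for the cMoL chain this gives +16, and the
dimer's +32 matches the 90 − 58 Cl⁻/Na⁺ imbalance needed to neutralise a
simulation box.  Box molarity ignores solute volume:
M = n_solute·ρ·1000/(n_water·18.015).

## Numerical choices and test scales

* OLS fits go through `scipy.stats.linregress`; property tests assert
  equality with the closed-form estimator to 1e-10.
* The stochastic recovery suite uses 200 seeds at 1% relative noise with the
  band-integral F mode and a single temperature per seed (~3 s total); the
  12-point default grid is the study condition, not a scaled-down size.
* The acceptance script fits the Hill model to a 12-point noise-free
  concerted isotherm (K_d = 6 mM), the configuration under which h = 2 is
  identifiable to three decimals.

## Known limitations

* The double-log binding fit is biased on the arithmetic mean under noisy
  peak-mode F values (~12% at 1% per-sample noise): the log of small noisy
  (F₀−F) differences at low [Q] is skewed, the intercept extrapolates far
  outside the data's log[Q] range, and 10^intercept is convex.  Use the
  band-integral F mode for noisy spectra, or report geometric-mean K_a
  across replicates.
* The mechanism z-test treats per-temperature K_SV errors as independent.
* The three-state rule assumes monotone progression with denaturant; it will
  label re-entrant (stabilising) conditions as anomalous intermediates.
* No inner-filter or dilution corrections are applied anywhere; supplied
  concentrations are taken as final.
* Molecular weight is computed for the monomeric chain only and is not a
  validation target (oligomer masses differ).
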