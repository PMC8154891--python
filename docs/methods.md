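# Methods

## The cycle model

The package models chaperone-mediated peptide exchange on MHC-I as four
coupled reversible binding steps between the heavy-chain/β2m heterodimer
(M), the chaperone TAPBPR (T) and peptide (P): M+T⇌MT (kd1), M+P⇌MP (kd2),
MP+T⇌MPT (kd3) and MT+P⇌MPT (kd4), all concentrations in molar. β2m is
implicit — "M" always means the assembled heterodimer, as in the assays the
package emulates; β2m dissociation is not modelled. Detailed balance
requires `kd1·kd4 = kd2·kd3`. Constructors therefore take three constants
(kd2, kd3, kd4) and complete kd1 by closure; a fully specified set is
accepted with a warning when its closure residual `kd1·kd4/(kd2·kd3) − 1`
is within 0.1 (published tables are rounded and rarely close exactly) and
rejected beyond that. kd3 is carried per peptide: the measured tables
report peptide-specific values, and each peptide's own closure is enforced.
Whether kd1 should differ between chaperone variants beyond what closure
implies is left to the user (the model takes kd1 as an input to the
solver).

Optional per-step binding enthalpies (kcal/mol) obey the Hess closure
`dh1 + dh4 = dh2 + dh3`, completed the same way.

### Equilibrium solver

`solve_equilibrium` finds free concentrations for arbitrary mixtures of M,
T and any number of peptides. The primary scheme is a damped fixed-point
iteration: each component's free concentration is updated by dividing its
total by the binding polynomial evaluated at the current iterate, with
geometric damping (exponent 0.5), which preserves positivity and is stable
when constants span pM–mM. Iteration stops at a relative change of 1e−12
or after 10,000 rounds; if the worst relative mass-balance residual still
exceeds 1e−10, the solution is polished by multivariate root finding on
log free concentrations (positivity again guaranteed by construction), and
a solver error carrying the final residual is raised if that also fails.
Components with zero totals are eliminated analytically. The solver is
deterministic and is validated in the test suite against closed-form
binary quadratics and an independent brute-force oracle (global
minimisation of squared mass-balance residuals).

## Calorimetric titrations

The three titration designs take their cell/syringe compositions from the
published experimental designs, with quoted ranges at their midpoints:
peptide (75 µM syringe) into 15 µM 1:1 complex for the displacement (KD2)
design; 175 µM loaded pMHC-I into 15 µM chaperone with 1 mM free peptide
on both sides (KD3); 175 µM peptide into 15 µM complex with 50 µM excess
chaperone (KD4). The cell volume is not published; the package uses
1.4 mL, the nominal cell volume of the instrument named in the study's
methods, with 28 × 10 µL injections by default (injection spacing is
irrelevant at equilibrium).

**Dilution model.** Each injection displaces cell solution continuously,
so totals evolve as `x ← x·exp(−dV/V0) + x_syr·(1 − exp(−dV/V0))`. This
perfusion form composes exactly — splitting one injection into two
half-volume injections reproduces the same state — which is what makes the
simulated heats additive under injection splitting (a property the test
suite asserts at 1e−6).

**Heat bookkeeping.** Measured heats are differences of a state function:
the cumulative heat after injection i is
`V0 · Σ_s dH_s · ([complex_s]_i − [complex_s]_i^dil)`, where the dilution
reference trajectory mixes cell and syringe identically but never
re-equilibrates. This is the simulation-side analogue of the standard
control-experiment subtraction (titrating the syringe into buffer):
material that leaves the cell without reacting contributes nothing. A
constant per-injection residual dilution heat is available and defaults to
zero. Under this convention a saturating titration's cumulative heat
equals dH times the moles of macromolecule currently in the cell, and a
binary titration reproduces the closed-form one-site (Wiseman) expression,
which doubles as the independent oracle in the tests.

**One-site fitting** estimates (n, kd, dH) by Levenberg–Marquardt least
squares on the per-injection heats, with the model evaluated on the full
injection series and subset afterwards (heats are cumulative differences,
so dropping points must not re-base the model). The first injection is
excluded by default, mirroring standard practice. Multistart over kd
decades guards against local minima. A fit whose modelled transition
amplitude is below three residual standard deviations is flagged
unidentifiable. For biphasic curves (the KD4 design shows a tight small
first phase before the capture transition) a fitting window can be given
explicitly or chosen automatically as the injections after the first
heat-slope sign change; with the default 50 µM chaperone excess the first
phase is small and the windowed one-site fit recovers the generating kd4
to within ~5% noiselessly, converging monotonically to kd4 as the excess
grows.

**What the designs recover.** The KD3 and KD4 designs are consistent
estimators in this model: noiseless fits land within 1% and ~5% of the
generating constants, with stoichiometry 1. The KD2 (displacement) design
is not: at full equilibrium the displacement constant is
`kd1/kd2 = kd3/kd4 < 1` for every measured constant set, so peptide cannot
quantitatively displace the chaperone and the fitted apparent kd is a
composite well above the true peptide/empty-MHC constant, with
stoichiometry near 1 rather than the sub-stoichiometric values real
displacement titrations show. That experimental signature reflects slow
chaperone rebinding — kinetics, which this package deliberately does not
model (all assays are treated as read at equilibrium; no on/off rates, no
time courses). The pipeline therefore reports the KD2-design fit as the
apparent composite it is, and closure-inferred kd1 values from pipeline
fits inherit that composite character; exact closure inference from
*measured* constants (the headline computation) is unaffected.

**Enthalpy defaults.** The study reports no per-step enthalpies. The
generator's declared defaults are dh2 = −10 kcal/mol (peptide burial in
the groove, strongly exothermic), dh3 = −8 (protein–protein association),
dh1 = −2 (chaperone binding to empty MHC-I taken as largely
entropy-driven), and dh4 = −16 by Hess closure. A small |dh1| also keeps
the displacement design observable (net displacement heat dh2 − dh1); a
|dh1| close to |dh2| would make that design nearly athermal.

## Polarization assays

The tracer is a labelled peptide; polarization mixes linearly in the
fraction of tracer inside any MHC-containing complex (binary MP and
ternary MPT both count as bound: both are slow-tumbling ~100 kDa species,
and polarization reports rotational correlation, not identity). Readings
are background-subtracted against tracer alone, so the noiseless signal is
`(mp_bound − mp_free) · bound_fraction` with fixed defaults mp_free = 20,
mp_bound = 200, plate noise 2 mP.

Competition plates use the published concentration grids as named presets
(13-point substoichiometric grid to 5 µM; 14-point stoichiometric grid to
100 µM with 1 µM excess chaperone) around 1 nM tracer and 50 nM complex.
IC50s come from a four-parameter logistic in log10 concentration with free
top/bottom, Hill slope bounded to [0.5, 3], and multistart over the
midpoint; zero concentrations enter at a floor of one tenth of the
smallest nonzero grid point. The published fitting constraints are
unknown; these are declared choices, not inferences.

Two caveats on this module's scope, both consequences of the
equilibrium-only model:

* At 50 nM complex the stoichiometric bound fraction is a few percent
  (MT = 50 nM against µM-range kd4), so the transition amplitude is
  comparable to the 2 mP plate noise and single-run IC50 ratios under
  noise are statistically unstable. The regime-dissociation result (the
  stoichiometric IC50 fold-change of 2–3× between chaperone variants with
  the substoichiometric fold-change at 1) is therefore asserted on the
  deterministic forward curves: it is a statement about which cycle step
  governs which regime, not about plate-reader precision.
* The chaperone-titration assay (tracer + loaded pMHC-I, chaperone
  titrated in) reads kd3 experimentally because pre-loaded peptide is
  kinetically trapped. At equilibrium the 50 nM pMHC-I is substantially
  dissociated, and the titration midpoint is a composite proportional to
  kd1 — hence, through closure, linear in kd3 (doubling kd3 doubles the
  midpoint), but offset below it. The simulation uses the published
  composition and documents the composite.

## Thermal melts

Melts follow a two-state Boltzmann sigmoid
`f(T) = f_min + (f_max − f_min)/(1 + exp((tm − T)/slope))` on a 25–95 °C,
1 °C-per-step scan; T_m is the sigmoid inflection of the raw signal (not
of its derivative — a declared choice, since the published analysis tool
and functional form are unstated). Post-transition aggregation decay is
excluded: only T_m is consumed downstream. Fitting is least squares with
the amplitude parameterised as non-negative span; a transition amplitude
under three residual standard deviations is flagged unidentifiable. At 2%
amplitude noise the median absolute T_m error over replicates is well
under 0.3 °C. The stability–loading comparison regresses log10(IC50) on
T_m and reports slope, intercept and R².

## Selection scores and NMR metrics

Enrichment scores are ratio-form, wild-type-normalised:
`log2[(post+pc)/(pre+pc)] − log2[(wt_post+pc)/(wt_pre+pc)]`, with a
declared pseudocount default of 0.5 added to every count; the wild-type
entry at each position is exactly 0 by construction. (A
regression-over-timepoints scoring variant is not implemented; only the
two-timepoint ratio form.) Per-position conservation is the mean over the
non-wild-type, non-stop substitutions (min and median selectable); stop
codons stay in the score tables but never enter conservation. Methyl
chemical-shift deviations combine proton and carbon shifts as
`sqrt(0.5·(ΔδH² + ΔδC²/4))`; probes are classified affected when CSD
exceeds mean + 1 sd or the bound/free intensity ratio falls below
mean − 1 sd, with population (n-divisor) standard deviations — declared,
since the convention is unstated — and probes broadened beyond detection
flagged affected by convention. Peak lists are read from whitespace
(assignment, w1, w2, height) or tidy CSV dialects; count tables are TSV.

## Synthetic data

The generator emulates the study's measurement conditions: isotherms at
the three titration geometries above with Gaussian heat noise (default
0.1 µcal per injection), competition plates on the published grids with
Gaussian 2 mP noise, Boltzmann melts with noise at 2% of amplitude, and
single-substitution libraries with multinomial counts at configurable
depth (default 1e5 reads per timepoint), where post-selection frequencies
are proportional to pre-frequency × 2^fitness. Noise-model shapes are
declared defaults — the study reports none. Sorting-based selection is
abstracted into the latent-fitness exponent; no cell-level simulation, no
simulated NMR spectra (peak lists are generated directly in shift space),
no read processing upstream of count tables.

All randomness flows from integer seeds through per-output child seeds
derived with CRC-32 of the output's name (process-independent), so
identical configs produce byte-identical files. Ground truth is written
alongside every bundle so downstream recovery can be asserted.

What passing synthetic tests do *not* show: robustness to baseline drift,
injection kinetics, photophysics, aggregation tails, sequencing bias, or
any kinetically limited behaviour — the three places where the package's
equilibrium assumption departs from the real assays are the KD2
displacement stoichiometry, the FP chaperone-titration midpoint, and the
stoichiometric FP signal amplitude, each documented above.

## Pipeline and reporting

`workflow.run_pipeline` chains generation, refitting from disk, cycle
assembly and fold-change computation, deterministically per seed, and
writes a JSON report with every fitted constant, closure residual and
recovery check plus a long-form cycle-summary CSV (one row per peptide ×
step × variant, kd in nM with standard error and observed stoichiometry,
kd1 marked inferred). Recovery checks use the tolerances the estimators
support: 15% for kd3, 25% for kd4, 0.5 °C for T_m under default noise.
Uncertainty on closure-inferred kd1 is first-order on the log scale
(relative variances of the three inputs add); the published table gives no
propagation rule, so this is the package's declared one.

Problem sizes throughout (28-injection titrations, 13/14-point plates,
71-point melts, 1e5-read libraries, 50–100 replicate recovery runs) are
the study's own designs or modest multiples chosen so the full suite runs
in well under a minute of compute per module.

## Known limitations

No kinetics anywhere (the single largest divergence from the real
system, detailed above). No Bayesian joint fitting across assays. No
structural modelling, no spectra, no read processing. The apparent
constants the pipeline extracts from the KD2 design are composites by
construction and should not be compared directly to true kd2 values.
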