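# Methods

## The model

The *de novo* pyrimidine biosynthesis pathway of *S. cerevisiae* is
represented as nine dynamic metabolite concentrations (mM):

    cp → ca → dho → oro → omp → ump → udp → utp → ctp

with the enzymatic steps CPSase (the carbamoyl-phosphate-synthetase
activity of URA2), ATCase (its aspartate-transcarbamylase activity),
URA4 (dihydroorotase), URA1 (dihydroorotate dehydrogenase), URA5
(orotate phosphoribosyltransferase, representing the URA5/URA10 isozyme
pair), URA3 (OMP decarboxylase), URA6 (UMP kinase), YNK1 (nucleoside
diphosphate kinase), and URA7 (CTP synthase, representing URA7/URA8).

Every reaction is irreversible Michaelis–Menten: the flux is the
product of a vmax (mM/hr) and one saturable factor s/(K + s) per
substrate.  Four substrate pools — bicarbonate, glutamine, aspartate,
ATP — are clamped at fixed concentrations, which are themselves model
parameters.  CPSase carries a noncompetitive UTP feedback inhibition
factor K_utp/(K_utp + utp).  Pyrimidine consumption for RNA synthesis is
a saturable drain g_pyr·s/(K_Mp + s) applied to UTP and CTP.  Every
dynamic species is diluted at the cell growth rate d (default 0.11/hr,
matching the chemostat conditions under which the target metabolite
concentrations were measured).  The time derivative of each species is
its enzymatic inflow minus outflow minus d·X.

Structural choices that the parameter table leaves open are exposed as
configuration flags rather than hard-coded:

- **UTP inhibition scope.** Both URA2 activities are reported to be
  UTP-inhibited, but the single K_utp constant is catalogued under the
  CPSase block; by default the factor multiplies CPSase only
  (`utp_inhibits_atcase=True` extends it to ATCase).
- **The second ATCase constant.** The table lists both K_asp and K_m2
  against aspartate; the default reads K_m2 as the carbamoyl-phosphate
  Michaelis constant of the bi-substrate ATCase rate (the reading used
  by the *E. coli* template this model descends from), with a flag for
  the two-aspartate-constants reading.
- **Drain targets.** The utilization drain applies to UTP and CTP by
  default; the species list is configurable.

With the defaults, the model evaluated at the published optimized
parameter values reproduces the published steady state within 10 % for
all nucleotides (UMP 0.405 vs 0.42 μM, UDP 2.82 vs 2.9, UTP 6.32 vs 6.7,
CTP 679 vs 750), reproduces the sign of all 28 published sensitivities,
and reproduces the published rank correlations to three figures — strong
evidence that the default reconstruction matches the original rate laws.
The one exception is orotate, whose published steady state is ~6× ours;
the original OPRTase law most likely carried a PRPP co-substrate factor
for which no second Michaelis constant is tabulated.  Orotate does not
enter any reported quantity (sensitivities are normalized on UMP and
ranks are unchanged), so the single-substrate form is kept.

## Steady states

`steady_state` integrates the stiff ODE system (LSODA) from a small
positive state (10⁻⁶ mM per species) until the relative rate of change
falls below 10⁻⁹/hr, then polishes the algebraic system in
log-concentration space with a quasi-Newton root solve.  Working in log
space enforces positivity without clipping; acceptance is judged by the
achieved residual ‖dX/dt‖∞ < 10⁻¹⁰ mM/hr rather than the solver's
progress flag (which can report failure when started at the solution
itself).  A warm-start state can be supplied, in which case integration
is skipped unless the polish fails.  The result carries the Jacobian
spectrum; a steady state with any eigenvalue real part ≥ 0 is flagged.
Pure long-time integration and integrate-then-polish agree to better
than 10⁻⁶ relative on all nine concentrations (tested).

## Calibration

The objective is the sum of a data term and a prior term.  The data term
compares steady-state UMP/UDP/UTP (converted mM → μM) to the chemostat
targets (0.37, 2.9, 6.7 μM) with a shared scale of 2.5 μM.  The prior
term penalizes (ln p − ln p₀)² divided by ln 1000 for the 23 measured
parameters and ln 10⁷ for the 5 parameters (vmax3, K_m3, K_m6, g_pyr,
K_Mp) referenced only to the *E. coli* model.  The penalties are
implemented exactly as stated, with no ½ factor.

Because the objective is a sum of squares, each local optimization is a
trust-region least-squares solve (`scipy.optimize.least_squares`, TRF)
in log-parameter space, which keeps all 28 parameters positive without
constraints.  A single-stage solve, however, is unreliable: at
low-throughput parameter sets the model nucleotide concentrations are
orders of magnitude below the μM targets, the exact residuals are
numerically flat (their gradient, ~10⁻⁴, is smaller than the prior
curvature), and descent stalls at a degenerate stationary point near the
prior mode.  Each local run therefore solves in two stages: first with
the delta-method surrogate residuals ln(X/t)·t/σ — identical to the
exact residuals to first order near the targets, but with an O(1)
gradient everywhere — then a polish on the exact residuals from the
stage-one endpoint.  Reported costs are always the exact ones.  With
this scheme every random start tested converges to the same optimum
(total cost 4.78613361), consistent with the pathway's single-global-
optimum behaviour; the multistart ensemble's parameter CVs are ~10⁻⁵.

Starts are drawn log-normally around ln p₀ with standard deviation
√(denominator/2) per penalty class (so the start spread tracks the prior
width); a log-uniform alternative over ±3 / ±7 decades is available.
Steady-state failures inside the objective map to a large finite penalty
(10⁹ split over the data residuals) plus the prior term, so optimizers
can retreat along the prior gradient.  Runs are limited to 5000
evaluations per stage and marked unconverged beyond that.

Ensemble diagnostics over converged runs: coefficient of variation
(sd/mean, natural scale) per parameter; per-enzyme influence standard
deviation; and the mean pairwise Spearman correlation of the
per-member influence rank vectors.

## Sensitivity and influence

The sensitivity of a parameter is the normalized first derivative of
steady-state UMP, (d[ump]/dp)·(p/[ump]), computed by central finite
differences with a step of 1 % of the parameter value; both perturbed
solves are warm-started from the unperturbed steady state, and halving
the step changes every sensitivity by < 1 % (tested).  Per-enzyme
influence is the geometric mean of the *absolute* sensitivities of the
enzyme's parameters: member signs differ within an enzyme (vmax and Km
sensitivities are nearly antisymmetric), so the absolute value is the
only well-defined aggregation.  A sensitivity of exactly zero is floored
at 10⁻¹² with a warning.  g_pyr, K_Mp, and the four clamped pools belong
to no enzyme and are reported but never aggregated.

## Rank correlations

Spearman correlation uses average ranks for ties and is the Pearson
correlation of the rank vectors.  Two-sided p-values come from exact
enumeration of all n! permutations of one rank vector for n ≤ 10 (the
null distribution is cached per rank pattern, so replicate-heavy
simulations reuse one enumeration) and from the t-approximation with
n − 2 degrees of freedom otherwise.  The partial correlation
rank-transforms both variables and each covariate, regresses the two
rank vectors on the covariate ranks (with intercept), and correlates the
residuals, with p from the t-distribution at n − 2 − k degrees of
freedom.  Both methods are cross-checked against independent
implementations (scipy's rho; pingouin's partial Spearman) in the test
suite.

The default dN/dS values are the per-activity 1-ratio codon-model
estimates (CPSase 0.01, ATCase 0.02, URA3 0.04, URA1/URA7/YNK1 0.05,
URA6 0.11, URA4/URA5 0.14).  The "core" subset is {CPSase, ATCase, URA4,
URA1, URA5, URA3} — the linear pathway through UMP synthesis, excluding
the downstream kinase/synthase arm.

## Synthetic scenarios

The generator emulates the three external inputs of the analysis:

- **Ground-truth parameters**: log-normal draws around the reference
  values with a spread given in decades of log10(p/p₀).
- **Observations**: steady-state UMP/UDP/UTP (μM) plus Gaussian noise,
  redrawn until positive; the emitted scale is max(noise_sd, 10⁻³ μM).
  The default noise (0.5 μM in the CLI fixture) is of the order of the
  smaller targets; 2.5 μM replicates the chemostat error scale.
- **dN/dS**: ω = exp(−β·rankscore(influence) + ε) rescaled into
  [0.01, 0.2] (the span of the real per-activity estimates); β = 1 with
  ε = 0 gives a perfect negative rank correlation with influence, β = 0
  an influence-independent null.
- **Covariates**: log-normal expression (~2000 molecules/cell, ±2
  decades) and uniform mean solvent accessibility (0.2–0.5), with an
  optional log-linear coupling of expression to ω.

All stages draw from named sub-streams of one master seed.

What the synthetic tests do and do not show: with three steady-state
observations, only parameter *combinations* (e.g. the CPSase saturation
ratio atp/K_atp) are identified; individual-parameter recovery within a
factor of 2 is therefore asserted for ground truth drawn 0.1 decades
around the priors — inside the identifiable neighbourhood — while larger
perturbations are recovered only up to prior shrinkage along sloppy
directions.  The end-to-end recovery check (fit → sensitivity →
correlate at β = 1) replicates the dN/dS generator draws around one
fitted scenario rather than refitting per replicate: the fit is
deterministic given the scenario, and start-to-start optimizer variation
is separately bounded at ~10⁻⁵ by the ensemble CVs.  None of this
emulates real measurement structure beyond the three targets (no
correlated errors, no day effects), so passing tests demonstrate the
machinery, not robustness to real chemostat data pathologies.

## Numerical choices

- Steady-state tolerance ‖dX/dt‖∞ < 10⁻¹⁰ mM/hr; integration plateau
  criterion 10⁻⁹/hr relative; log-state clamped to [−700, 300] during
  root exploration so exp cannot overflow.
- Optimizer tolerances ftol 10⁻¹⁰ / xtol 10⁻¹⁰ (exact stage), ftol 10⁻⁸
  (surrogate stage); maximum 5000 evaluations per stage.
- Finite-difference step h = 0.01 (exposed, capped at 0.05, for
  convergence testing only).
- Exact-permutation p-values compare |ρ| with a 10⁻¹² slack so ties at
  the observed value count as at-least-as-extreme.
- TSV floats are written with %.17g and read with round-trip parsing, so
  parameter and state tables round-trip bit-exactly.

## Problem sizes

The test suite runs a 25-start calibration ensemble, a 3-start recovery
fit, 50 generator replicates for the end-to-end check, and 10³
replicates for the null-calibration check; the acceptance script runs
the full 100-start ensemble.  These sizes are the package's defaults for
desk-scale reproduction; the multistart size is an argument everywhere.

## Known limitations

- The uracil salvage pathway, UDP→dNTP channeling, transcriptional
  regulation, and the mitochondrial DHODH variant of other yeasts are
  not modeled, matching the scope of the original analysis.
- The OPRTase step uses a single-substrate law (no PRPP factor); see
  above for the one concentration this affects.
- dN/dS values are consumed as given; no codon-model estimation is
  performed.
- The SBML export writes the constructs this model uses (L3V1 species,
  parameters, reactions with MathML kinetic laws, dilution sinks); it is
  not a general-purpose SBML writer.
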