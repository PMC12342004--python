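# Methods

## Model structure and assumptions

The disposition model tracks losartan through four compartments — stomach,
small intestine, central (plasma) and peripheral — and E-3174 in its own
central compartment. All seven reactions are first order, so the system is
linear in dose; this underpins the dose-linearity used to construct the
25 mg and 100 mg exposure anchors without re-simulation.

**Gastric emptying.** Stomach-to-intestine transfer is modulated by
`r(t) = a·(1 + sin(b·t))/2`, a non-negative sinusoid with period `2π/b`
and time-average `a/2` that mimics the open/close cycling of the pyloric
valve during the migrating motor complex. `b` is fixed at 3.95 rad/h,
giving a ~95 min period inside the physiological 85–115 min cycle range;
`a` is calibrated. The phase convention (valve half-open at t = 0) is a
modeling choice; the function is a single injectable component
(`pyloric_rate`) so an alternative phase or waveform can be swapped in
without touching the integrator.

**Metabolite delay.** Conversion removes losartan from the central
compartment at rate `k_m·A_c(t)` but the metabolite appears a fixed
transit time `T` later, as `k_m·A_c(t−T)`. The delay applies to the
formation term only; mass converted is therefore "in transit" for `T`
hours (verified numerically by the delay-bookkeeping test). Pre-dose
history is identically zero, which makes plasma E-3174 exactly zero on
`[0, first dose + T]`.

**Bioavailability.** There is no explicit F; all volumes and clearances
are *apparent* (F-scaled), and losartan leaves the system only through the
seven modeled reactions.

**Dose units.** "50 mg losartan potassium" is converted to amount with the
salt's molar mass 461.0 g/mol (≈ 108,460 nmol); the constant is
configurable since different salt/base conventions shift all
concentrations proportionally (and are absorbed by the apparent volumes
during calibration).

## Numerical solution

The delayed metabolite state does not feed back on the parent states, so
the delay equation is solved exactly as a cascade: the 4-compartment
parent subsystem (plus its AUC state) is integrated first with dense
output, restarting at dose events (instantaneous additions to the stomach,
or optionally the intestine for degenerate-limit checks); the metabolite
equation is then integrated against the interpolated, delayed parent
history, with breakpoints at dose times and dose times + T where the
forcing has kinks. This is a method-of-steps scheme in which every step
can read the already-completed parent solution. Integrator: LSODA
(stiff/non-stiff switching) at rtol 1e-8 / atol 1e-10; output grid 2401
points over 24 h (0.01 h, the resolution limit of reported tmax values).
Solver-level negative dust in amounts is clipped at zero; violations
beyond 1e-6 of the dose raise an integrity error.

## Reference parameters

Shared across genotypes (only `k_m` varies):

| symbol | meaning | unit | value |
|---|---|---|---|
| a | pyloric-flux amplitude | 1/h | 4.548 |
| b | pyloric-flux angular frequency | rad/h | 3.95 (fixed) |
| k_a | intestinal absorption rate | 1/h | 4.338 |
| T | conversion transit delay | h | 0.745 |
| CL_p | apparent losartan clearance | L/h | 30.53 |
| CL_m | apparent E-3174 clearance | L/h | 17.53 |
| Q | inter-compartmental clearance | L/h | 112.6 |
| V_p1 | losartan central volume | L | 53.2 |
| V_p2 | losartan peripheral volume | L | 112.7 |
| V_m | E-3174 central volume | L | 58.4 |

These were calibrated (weighted relative least squares, Nelder–Mead in log
space) against the reference per-genotype PK metric table (Cmax, tmax,
t1/2, AUC of both analytes for all six diplotypes after a single 50 mg
dose), weighting most heavily the wild-type losartan Cmax and half-life,
the wild-type metabolite exposure, and the `*3/*3` losartan exposure and
AUC ratio. The full metric table cannot be matched exactly by any single
parameter set under the stated sinusoid and delay conventions (for
example, the reference table reports the same losartan Cmax for all six
genotypes while `k_m` spans 0.025–1.056 1/h), so the remaining metrics
carry lower weight and show residual misfit of up to ~10% (losartan AUC in
fast-converting genotypes) and ~0.2 h (tmax).

Genotype conversion rates: homozygotes carry the calibrated constants
(1.056, 0.823, 0.025 1/h); heterozygotes the arithmetic mean of their two
homozygote rates, justified by first-order kinetics with each allele
contributing half the enzyme pool.

## PK metrics conventions

* **Cmax/tmax** are read off the dense output grid; ties break to the
  earliest time; an all-zero profile returns Cmax 0 with a degenerate flag.
* **AUC** is the terminal value of the AUC state variable integrated
  alongside the amounts (0–24 h, the span of the sampling schedule; no
  extrapolation to infinity by default). For observed arrays the trapezoid
  rule is used instead.
* **AUC ratio** is piecewise: 0 while the delayed metabolite has not
  appeared, `AUC_p/AUC_m` otherwise.
* **Terminal half-life** is ordinary least squares of ln C on t. Because
  the source data never state which points defined "the terminal linear
  part", the default window is the last 3 scheduled sampling times with
  positive concentration (all after tmax), extended backwards point by
  point while the semilog fit keeps R² ≥ 0.98; the window used is part of
  the output.

## Exposure–effect (E-max) link

`k_block = Emax·AUC^α/(ED50^α + AUC^α)` with three unknowns is fitted
*exactly* through three anchors: at fixed α, Emax and ED50 are closed form
from two anchors; α is then found by bracketed root-finding (Brent) on the
third anchor's residual, using the overflow-safe logistic-in-log form. For
more than three anchors the solver falls back to bounded least squares
seeded by the exact three-anchor solution. The anchors are the 25/50/100 mg
exposures (0.5×/1×/2× the 50 mg wild-type AUC_E-3174 = 3996.6 nmol·h/L, by
dose linearity) with blocking coefficients 0.1, 0.886 and 0.954. Fitted
coefficients: Emax 0.9547, ED50 2741.5 nmol·h/L, α 6.785. The curve is
exactly 0 at zero exposure.

## Calibration and identifiability

The objective is the unweighted pooled sum of squared concentration
residuals over all datasets and analytes (optional relative weighting is
available but off by default); inequality constraints enter SRES through
stochastic ranking and the scalar `objective()` through a quadratic
penalty (weight 1e3 by default). Simulation failures inside the optimizer
return a large finite sentinel (1e12) rather than raising.

SRES defaults are λ = 140 offspring, μ = 20 parents, Pf = 0.45, with
log-normal self-adaptive step sizes (τ = 1/√(2√n), τ′ = 1/√(2n)) and
non-elitist (μ, λ) selection; the best feasible individual ever seen is
reported. Runs are bit-reproducible under a fixed seed.

Identifiability profiling fixes one parameter on a multiplicative grid
(default 15 log-spaced points spanning ×0.25 to ×4 around the optimum),
re-optimizes the rest with a reduced-budget, warm-started SRES, and
classifies by whether the re-optimized objective exceeds
`1.05 × optimum objective` on both sides (identifiable), one side
(partially identifiable) or neither (unidentifiable). The 5% threshold and
the optimum-relative reading are configurable; an absolute floor (1e-12)
handles the exactly-zero optimum of noiseless data. The test suite runs
this scan at deliberately small problem sizes — two noisy wild-type
subjects, a 4-point grid, refits with λ = 18 over 25 generations — which
the structure of the problem tolerates because the objective rises by
factors of 1.1–50× at the grid edges, far above the 5% threshold.

## Synthetic data

The generator emulates the clinical sampling design: 11 samples at 0, 0.5,
1, 1.5, 2, 4, 6, 8, 10, 12 and 24 h after a single 50 mg dose. Noise is
proportional log-normal with a subject-level multiplicative random effect
(default CV 0.5, mid-range of the 28–73% between-subject SDs reported for
these profiles) plus per-observation log-normal noise (default CV 0.1);
values below a configurable quantification floor are reported as 0.
What it does **not** emulate: inter-subject kinetic heterogeneity (every
subject shares the true curve shape; only amplitude varies), circadian or
food effects on gastric emptying, and assay-specific error structure —
so recovery tests certify the estimation machinery, not robustness to
structural misspecification in real data.

Virtual cohorts draw baseline pressures from truncated normals (SBP
158 ± 11 mmHg in [140, 185], DBP 96 ± 7 in [85, 115], pulse pressure
≥ 20 mmHg by rejection) — deliberately simple stage-1/2 hypertensive
ranges — and genotypes either fixed, from an explicit mix, or by
Hardy–Weinberg sampling from the bundled allele-frequency table (10
ethnicity groups).

**Blood-pressure surrogate.** The mechanistic cardiorenal model that
originally produced cohort responses is out of scope here. In its place a
reduced-order surrogate maps `k_block` to expected ΔSBP/ΔDBP through a
monotone PCHIP interpolant through pre-calibrated anchors, with a
patient-level responder effect (relative SD 0.17 systolic / 0.10
diastolic, shared between pressures) and a small additive floor
(0.009/0.003 mmHg). The anchor values *are* the reference per-genotype
cohort means, so cohort-level agreement with them is circular by design:
the surrogate supports ordering, contrast and pipeline demonstrations
only, and is labelled as a surrogate in code, outputs and here. Group
contrasts use the unpaired Student's t-test (pooled variance, closed-form
statistic) with a Bonferroni cutoff of 0.05/6 for six-genotype
comparisons.

## Degenerate inputs and edge cases

Zero dose gives identically zero concentrations; `k_m = 0` gives zero
metabolite; zero clearances give a closed, mass-conserving system (used by
the conservation tests); `Q = 0` decouples the peripheral compartment,
reducing losartan kinetics to the one-compartment Bateman form; `T = 0`
reduces the delay system to a plain ODE (cross-checked against an
independent ODE integration). Rates and clearances may be zero but
volumes, `a` and `b` must be strictly positive.

## Known limitations

* Single-dose scenarios only; no steady state, enterohepatic
  recirculation, or the E-3179 aldehyde intermediate (conversion is
  collapsed into one delayed step).
* The reference parameter set is one point in a weighted-fit trade-off;
  non-headline metrics (notably losartan AUC in extensive metabolizers and
  both tmax values) deviate from the reference table by up to ~10%.
* Rare CYP2C9 alleles (*5, *6, *8, *9, *11, *13), CYP3A4 contribution and
  transporter (ABCB1) polymorphisms are not modeled.
* The blood-pressure surrogate is non-mechanistic and valid only near its
  calibration anchors; per-genotype response SDs are approximated by a
  single relative-SD pair and are less accurate for low-activity
  genotypes.
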