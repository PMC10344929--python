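# Methods

`idrflex` implements the computational core of an integrative structural
analysis of a disordered ion-channel region: random-chain ensemble
generation with SAXS-driven sub-ensemble selection, residue-level HDX
mapping, crosslink validation, a set of spectroscopic analysis
equations, and post-processing of membrane-tether simulations.  This
note records the models, defaults, numerical choices and limitations.

## Chain model

Disordered segments are modelled as one bead per residue on a virtual
Calpha trace.  Consecutive beads sit at a fixed virtual bond of
0.38 nm; the pseudo bond angle between successive bonds is drawn
uniformly from 65-165 degrees (a coarse stand-in for the
Ramachandran-compatible range of Calpha pseudo-angles) with a uniform
dihedral; non-bonded beads may not approach within a hard excluded
diameter of 0.40 nm.  Growth uses up to 100 placement attempts per bead
with single-bead backtracking and an explicit failure when the total
budget is exhausted.  The resulting walks scale as mean Rg ~ b N^nu
with nu ~ 0.57 (checked in the tests over N = 16-128), i.e. genuine
self-avoiding-walk statistics rather than ideal-chain scaling.  All
three geometry parameters are exposed on `ChainParams`.

Chains can be grown off a rigid anchor (a Calpha trace read from a PDB
file, or the synthetic compact anchor provided for testing).  Anchor
coordinates are carried through bitwise unchanged; new beads are
clash-checked against every anchor bead with the same excluded
diameter.  Units are nm internally; only the crosslink interface speaks
Angstrom, because crosslinker spans are conventionally quoted that way
(33 A lysine-lysine Calpha distance for DSS, checked at a 30 A cutoff
against the minimum over conformers).

## SAXS forward model and analyses

Scattering of a bead chain uses the Debye sum with unit form factors,
so I(0) = n^2 and ensemble profiles are volume-fraction weighted
averages (linearity is a tested invariant).  Unit form factors omit
solvent and excluded-volume contrast; this is adequate for the low-q
shape information that drives ensemble selection but is not a
CRYSOL-grade predictor at wide angles — a deliberate limitation.

* **Guinier fit** — weighted linear regression of ln I on q^2 with the
  window tightened iteratively until q_max Rg <= 1.3 (the limit
  appropriate for flexible particles); at least five points must
  remain and a non-negative slope is an explicit failure.  On coil-like
  profiles the 1.3 window carries the known few-percent downward bias
  relative to the true ensemble Rg; the p(r) moments are the better
  estimator and the two are required to agree within 5% in the tests.
* **p(r) inversion** — cubic B-spline expansion on [0, Dmax]
  (3 knots/nm) with the first and last basis functions dropped so
  p(0) = p(Dmax) = 0, fitted by weighted least squares with a
  second-derivative roughness penalty and iteratively escalated soft
  nonnegativity.  The weighted data vector is normalized before
  solving, making every output invariant to a common rescaling of I
  and sigma and the regularization weight dimensionless; alpha is
  chosen by an L-curve-style rule (largest alpha whose chi^2 stays
  within 10% of the least-smooth fit) unless given.  Dmax selection
  inverts once on the generous end of the scan range and takes the
  largest r where the recovered distribution still exceeds 1% of its
  peak — a decay criterion that is robust where chi^2 differences
  between long supports fall below the sampling scatter of a reduced
  chi^2 (sqrt(2/n)); the transform is then re-solved on the detected
  support.  On the analytic sphere this recovers Rg to <0.5% and Dmax
  to ~4%; the pointwise-decay definition inherently reads a few
  percent short for distributions that meet zero with vanishing slope.
* **Reduced chi^2** — optimal scalar intensity scale fitted
  analytically per comparison (experimental intensity scales are
  arbitrary), divided by n minus the parameter count (the scale by
  default).
* **CorMap** — longest run of same-sign residuals over the full q
  range as a single window; the one-tailed p-value is exact, computed
  from the composition-count recurrence for runs in fair two-letter
  sequences and verified against exhaustive 2^n enumeration for all
  n <= 16.  Residuals within 1e-10 of the data scale count as ties and
  inherit the previous sign; an all-zero residual vector returns p = 1
  with a flag.
* The text reader treats files whose largest q is below 1 as
  Angstrom^-1 and converts to nm^-1, with an explicit override.

## Ensemble optimization

A chromosome is a multiset of `ensemble_size` pool indices (repeats
encode volume fractions), fitness is the scale-free reduced chi^2 of
the weight-averaged profile.  Defaults: ensemble size 10, population
100, 300 generations, crossover 0.8, per-gene mutation 0.1, elitism 2
— all exposed, since the underlying method leaves these to the tool.
Two refinements make planted solutions recoverable at low noise where
a plain GA stalls in chi^2-equivalent local minima: half the initial
population consists of homogeneous chromosomes of the best-fitting
single members, and the final answer is polished by exhaustive
single-slot coordinate descent started from the GA optimum and from
homogeneous chromosomes spanning the pool's Rg range.  Both can only
lower chi^2, so the best-ever fitness trace remains monotone (a tested
invariant, as is "selection chi^2 <= best single member").  Pool-vs-
selected Rg comparison reports the weighted mean shift (negative =
data prefer compaction) and the Kolmogorov-Smirnov distance between
the weighted selected and unweighted pool distributions.

## HDX mapping

Residue-level uptake uses the shortest-covering-peptide rule with
length ties broken by the peptide whose C-terminus is nearest the
residue; the winner for every covered residue is re-verified against a
brute-force implementation on randomized layouts in the tests.  Each
peptide's first residue and all prolines are exchange-incompetent and
excluded from coverage (the standard back-exchange convention); a
strict-literal mode includes first residues.  Coverage percentages are
computed over raw residues by default — the convention that matches
whole-region coverage figures — with a competent-residue mode
available; the mode is part of the result.  Disorder classification is
deliberately literal: uptake strictly above 50% at the 10 s timepoint
and no consecutive increment strictly above 5%; both boundary cases
are pinned in tests.  Percent uptake is the canonical unit throughout.

## Spectroscopy equations

All eight analyses are closed-form or single-fit operations: the SEC
log-linear calibration and inversion; the MALS molecular weight with
dn/dc defaulting to 0.185 mL/g; mean residue ellipticity with
MRW = MW/(N-1); the amide chemical shift perturbation with nitrogen
scaling 6.5; signed relative intensity change (signal loss is negative,
-1 is complete broadening) with an intensity-ratio mode; the
single-exponential relaxation fit, accepting R2 series as loop counts
at 16.96 ms per loop and shipping the standard 12-delay schedules; the
hetNOE ratio; the 320-380 nm intensity-weighted mean emission
wavelength; and the Langmuir isotherm with the accessible lipid
concentration defaulting to half the titrated concentration (outer
leaflet only), which makes fitted Kd values exactly 2x smaller than a
whole-lipid analysis — a tested identity.  The published calibration
standards print Stokes radii with "nm" units at Angstrom-scale
magnitudes; values here are stored and returned in Angstrom and the
discrepancy is documented rather than propagated.  Prolines and
unassigned residues are carried as missing, never zero.

## Trajectory analyses

`TrajectorySlice` is a plain in-memory container (frames x beads x 3,
nm, times in microseconds) fed either from a CSV frame table or from
standard trajectory formats through an optional MDAnalysis loader.

* **Membrane contacts** — a contact is a lipid bead within the cutoff
  (default 0.6 nm, the coarse-grained bead scale; no published value
  exists, so it is config-exposed and reported with every output) of
  any bead of a residue; per-frame counts (or a binary mode) are
  averaged over the analysis window, optionally restricted to one
  lipid type.
* **Restraint forces** — recomputed from bead heights and the force
  constant, k (z_target - z), converted at 1.66054 pN per kJ/mol/nm,
  so any trajectory source works without engine pull logs.  Curves
  aggregate replicate means per (condition, target height) with
  SEM = Bessel-corrected SD of replicate means / sqrt(n); the
  effective force constant is the SEM-weighted least-squares slope of
  force on mean height beyond 6.5 nm (config), with a ratio utility
  for comparing conditions.
* **Axial RMSF** — frames are Kabsch-aligned on a selection, the
  channel axis is recomputed per frame as the normalized cross product
  of two inter-subunit vectors, positions are projected on it and the
  RMSF is the square root of the projection variance, averaged over
  the four subunits with SEM = Bessel SD / 2.  Frames with a
  degenerate axis are dropped and counted.

## Synthetic data and what passing tests show

Every generator records ground truth sufficient to predict the
downstream result analytically.  The SAXS generator adds Gaussian
noise with a configurable q-dependence to known mixture profiles; the
HDX generator uses D(t) = 100 (1 - exp(-k_int t / P)) with a single
constant intrinsic rate (sequence-dependent k_int tables are real but
unnecessary for known-truth testing) and peptide uptake as the mean
over competent residues; the titration and peak-list generators plant
isotherm parameters, shift deltas and intensity ratios directly.

The tether generator integrates an overdamped Langevin bead-spring
chain (Euler-Maruyama) whose terminus is harmonically restrained at a
set height, with a planted constant adhesion force on one site bead.
Because the stationary mean of the total force on the chain is zero,
the mean restraint force equals the planted force exactly, independent
of discretization — the oracle needs no membrane physics.  Reduced
units map to kJ/mol and nm with kT = 2.577 kJ/mol (310 K); soft
defaults (bond and restraint constants 50 kJ mol^-1 nm^-2, dt such
that k dt/gamma = 0.2) were chosen because the number of steps per
statistically independent force sample scales with the stiffest
constant, and stiffness buys no accuracy for a force-balance estimate.
When a force *law* F(h) is planted, the applied forces are solved so
the law holds against the equilibrium tether height (the restrained
bead sits F/k below its target), giving the slope fit an exact truth.
Batched replicate simulations share one lock-step integrator and one
noise stream keyed on all replicate seeds.

What the generators do not emulate: real SAXS detector artefacts,
inter-frame correlations and buffer-subtraction residuals; HDX
back-exchange, EX1 bimodality and sequence-dependent intrinsic rates;
NMR peak overlap; and any genuine membrane physics (lipid diffusion,
leaflet structure, force-field energetics) in the tether model.
Passing tests therefore demonstrate correctness of the analyses and
identifiability under the stated noise models, not instrument- or
force-field-level realism.

## Problem sizes

Test and acceptance runs use desk-scale versions of the production
workflow chosen once for statistical adequacy: conformer pools of
120-500 members (production pools of 10,000 are supported and only
cost linearly more), 50-60-residue chains, 20 optimizer seeds for the
mixture-recovery statistics, tether batches of 24-40 replicate
simulations at 1.2-2.4 million steps (empirically ~1-3% standard error
on a 10 pN planted force), and 1,000 randomized layouts for the HDX
rule oracle.

## Known limitations

* Dummy-bead Debye profiles ignore solvent contrast; chi^2 values
  against real detector data will differ from ATSAS-pipeline values.
* Dmax from the decay criterion is an analyst-style estimate with the
  usual few-percent softness; it is reported alongside the
  regularization weight so runs are reproducible.
* The GA is stochastic; determinism holds per seed, and multi-restart
  stability should be checked on real data (`ga_select_restarts`).
* Deposited experimental datasets (SAXS curves, peptide tables, the
  real channel sequence) are not shipped; tests that benchmark against
  published values look for user-supplied files under
  `data/reference/` and fail with instructions otherwise.  A clearly
  labelled synthetic stand-in sequence with the documented census
  properties supports all code paths.
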