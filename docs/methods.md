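# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute at run time.

## Alkylation kinetics and the pKa estimator

Model. The observed probe-incorporation rate at a given pH is

    k(pH) = k0 + sum_i k_lim,i / (1 + 10^(pKa_i - pH)),

the thiolate-fraction-weighted sum over independent ionization sites plus
a pH-independent background k0 (units min^-1 throughout; sampling times
in minutes, matching a plate read every 3 min for up to 90 min).

Curve family. Sample wells follow logistic growth
F(t) = f0 fmax e^{kt} / (fmax + f0 (e^{kt} - 1)), which starts at f0,
saturates at fmax, and satisfies ln F(t)/f0 = k t exactly in the early
phase. This family was chosen over a saturating exponential precisely so
that the ln(F/F0)-slope estimator is consistent; a saturating-exponential
alternative is available behind the preset's `curve_family` flag to probe
estimator robustness. Background wells (no protein) are flat at f0.

Plateau extraction. The per-trace fit uses the logistic
top/(1 + exp(-rate (t - mid))) with three free parameters; the reported
bottom (F0) is the fitted curve at the first sampled time. A free fourth
"bottom" parameter was deliberately not used: the generator's curve has a
lower asymptote of zero, so an unconstrained four-parameter logistic
would report that asymptote instead of the initial fluorescence of the
unreacted protein, which is the quantity the ratio F(t)/F0 needs.
Numerics: multistart (a data-driven guess plus two spread guesses),
unbounded Levenberg-Marquardt with an analytic Jacobian, then a
positivity-preserving (log top, log rate) reparameterization as fallback
for the top->infinity ridge of slow, plateau-free traces; a trace with no
statistically significant positive linear trend (OLS p >= 0.01)
short-circuits to the degenerate flat fit bottom = top = mean. If every
start fails, the bottom falls back to the mean of the lowest quartile and
the fit is flagged.

Early-phase window. ln(F_t/F0) is regressed on t over the contiguous
prefix with F_t <= bottom + 0.3 (top - bottom), minimum 4 points,
expanding to the first 6 points when the threshold leaves fewer. Inside
this window the logistic's log-slope is below the true k by up to ~25%
(the instantaneous slope is k (1 - F/fmax)); the bias is multiplicative
and nearly uniform across pH, so it is absorbed by the fitted limiting
rates and leaves the pKa estimates essentially unbiased — the property
the estimator actually needs. Traces whose fitted rise does not clear
five residual SDs are treated as flat and use the full time range; this
keeps background-well slopes from being estimated on a handful of noisy
early points.

Background correction and uncertainty. Per pH group, the mean background
raw slope is subtracted from every sample slope. Because that background
error is shared by all replicates in the group, its standard error is
propagated into the point SEM (added in quadrature to the replicate-mean
SEM); without this term the 1/SEM^2 weights grossly overstate the
precision of points whose three replicates merely agree with each other.
Per-well reported k_obs is clipped at zero (noise at near-zero rates),
but titration points carry the unclipped replicate mean so that null data
average to zero and the weighted fit stays unbiased.

Titration fit. Weighted (1/SEM^2; unweighted if any SEM is 0) nonlinear
least squares via lmfit, pKa bounded to [2, 12], multistart over a pKa
grid (3..11 step 1; ordered pairs for two sites). Model selection
compares 0-, 1- and 2-site fits by AICc; models within 2 units of the
minimum tie toward fewer sites. A warning is attached when two fitted
sites lie within 2 pH units, where inflexion points start to deviate from
the pKa values. Pooling is fit-per-experiment-then-average (mean +/- SD
across experiments), not a global fit, matching how replicate titration
experiments are conventionally summarized.

## Gel densitometry

Ratios are computed per lane and then averaged (never a ratio of group
means): biotin/vimentin for modification readouts, oligomer/monomer for
crosslinking. Percent inhibition is 100 (1 - ratio_treated/ratio_control)
and may be negative (enhancement, as with magnesium on DBB crosslinking);
it is never clipped. Group comparisons use two-sided Student's t-tests
(paired or unpaired per comparison; default unpaired); no multiple-testing
correction is applied. The spacer-length analysis pairs each thiol
crosslinker's inhibition with its spacer-arm length and reports the
Spearman rank correlation; ties across all agents yield a "flat" verdict
rather than an error. Band intensities are assumed background-subtracted
upstream; the module does not model gel background.

## Competitive zinc binding

Model: 1:1 Zn:Zincon stoichiometry and n independent, identical protein
sites — the minimal model supporting an affinity-range inference. The 1-D
mass balance in free zinc z is solved by Brent's method on [0, zn_total]
(xtol 1e-14; the bracket is guaranteed because the balance is -zn_total
at 0 and non-negative at zn_total). In stiff regimes (K_D far below the
totals) float64 cannot drive the balance residual below the gradient*eps
floor, so the remainder (relative size ~1e-7 or less) is assigned to the
dominant complex, making conservation exact. Absorbance is linear:
A620 = baseline + scale [Zn-Zincon].

Fitting calibrates scale/baseline by linear regression on the
protein-free curve (avoiding scale/K_P confounding), then fits log10 K_P
and optionally n to the with-protein curve by multistart bounded least
squares, holding the probe K_D fixed (default 214 nM, overridable).
Standard errors come from the Jacobian at the optimum (delta method for
K_P). A fit whose competition term adds nothing significant (extra-sum-
of-squares F-test, p > 0.05, or K_P at the 10 mM bound) is flagged
"non-competing" rather than treated as an error. All internal
concentrations are uM; probe K_D is accepted in nM with an explicit unit
tag.

## Structure geometry

PDB I/O goes through biotite; multi-MODEL files are frames of a
trajectory with fixed atom ordering, and elements missing from columns
77-78 are inferred from atom names. Distances are internal to a frame, so
no superposition is performed. The feasibility rule: a thiol crosslinker
can bridge two SG atoms iff their separation <= spacer_arm + slack, with
slack defaulting to 1.12 A so that the rule for the shortest crosslinker
(DBB, 4.88 A arm) reproduces the 6 A oxidative-crosslinking cutoff
exactly; disulfide formation is feasible below 6 A; amine-reactive agents
are reported "not applicable" for Cys pairs. Ion persistence counts the
fraction of frames whose minimum ion-to-protein-atom distance is within
the contact cutoff (default 3.0 A, covering a 2.5 A Zn-S coordination
bond with vibrational margin; "protein" = all non-HETATM atoms);
"persistent" is strictly > 0.9. Cutoff, slack and threshold are all
configurable.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the estimators assume:
triplicate kinetics wells on a 16-point pH grid from 3 to 10.8 with
measured-pH jitter (SD 0.03) and additive Gaussian fluorescence noise;
lognormal multiplicative band-intensity noise; Gaussian absorbance noise;
exact-geometry structure fixtures with seeded coordinate jitter. Defaults
encode the study conditions: the wild-type preset has two sites at pKa
4.61 and 7.39; the Cys-to-Ser preset has background only. Values the
source experiments do not pin down were fixed once as realistic choices
and surfaced in generator metadata:

* fluorescence noise SD 4 AU on an f0 = 50, fmax = 500 AU scale (~0.9% of
  the dynamic range, typical of plate readers);
* wild-type limiting rates 0.025 and 0.045 min^-1 with baseline
  0.002 min^-1, so alkylation progresses over the 90-min window at mid
  pH; mutant baseline 0.003 min^-1;
* band-intensity CV 0.06 — calibrated (before any acceptance run) with a
  10^4-draw Monte-Carlo of the ratio estimator so that the +/-8-point
  recovery tolerance used in the end-to-end checks corresponds to at
  least ~2.6 sampling SDs at n = 3 for every encoded magnitude; 6% is a
  realistic replicate densitometry CV;
* gel baseline ratios and agent concentrations per design row (arbitrary
  positive values; only directions and the two quoted inhibition
  magnitudes, 76% and 56%, are encoded);
* competition truth K_P = 0.5 uM with n = 2 sites (sub-micromolar, in the
  "nanomolar to micromolar" regime) and noise 0.0158 AU (2% of the
  noiseless dynamic range).

What passing tests therefore show: the estimators recover their
generating parameters under realistic noise, sample sizes and designs.
What they do not show: robustness to features real data have and the
generators lack — instrument drift and photobleaching, inner-filter
effects, gel background and saturation, buffer-specific artefacts,
correlated well noise, DTT chelation in the competition assay, and real
conformational heterogeneity. MD-derived statistics from the source
study (counts of persistent ions around an actual dimer, the 2.5 A Zn-S
bond as an observation) are not reproducible here and are covered only
by oracle-equivalence on synthetic fixtures.

## Problem sizes

Default study sizes were chosen to match the emulated experiments and
keep every analysis desk-scale: 3 experiments x 16 pH x 3 replicates for
the pKa pipeline; 20 seeds for selection-consistency and
affinity-recovery studies; 50 seeds for the recovery/robustness property
studies; 1000 random draws for solver-oracle agreement; 10-frame
trajectories for persistence.

## Known limitations

* The ln(F/F0) estimator is consistent only because the generator is
  logistic; on saturating-exponential data it underestimates k more
  strongly (exercised via the alternative curve family).
* With two ionization sites closer than ~2 pH units, inflexion points and
  pKa values separate; the fit warns but does not reparameterize.
* The competition model assumes independent identical sites and
  equilibrium; cooperative or kinetically limited binding would bias K_P.
* The feasibility rule is a rigid-geometry screen: it ignores side-chain
  flexibility, linker conformation and reaction chemistry beyond the
  thiol/amine distinction.
* Gel quantification assumes upstream densitometry has removed background
  and that intensities are linear in amount.
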