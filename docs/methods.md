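# Methods

`ligandtree` couples a mechanistic multi-receptor signaling model to a
bagged-decision-tree classifier.  The question it operationalizes: given
only a cancer cell line's receptor surface expression (EGFR, HER2, ErbB3,
Met, IGF-1R) and its KRAS/PIK3CA mutation status, can one predict whether
the line proliferates when exposed to a growth factor (EGF, HRG, HGF,
IGF-1)?  Receptor expression alone correlates poorly with response; the
model's role is a non-linear transformation of expression into simulated
signaling dynamics whose summary features are far more predictive.

## The signaling model

**Network.** Five receptors form ten dimers: the five homodimers plus
EGFR–HER2, EGFR–ErbB3, EGFR–Met, HER2–ErbB3 and ErbB3–Met.  The ErbB3
homodimer forms but cannot trans-phosphorylate (ErbB3 has no functional
kinase), so it carries zero pathway weight.  Two further heterodimers
(EGFR–IGF-1R, HER2–IGF-1R) exist as the `with_igf1r_heterodimers` variant;
setting their association rates to zero reproduces the default ten-dimer
network exactly (a tested equivalence), which is why they are not part of
the default.  A `no_heterodimers` variant keeps only the homodimers and
lets all of them signal (including ErbB3); it is the reduced model of the
likelihood-ratio comparison.

**States.** Per receptor: a free surface monomer and, for each cognate
ligand, a ligand-bound monomer.  Per dimer: a phosphorylated surface pool
and an internalized pool (dimerization and trans-phosphorylation are
collapsed into one step).  Downstream: active fractions of MEK, ERK, AKT,
S6K1 and S6 with conserved totals.  The full network has 35 states
(5 + 5 + 20 + 5); `CompiledModel.describe()` reports the inventory.  This
is deliberately the smallest inventory supporting every arrow of the
network diagram, not a replica of any deposited model's state list.

**Kinetics.** Mass-action throughout.  Ligand is a constant bath input
(bulk-medium stimulation; no depletion).  Ligand binding uses
K_D = koff/kon with literature-scale nanomolar affinities.  A ligand-bound
monomer dimerizes `phi_ligand` (default 250) times faster than a free one,
modulated by per-ligand, per-dimer multipliers: EGF-bound EGFR prefers
HER2 as partner (multiplier 2.0) over ErbB3/Met (0.05), while BTC drives
EGFR homodimerization (3.0) at the expense of EGFR–HER2 (0.3).  These
preferences are what produce the competition effects — e.g. EGF + HRG
co-stimulation lowering phospho-ErbB3 relative to HRG alone because
EGF-occupied EGFR sequesters HER2.  Surface dimers dissociate or
internalize; internalized dimers recycle to free monomers or are degraded.
Trafficking differs between dimers (EGFR homodimers recycle efficiently,
HER2-containing heterodimers are degraded); with one shared parameter set
this yields sustained receptor phosphorylation in EGFR-high lines
(homodimer-dominated) and transient, early-peaking phosphorylation in
EGFR-low lines (heterodimer-dominated).

**Downstream cascade.** The weighted sum of active dimer pools (surface +
internal by default; a switch restricts signaling to the surface pool)
drives two branches — MEK→ERK and AKT — converging on S6K1 and then S6.
Pathway weights route ErbB3- and IGF-1R-containing dimers mainly to PI3K
and EGFR/HER2/Met dimers mainly to MAPK, with IGF-1R only weakly coupled
to MAPK.  Two negative feedbacks are wired by default and configurable:
pERK inhibits the MAPK input (SOS-like) and pS6K1 the PI3K input
(IRS-1-like), both as multiplicative 1/(1 + k·x) terms.

**Units.** Receptor abundances in molecules/cell (the reference table
prints thousands/cell; the loader multiplies by 1e3), ligand in nM, time
in minutes.  No explicit volume conversion — binding rates absorb units.

**Steady state.** The only cell-line-specific inputs are receptor surface
counts.  The ligand-free basal state is solved analytically for the
receptor layer: free monomer levels are *pinned* to the measured
expression and per-receptor synthesis rates are solved from the balance
(returns from dissociation/recycling never exceed consumption, so the
solved synthesis is always non-negative).  The two feedback-coupled
cascade fixed points are 1-d monotone root problems solved by bracketing
to machine precision.  A long-horizon pre-equilibration plus residual
check is the fallback; the normalized residual tolerance is 1e-8, and in
practice the analytic state is exact to ~1e-16, so ligand-free
trajectories drift by less than 1e-9 relative over 240 min.

**Integration.** LSODA (via `scipy.integrate.odeint`) with rtol 1e-8,
atol 1e-10 by default; the right-hand side is JIT-compiled with numba when
available (a bitwise-equivalent numpy fallback is kept and exercised by
the same tests when numba is absent).  Calibration loops may loosen to
rtol 1e-6 with a matched finite-difference step (1e-3 in log10 space) so
differencing noise stays well below prediction changes.

## Calibration

Measurements y(t_i) connect to the model through per-observable scale and
offset with known sigma; where the log flag is set the residual is taken
on log10 values (multiplicative log-normal noise becomes Gaussian), and
chi2 = sum((y - g)/sigma)^2 is -2 log L up to a constant.  Fitting is
multi-start trust-region least squares (`scipy.optimize.least_squares`,
`trf`) in log10 parameter space: first start at the nominal vector,
remaining starts log-uniform within ±2 decades (seeded, bit-reproducible),
bounds ±6 decades.  The calibration scheme shares all kinetic rates across
lines and frees only per-line receptor expression, mirroring the model's
central claim; arbitrary kinetic parameters can also be freed by path.

**Nested-model comparison.** The LRT statistic is chi2_reduced −
chi2_full with df the free-parameter difference.  Removing a dimer
constrains its association rate to the boundary ka → 0 of its admissible
range, so under the null the statistic follows the Chernoff 50:50 mixture
of chi2_0 and chi2_1 per removed rate, not chi2_df; `lrt_reduced` exposes
`boundary=True` for this case (the plain chi2 tail remains the default
for interior hypotheses).  The replication harness fits a scaled-down
two-receptor network (EGFR + HER2, one heterodimer; six time points, two
EGF doses, ~24 points per replicate) and seeds the full fit with the
reduced optimum so the pair is numerically nested by construction.  At
100 replicates the measured type-I rate is consistent with alpha = 0.05.

**Coverage.** `coverage_fraction` reports the share of points within
k·sigma of the prediction — the measurement-band reading of "model
uncertainty".  Propagating fitted-parameter uncertainty (profile
likelihood bands) is explicitly out of scope.

## Phenotype calls

A (line, ligand) pair is a responder when mean day-3 viability exceeds
the matched control by more than 20% AND a two-sided Wilcoxon rank-sum
test rejects at alpha = 0.05.  For quadruplicates the exact null is
enumerated over all C(8,4) = 70 assignments (mid-ranks for ties), so the
smallest attainable p is 2/70 ≈ 0.029 — significance requires complete
separation, and with triplicates (p_min = 0.1) no call can ever fire.
The effect ratio uses the mean (median available); the mirrored rule
(≥20% below reference) classifies inhibition.  A sweep utility recomputes
calls across 10–30% thresholds.

## Features and classifier

For each (line, ligand) the model is simulated at the screen doses
(EGF 5 nM, HRG 5 nM, HGF 1 nM, IGF-1 50 nM) and the trapezoidal AUC over
0–240 min of the nine signaling dimers' phospho-levels plus pAKT, pERK
and pS6 forms the 12-dimensional feature vector; mutation flags ride
along, and fold-change/quasi-steady-state extras are optional.  AUCs
integrate the raw (not baseline-subtracted) level; subtraction sits
behind a flag.  Features are log10-transformed before classification —
cosmetic for order-preserving tree splits, but it keeps thresholds
readable across the orders of magnitude receptor inputs span.

**Trees.** At a node with S responders among n rows the significance is
Z = S/sqrt(n); a split is scored by the gain in squared significance,
gain = Σ_c S_c²/n_c − S²/n.  The naive "sum of child Z" score was
rejected because it is linear in how signal is allocated between
fixed-size children — all balanced splits of a node score identically and
the criterion cannot rank features; the squared form is zero exactly for
uninformative splits and positive otherwise, so every recorded split has
positive gain and impure-but-uninformative nodes become leaves.  Gini
gain is available as an alternative and the suite checks both recover
planted signals.  Ties break to the lowest feature index with midpoint
thresholds (determinism under a fixed seed).

**Bagging and evaluation.** Defaults: 200 trees on full-size bootstrap
resamples, depth limit 4, minimum leaf 3.  Prediction is the majority
vote; importance is the mean split gain per feature over all trees
(optionally normalized to max 1).  Evaluation follows the
leave-whole-cell-lines-out protocol: lines are split 500 times into
train/test (default fraction 0.7), training uses all ligand rows of the
training lines, and accuracy — the fraction of true predictions — is
scored on held-out lines for the target ligand (or all ligands, with
IGF-1 excludable: its scarce responders make its splits unstable).  The
500-repetition harness uses 30–50 trees per repetition to keep the
protocol fast; single trained models use the 200-tree default.  The
control replaces the classifier by a coin flip (50% true predictions);
comparisons are paired one-sided Wilcoxon signed-rank over repetitions.
A receptor-expression-only feature mode supports the head-to-head
comparison with simulated features.

## Expression mapping and cohorts

Surface counts relate to mRNA (TPM) by a per-receptor power law, fitted
on the log10–log10 scale (≥3 positive pairs per receptor).  For cohort
tables on an arbitrary scale, each receptor gene is divided by its cohort
mean and multiplied by the reference panel's mean surface count — the
anchor to absolute counts is this package's choice, and it makes
predictions invariant to global rescaling of the table.  Each sample is
then simulated like a cell line, classified by the trained trees, and
predicted responders are tested for elevated ligand expression
(Welch t-test on log2(TPM + 1)).

## Synthetic data

The generators define the study conditions; all are bit-reproducible from
their seed.  Receptor counts are log-uniform over the reference panel's
span (3.0k–5501.4k molecules/cell); mutation frequencies are computed
from the packaged table at run time (17/58 KRAS, 16/58 PIK3CA).  Time
courses follow the experimental design — four doses (0.156–10 nM) of
EGF, HRG and IGF-1 plus pairwise co-stimulations at 2.5 nM, twelve time
points 0–240 min — with multiplicative log-normal noise of 0.1 log10
units (cv ≈ 26%, a typical immunoassay noise level).  Viability is
quadruplicate with 5% CV, a +35% day-3 effect for planted responders and
a 10% label-noise rate; the planted rule (default: pS6 AUC above the
pooled median, with an optional OR-clause, always depth-≤3) freezes its
absolute threshold at first application so every dataset from one ground
truth uses the same rule.  Cohorts are accept/reject sampled to a target
responder fraction with ligand genes shifted in responders on the log2
scale.

What passing these tests shows — and does not.  The synthetic data share
the real screen's design (doses, grids, replication, label rules) but not
its biology: no plate or batch effects, no autocrine signaling, no
mutation-kinetics coupling, and the generator's model *is* the fitted
model, so recovery results certify the pipeline's statistics and
numerics, not the biological truth of the network.

## Problem sizes of the shipped checks

The acceptance script and suite use: the full 58-line reference panel for
steady-state checks; a 20-line synthetic panel (80 line-ligand pairs) for
the 500-split evaluation; two lines for receptor recovery (20 starts);
100 replicates of the scaled-down LRT; 400-sample cohorts (200/arm).
These sizes were chosen so the whole battery runs on a laptop-class
machine in minutes while keeping every statistical margin wide.

## Known limitations

- The state inventory and rate values are this package's own; no attempt
  is made to reproduce any deposited parameterization, and absolute
  phospho-levels are in arbitrary (scaled) units.
- Antibody/inhibitor pharmacology, receptor-mutant kinetics, spatial
  effects and pathways beyond MAPK/PI3K are out of scope.
- `coverage_fraction` ignores fitted-parameter uncertainty.
- Sigma is treated as known (supplied per record or per observable);
  joint noise estimation is not implemented.
- The SBML export writes structure (species, reactions, stoichiometry)
  without kinetic laws; it round-trips counts and identifiers, not rate
  expressions.
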