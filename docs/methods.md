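# Methods

## The dynamics classifier

One participant-cycle is a series of daily records over a declared range
(default cycle days 4–32; day 1 = first day of menses). Each record is
either present, carrying a CST, or explicitly absent; absent days are
kept as records so every denominator is unambiguous. All fractions use
present samples only.

The decision tree has two stages. Stage one looks at the eubiotic
fraction *f* of the whole series: at least 80 % eubiotic means constant
eubiotic; more than 80 % dysbiotic means constant dysbiotic. Stage two,
reached only by intermediate series, looks at the menses-free window
(default days 9–25): more than 80 % eubiotic there means the dysbiosis
tracks menses (menses-related dysbiotic); anything else is unstable.

Numerical choices:

- **Exact rationals.** Thresholds are stored as `fractions.Fraction`
  (0.8 parses to 4/5) and eubiotic fractions are built from integer
  counts, so boundary cases like 20/25 = 4/5 compare exactly. No
  floating-point threshold comparison occurs anywhere in the tree.
- **Boundary asymmetry.** The constant-eubiotic comparison is inclusive
  (*f* ≥ 0.8) while the constant-dysbiotic and window comparisons are
  strict (> 0.8). This asymmetry matters: a 15-sample subseries with 12
  eubiotic samples sits exactly on the boundary and is called constant
  eubiotic under the inclusive rule. Both comparisons expose
  inclusive/exclusive flags for populations where the other convention
  is preferred.
- **Guards, not guesses.** Series with fewer than `min_samples_total`
  (default 5) present samples, or fewer than `min_samples_midcycle`
  (default 3) window samples when the window decision is required,
  return *indeterminate*. The defaults reflect the observed minimum for
  separating the two intermediate categories (two menses + three
  mid-cycle samples); they are deliberate guards rather than inferred
  values.
- Eubiosis is decided on the CST main type only; subtypes are parsed and
  retained (dialects "III-A"/"IIIA"/"III_A" normalize to one value) but
  do not influence the label. The default eubiotic set {I, II, V} can be
  narrowed to {I, V} for cohorts where CST II does not occur.
- Menses membership in the *sampling* module is defined by the recorded
  bleeding flag, not by cycle-day arithmetic, because cycle-day
  positions of bleeding are unreliable for participants with irregular
  or very light bleeding. The classifier's window, by contrast, is a
  fixed day interval by design.

## Reduced-sampling analysis

A `SubsampleScheme` keeps `n_menses` samples from bleeding days and
`n_nonmenses` from menses-free days. By default the menses-free pool is
restricted to the mid-cycle window: a "non-menses" sample drawn from the
shoulder days (6–8, 26–28) can still carry menses-triggered dysbiosis,
which would make even generous designs unable to distinguish
menses-related from constant dysbiosis. Selection is exhaustive when the
number of distinct selections is at most 5 000, otherwise 200 seeded
random replicates; every replicate is deterministic given (seed,
participant, replicate index).

Reference labels come from the full series under the standard guards.
Subsampled series are classified with the guards relaxed to one sample —
otherwise no small design could be scored at all — and agreement is the
fraction of (participant, replicate) evaluations recovering the
reference label, reported overall and stratified by reference category.
Participants with indeterminate reference labels, or for whom a scheme
is infeasible, are counted and excluded. The frontier routine evaluates
a grid (menses 0–4 × mid-cycle 0–6) and returns the componentwise
Pareto-minimal schemes whose stratified agreement meets the target for
every category present.

## The synthetic cohort generator

No generative model exists for these dynamics; the simulator is the
minimal mechanism able to produce all four categories with known ground
truth, and is a testing stand-in, not a biological claim.

**Calendar.** A 28-day cycle with menses on days 1–5 gives bleeding on
observed days 4, 5 and 29–32. Intercourse is i.i.d. Bernoulli per day
(default rate 0.10, matching a few reported intercourse days per
cycle). Sampling failures are i.i.d. Bernoulli with default missingness
0.08, i.e. about 26 successful samples per cycle.

**Trajectories.** A two-state (eubiotic/dysbiotic) Markov chain runs
from cycle day 1 — so the first menses shapes the state before the first
observed day — and emits days 4–32. Each day, a dysbiotic state first
attempts recovery (probability `p_recover`); a state that is (or
becomes) eubiotic is then exposed to the day's trigger: menses
(`p_dysbiosis_menses` on bleeding days), intercourse, or spontaneous.
Evaluating recovery before the trigger means sustained menses keeps a
susceptible chain dysbiotic, and a chain with certain trigger and
certain recovery is dysbiotic exactly on bleeding days — the intended
limiting behaviour. The state is decorated with a CST subtype drawn from
per-state categorical distributions.

Regime presets (shipped in `data/regime_presets.yaml`, version 1) were
calibrated so that classifying the default 49-participant mix
approximates a 20/6/11/12 split: constant regimes have near-zero
switch or recovery rates; the menses-related regime has a certain
bleeding-day trigger, 0.5/day recovery (about two days of post-menses
dysbiosis) and a rare (0.01/day) spontaneous blip; the unstable regime
mixes moderate spontaneous (0.24) and intercourse-driven (0.55)
switching with slow recovery (0.35). Two intrinsic limits are worth
knowing: losing one of the six bleeding days to missingness can leave a
menses-related chain with exactly five dysbiotic samples out of 25+,
which the inclusive 80 % boundary calls constant eubiotic — so
menses-related recovery plateaus near 80 % and the recovery guarantee is
strongest pooled across the two intermediate regimes; and an unstable
chain can, by chance, be mostly eubiotic mid-cycle and look
menses-related.

**Compositions.** Per-sample counts are Dirichlet–multinomial over a
nine-taxon panel (four *Lactobacillus* species, *Gardnerella*,
*Prevotella*, *Fannyhessea vaginae*, *Sneathia*, other), with CST-
conditional concentration vectors (CST I dominated by *L. crispatus*,
III by *L. iners*, IV by *Gardnerella*/*Prevotella*) and log-normal
library sizes (median 2×10⁴). Columns sum exactly to the drawn library
size.

**Phage ratios.** Log-normal draws per (regime, state-class), censored
at a detection limit of 10⁻⁵ and clipped at 2.7×10⁻². Non-detects are
explicit (ratio 0 with a censoring flag), never dropped silently. A
log-scale boost (default ln 5) applies on days whose state differs from
the participant's majority state, reproducing the observation that phage
ratios spike at community transitions; this is what gives simulated
cohorts a positive phage/neighbour-distance correlation.

What the generator does *not* emulate: hormonal covariates, strain-level
structure, biofilm persistence, autocorrelated missingness, or
contraceptive-group differences. Tests passing on simulated cohorts
certify the pipeline's logic, not any biological effect size.

## Statistics

- **Aitchison distance** is the Euclidean distance between CLR-
  transformed counts. The pseudocount (default 1, added to raw counts
  before the transform) is exposed; pseudocount 0 is allowed only for
  strictly positive vectors and makes the distance exactly
  depth-invariant.
- **Jaccard distance** uses presence sets at ≥ 0.5 % relative abundance
  (the same threshold as the prevalence test, for consistency). Two
  empty presence sets have distance 0 by convention.
- **Dispersion** is the mean over all unordered sample pairs of a
  participant; **neighbour distance** averages a sample's distance to
  its nearest present neighbours before and after (endpoints use their
  single neighbour; missing days are skipped over).
- **Prevalence test**: per taxon, a 2×2 chi-square (with continuity
  correction) of presence between menses and menses-free samples; taxa
  present in all or no samples are degenerate and reported separately;
  cells with expected counts below 5 are flagged, with an optional
  Fisher-exact fallback. q-values are Benjamini–Hochberg, implemented as
  the canonical step-up (p·m/rank, suffix cumulative minimum, clipped at
  1) so results are reproducible bit-for-bit.
- **Resampled group test**: each trial subsamples every participant to
  at most *m* values (10 when comparing across all samples, 5 within a
  category) without replacement — participants with fewer contribute all
  their samples and are kept, not dropped — then applies Kruskal–Wallis
  across groups; the rule is significant when p < 0.05 in at least 7 of
  10 trials. This blunts the influence of heavily sampled participants;
  it is not a random-effects model, and under participant-level
  variance components the pooled test remains anti-conservative. The
  Dunn post-hoc (mean-rank z tests with tie correction, BH-corrected)
  runs on the full data, not a subsample, and the result records that
  choice.
- **Phage correlations** use Spearman's rank on detectable ratios only;
  censored non-detects carry no rank information and are excluded, with
  the exclusion count reported.

## Problem sizes

The test suite and `scripts/acceptance.py` use problem sizes chosen to
make sampling error negligible relative to the properties asserted:
exhaustive truth-table comparison for all binary series up to length 10
under every window placement; 49-participant cohorts for agreement
checks; 200 participants per regime for recovery; 100 null and 50
shifted replicates for the resampled test's operating characteristics;
1 000 random pairs/tables for the distance oracle and read-conservation
checks.
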