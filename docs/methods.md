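# Methods

## Scope and data model

The package operates on three substrates: a staged gene-expression matrix
(genes × samples, FPKM, each sample labelled with one of NL / CH / LC /
DN / eHCC / aHCC, HCC stages optionally grade-tagged G1–G3), per-subject
serum marker concentration tables (ng/mL; missing measurements allowed),
and two-group survival records (time, event flag, group).  All interchange
formats are plain TSV/JSON/FASTA (`seropanel.io`).

## Synthetic cohorts

The serum data behind the published marker panels are not deposited, so
cohorts are simulated.  Concentrations are modelled per marker and stage
as log-normal: concentrations are positive and right-skewed, and the
log-normal is the simplest family with a closed-form exceedance
calibration.  Given a target exceedance probability *t* at cutoff *c* with
log-scale SD σ, the location is

    μ = ln(c) − σ · Φ⁻¹(1 − t).

Defaults pin each marker's HCC-stage exceedance to its published
sensitivity and each control stage to 1 − specificity, at the published
cutoffs: HMMR 0.8 ng/mL (80.3 / 91.86), NXPH4 7.5 (75 / 74.42), PITX1 2.5
(80.3 / 66.28), THBS4 90 (57.58 / 90.7), AFP 20 (52.27 / 84.88).  σ
defaults to 1.0: with only one operating point per arm published, the
cutoff exceedance — not the spread — is identified, and σ = 1 yields
realistic order-of-magnitude concentration ranges.  An alternative
"stage-refined" AFP profile uses the published per-stage positive rates
(2% NL, 33% eHCC, 73% aHCC) with CH/LC exceedance 0.2347 chosen so pooled
specificity over the validation control mix (49 NL : 31 CH : 46 LC) stays
at 84.88%.  The six candidates that were screened but dropped (CCNB2,
CDT1, COCH, CSMD1, OLFML2B, UBE2T) have no published operating points;
when requested they are simulated with nominal weakly-informative
defaults (cutoff 5 ng/mL, exceedance 0.45 in HCC, 0.40 in controls) —
a synthetic choice, flagged as such.

Stage compositions default to the published cohort compositions: test set
16/13/15/35/24 (NL/CH/LC/eHCC/aHCC), validation set 49/31/46/77/64,
tissue set 15/20/10/18/45 (high-grade dysplastic nodules folded into
eHCC, G2+G3 into aHCC).  The published cohort *totals* (100 and 279)
disagree with the per-stage sums (103, 267); the per-stage counts are
honoured.  Markers are drawn independently across subjects and markers —
real marker correlations are not emulated, so simulated panel gains are
the independence-case gains; a missing-rate parameter masks measurements
at random to exercise complete-case logic.

Survival data are exponential event times with a group hazard ratio and
independent exponential censoring whose rate is set so the marginal
censoring probability equals `censor_rate`.

What passing the simulation-backed tests shows: the estimators recover
the operating points, effects and error rates they were configured with.
What it does not show: performance on real sera with assay noise,
between-marker correlation or non-log-normal tails.

## Expression fixture

`generate_expression_fixture` plants K marker genes that jointly satisfy
all four selection criteria and 90 decoys that each violate exactly one
(non-coding; coding without a signal peptide; overexpressed also in
CH/LC; absent from the signature list).  Values are generated as
log2(FPKM+1) = baseline + offset + N(0, 0.3); planted genes receive a
log2(effect)-fold offset in HCC stages (default effect 4), graded by
+0.2·(K−1−i) so the planted order is the expected expression ranking.
This makes end-to-end funnel recovery a by-construction ground truth,
deterministic for a fixed seed.

## Signal-peptide calls

The external predictor's neural networks are *not* reimplemented.  Two
routes exist: a parser for SignalP 4.x short-format output (positivity
from the `?` column; the reported Ymax position is the first mature
residue, stored as cleavage after position Ymax−1), and a built-in
classical rule: (i) the maximal 8-residue mean Kyte–Doolittle window
starting in the first 30 residues must exceed 1.6 (h-region); (ii) at
least one K/R before that window (n-region); (iii) a (−3,−1)
small-residue cleavage site (A/G/S/C/T/V, Ala-weighted matrix, scan over
first-mature positions 15–45, earliest best site on ties).  Sequences
under 25 residues are negative with a reason rather than an error;
ambiguity codes score hydropathy 0 and are never accepted at (−3,−1).
Cleavage positions are 1-based indices of the last signal residue.  The
rule is deliberately simple — the funnel consumes only a boolean per gene
— and raising the hydrophobicity threshold is monotone (never adds
genes).

## Selection funnel

Overexpression is called per stage vs NL on log2(FPKM+1) (the +1 offset
avoids log 0 and mirrors the convention used for public RNA-seq
reference data): pass ⇔ mean difference ≥ log2(fold threshold) and
two-sided Welch p < α, defaults fold > 2 and α = 0.05, both configurable;
Benjamini–Hochberg adjustment is available behind a flag but off by
default.  Degenerate genes (constant in both groups) get t = 0, p = 1
when equal and p = 0 flagged when separated; groups with n < 2 are
excluded with a log entry.  "Expressed in CH or LC" is interpreted as
*called overexpressed vs NL* in CH or LC — detection-level exclusion
would empty any realistic candidate set.  The ELISA-assayability step is
an externally supplied allow-list, since kit availability is not
computable.  Ranking uses mean log2(FPKM+1) over eHCC+aHCC samples,
descending, ties broken lexicographically.

## ROC and 2×2 statistics

ROC curves are built over the unique observed values (descending, ±∞
sentinels); ties collapse into single steps, so the trapezoidal area is
identically the tie-adjusted Mann–Whitney probability — an invariant the
tests check to 1e-12.  AUC inference uses DeLong structural components
(midrank implementation), a Wald 95% CI truncated to [0,1], a two-sided
test against AUC = 0.5, and the paired-covariance version for marker
comparisons; a stratified bootstrap SE is provided as a cross-check.
Degenerate variance at AUC ∈ {0, 1} collapses the CI and flags the
p-value as a boundary case.

Positivity is strict (value > cutoff) everywhere; published-table
reconstructions are insensitive to this choice but it is fixed for
reproducibility.  The "optimum" cutoff maximises Youden's J with ties
broken toward higher specificity.  From a 2×2 table: sens = TP/(TP+FN),
spec = TN/(FP+TN), accuracy, PPV, NPV, +LR = sens/(1−spec),
−LR = (1−sens)/spec, OR = TP·TN/(FP·FN), RR = [TP/(TP+FP)]/[FN/(FN+TN)].
Empty margins yield flagged infinities/NaNs; a Haldane–Anscombe +0.5
correction is available behind a flag.  Rates are kept at full precision
internally and rounded to 2 decimals only for display.  Published
combination-table PPV/NPV columns that merely repeat the printed
sensitivity/specificity are not used as verification targets, and the
published "relative risk" column does not follow the standard definition
on reconstructed cells — RR here is the standard definition.

## Panels

Panels combine 1–5 distinct marker cutoffs by the OR rule (any member
positive), the only rule consistent with positive-rate panel framing and
with panels raising sensitivity over AFP alone; AND is available for
specificity-oriented use.  The continuous combination score is
max over members of log(value/cutoff) (zero values floored at 1e-9
ng/mL): its sign agrees with OR positivity, and for singleton panels it
is a strictly increasing transform of the raw value, so the combination
AUC reduces exactly to the single-marker AUC.  No logistic fusion is
fitted — no coefficients exist to reproduce.  Subjects missing any member
measurement are excluded from that panel's evaluation.  The
full-coverage search enumerates all size-2/3 subsets exhaustively and
returns those detecting every case, in lexicographic member order.

## Survival

Kaplan–Meier product-limit estimation with Greenwood variance; censoring
tied with events at the same time keeps the censored subject at risk
through that time (events first).  The two-group log-rank test uses the
summed hypergeometric variance and a 1-df chi-square.  For
expression-based survival splits the default dichotomisation is
value > 2 × healthy-group mean, configurable.

## Problem sizes and numerical choices

Simulation-backed checks use sizes chosen as comfortable asymptotic
regimes: operating-point recovery at 10⁴ subjects per arm (3 binomial SE
tolerance), DeLong null calibration at 100 cases/100 controls and
log-rank at 60/group with 20% censoring, 2000 replicates each
(rejection rate expected within 0.05 ± 0.02).  All randomness flows
through seeded NumPy generators; identical (design, seed) pairs produce
bit-identical outputs, which the CLI records as manifest checksums.

## Known limitations

- Markers are simulated independently; real inter-marker correlation
  would shrink panel gains relative to the independence case.
- The built-in signal-peptide rule is a classical approximation: adequate
  for planted fixtures and coarse screens, not a SignalP replacement (no
  transmembrane discrimination, no newer output formats).
- Published AUCs and positive-rate percentages for the real cohorts are
  not reproducible without the undeposited sera; only
  contingency-derived arithmetic is reproduced exactly.
- The log-rank implementation is two-group only; no stratification or
  Cox regression.
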