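# Methods

This note documents the models, estimators, numerical choices and known
limitations of `chemoscreen`. It describes what the code computes; every
empirical number mentioned here is produced by the test suite or by
`scripts/acceptance.py`.

## Screening model and estimators

**Pearson screen.** For each gene × drug pair within a panel the sample
Pearson coefficient is computed over pairwise-complete observations (pairs
with either value missing are dropped per pair, not per line). The two-sided
p-value uses the exact t transform t = r·√((n−2)/(1−r²)) against Student's t
with n−2 degrees of freedom; |r| = 1 is reported as the p → 0 limit. No
multiple-testing correction is applied at the screen stage — the run
manifest records the number of hypotheses attempted so the burden is
visible. The orientation contract is that lower response (AUC or ln IC50)
means more sensitive, so negative r means sensitization. Raw IC50 inputs
must be natural-log transformed upstream and declared `LN_IC50`; the reader
refuses undeclared metrics.

**Validity threshold.** A correlation is valid only with n ≥ 10
pairwise-complete lines and non-constant vectors. Ten is a deliberate floor:
small-n Pearson p-values are unstable, while even the smallest real panel
(≈58 solid-tumor lines) sits far above it. Invalid records are emitted with
a flag rather than dropped, so the per-panel record count always equals
|genes| × |drugs|.

**Consensus sieve.** Per gene × class × database, the fraction of the
class's drugs with r ≤ −0.2 (sensitivity) or r ≥ +0.2 (resistance) is
formed from valid records only; the magnitude boundary is inclusive, the
>50% fraction rule strict, and a gene is selected for a class/direction when
at least 2 databases pass. Only the signed form of the rule is implemented;
an unsigned |r| reading would let the same gene pass both directions and is
rejected. A database with no valid record for a gene/class abstains — it
counts neither for nor against — but the two-database bar is absolute.
Databases screened under two response metrics carry a shared identifier
prefix (`GDSC:AUC`, `GDSC:LN_IC50`) and are collapsed before the vote by
keeping the better fraction, so corroborating views of one database can
never satisfy the two-database requirement alone. Per-database denominators
are used for the drug fraction (a database is judged against the drugs it
itself tested).

**Concordance and lineage summaries.** Cross-panel reproducibility of a
candidate's expression uses the same Pearson kernel over cell lines shared
between panels, with a least-squares line for display. Cell-line identifiers
are matched after uppercasing and stripping spaces, hyphens and periods
("MDA-MB-231" ≡ "MDAMB231"); the normalization refuses to merge two distinct
lines within one panel. Lineage summaries report n, mean and sample SD
(n−1), with SD undefined for single-line lineages.

## Clinical estimators

All survival machinery is implemented from the defining formulas (the test
suite cross-checks against lifelines and scipy):

* **Median dichotomization** on the analyzed subset (after any
  chemotherapy-only filtering): expression strictly above the median is
  HIGH; ties at the median fall LOW. This tie rule is a documented choice —
  "above or below the median" needs one, and strict-above is deterministic.
* **Kaplan–Meier** product-limit estimator with the standard convention that
  events precede censorings at tied times.
* **Log-rank (Mantel–Cox)**: hypergeometric observed/expected/variance per
  distinct event time, χ² = (ΣO − ΣE)²/ΣV against χ²(1).
* **Mantel–Haenszel hazard ratio** HR = (O_low/E_low)/(O_high/E_high),
  reported as hazard in the LOW-expression group relative to HIGH, so HR > 1
  means high expression is protective. A Cox model is deliberately not used:
  the analysis pairs HRs with the log-rank test and fits no covariates.
* **Welch's t** on z-scored expression (sample SD) for responder contrasts,
  with Welch–Satterthwaite degrees of freedom.

Survival time units are pass-through; no conversion is attempted.

## Synthetic data: what it emulates, and what it does not

The screen generator produces `n_databases` panels over partially
overlapping cell-line name lists (a shared pool sized by
`line_overlap_fraction`). Expression for every gene is Normal(μ_g, 1) with
gene-specific means on an RMA-like log2 scale (center 7); each panel draws
its expression independently around the shared means, i.e. panels are
independent re-measurements of the same biology. Drug response for a drug of
class c is the sum over planted genes affecting c of s·β·(expr − μ) plus
Normal(0, σ) noise, with s = −1 for sensitizers. Defaults are the study
conditions the pipeline is benchmarked at: 3 databases × 60 lines, 500 null
genes plus one pan-class sensitizer (β = 1.5, σ = 1, affecting the four
DNA-damage classes), and 6 drugs per class per database — the real
inventories average ≈6 drugs per class per panel (91 drug-slots across
3 panels × 5 classes).

The clinical generator draws expr ~ N(0,1), treatment ~
Bernoulli(chemo_fraction), and exponential survival with hazard
λ₀·exp(−γ·expr·1[chemo]) — high expression is protective only under
chemotherapy, the pattern the validation stage is designed to detect.
λ₀ = 0.05 per month gives a ≈14-month baseline median. Censoring is an
independent exponential with rate λ₀·c/(1−c) for target rate c (exact in
expectation against the baseline hazard; the realized rate shifts slightly
with γ). Responder labels for treated patients are
Bernoulli(logistic(a + b·expr)), defaults a = −0.5, b = 1.5.

Deliberately not modeled: dose–response curve shapes (the screen only
consumes summary metrics), platform batch effects, copy-number/methylation
layers, and cross-panel correlation of measurement error. Passing tests on
this generator show the pipeline's statistical machinery is correct and
calibrated; they do not show that real panels satisfy the generative
assumptions.

### A small-sample caveat on pan-class false positives

Because every drug of an affected class shares the identical planted-effect
term, a null gene whose expression is chance-correlated with the planted
gene's expression inherits correlation with *all* affected drugs at once. At
60 lines the sampling SD of that inter-gene correlation is ≈0.13, so a
≈3%-per-database tail event pushes a null past the class threshold in every
affected class simultaneously; with 500 null genes, at least one null
reaches the 4-class bar in roughly a quarter to a third of replicates. This
is a property of screening for class-consistent correlates at small n — the
per-drug evidence is not independent — and it vanishes at real panel sizes
(hundreds of lines), where the tail probability is negligible. The planted
gene itself is recovered at the pan-class bar in essentially all replicates;
uniqueness is what small panels cannot guarantee.

Relatedly, the Mantel–Haenszel HR between median-dichotomized groups does
not estimate e^γ: the group contrast of E[e^(−γX)] for a standard-normal
X is ≈e^1.6γ at time zero and is attenuated by within-group frailty over
follow-up, landing near e^1.15 at γ = 1 under the default censoring.
Parameter-recovery checks therefore compare the *mean* ln HR across
replicate cohorts against γ with a generous band rather than asserting
per-seed agreement.

## Numerical and engineering choices

* Delimiters are auto-detected between tab and comma (ties → tab); missing
  values are empty cells or `NA`; non-numeric cells are read as missing.
  Duplicate gene/sample/drug identifiers are hard errors naming the label.
* Gene and drug identifiers are opaque, case-sensitive strings; no symbol
  aliasing is attempted (identifier conversion is out of scope).
* Matrices are stored sample-major internally; file orientation is fixed by
  contract (expression: genes × samples on disk; response: lines × drugs),
  never guessed.
* Constant-vector detection uses the exact range of the valid entries, so it
  is unaffected by the scale of the data.
* All writers use a fixed `%.10g` float format; with a fixed seed the whole
  pipeline is byte-reproducible, which the test suite asserts.
* Generator seeds are mandatory config fields, never wall-clock derived;
  replicate seeds are derived arithmetically from a base seed.
* Benchmark problem sizes (20 screen replicates, 100 null cohorts, 2,000
  null gene–drug pairs, cohorts of 150–200 patients) are the package's
  chosen study conditions for calibration and recovery checks; they complete
  in seconds.

## Known limitations

* The consensus rule is a fixed sieve, not an error-controlled selection
  procedure; no FDR statement attaches to the nominated gene lists.
* Pearson-only: robust or rank-based variants are not offered.
* The clinical module handles a single gene at a time and overall survival
  only; multi-gene signatures, covariate-adjusted Cox models and competing
  risks are out of scope.
* RMA normalization, probe-to-gene collapsing and any download tooling for
  the real public panels are explicitly not included; inputs are assumed
  pre-normalized text matrices.
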