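# Methods

## Model and estimators

`ivmr` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics. Genetic variants associated with an exposure serve
as instrumental variables; because alleles are randomized at meiosis,
the instrument–outcome association is protected from the confounding
and reverse causation that afflict observational estimates, provided
three assumptions hold: (a) the variant is associated with the
exposure, (b) it is independent of confounders of the
exposure–outcome relation, and (c) it affects the outcome only through
the exposure (no horizontal pleiotropy). These assumptions are
contracts, not runtime checks: the simulator can violate (a) and (c)
on demand so their consequences are measurable.

For SNP *j* with exposure association (b<sub>xj</sub>, s<sub>xj</sub>)
and outcome association (b<sub>yj</sub>, s<sub>yj</sub>) expressed on
the same effect allele, the Wald ratio

&emsp;r<sub>j</sub> = b<sub>yj</sub> / b<sub>xj</sub>

is the per-SNP causal estimate (identical to two-stage least squares on
individual-level data). Its delta-method standard error is computed at
both orders:

&emsp;first order: s<sub>yj</sub>/|b<sub>xj</sub>|
&emsp;second order: sqrt(s<sub>yj</sub>²/b<sub>xj</sub>² + b<sub>yj</sub>²s<sub>xj</sub>²/b<sub>xj</sub>⁴)

Ratios are pooled with a fixed-effect inverse-variance-weighted (IVW)
meta-analysis, weights 1/se². With first-order weights this is
algebraically a zero-intercept weighted least-squares regression of
outcome betas on exposure betas with weights 1/s<sub>yj</sub>² — a test
suite exploits the equivalence as an independent oracle (NumPy QR
solver and statsmodels WLS), alongside R's `metafor::rma(method="FE")`.
P-values are two-sided standard-normal (summary statistics carry
effectively no small-sample t correction), Bonferroni adjustment
multiplies by the family size (default: the number of exposure–outcome
cells estimated in the run; configurable). Heterogeneity across
instruments is Cochran's Q with I² = max(0, (Q−df)/Q) and a
Higgins–Thompson test-based 95% CI on ln H, truncated to [0, 100];
with two instruments and Q ≤ k the CI is reported as the uninformative
[0, 100] since neither test-based formula applies.

### Choice of SE order

The IVW weighting default is the first-order SE — the convention in
summary-data MR, and the convention under which the bundled study's
reproducible cells come out exactly. The second-order SE is always
computed and can be selected (`se_order="second"`). The calibration
driver (`recovery_experiment`) defaults to second order: a coverage
statement about the causal effect needs the SE to carry the
exposure-side sampling variance, and with finite instrument strength
the first-order interval is anti-conservative (at the default
simulation regime the delta calculation puts first-order coverage near
0.92–0.93 versus ~0.95 at second order).

## Harmonization

Outcome associations are re-expressed per copy of the exposure's
effect allele. Allele-pair bookkeeping distinguishes: identical
orientation; swapped alleles (negate beta, complement EAF); opposite
strand (relabel through A↔T/C↔G); opposite strand plus swap. Pairs
that cannot be reconciled are *dropped with a recorded reason* — the
audit trail lists one action per instrument SNP, so nothing leaves the
pipeline silently.

Palindromic variants (A/T, C/G) are oriented by effect-allele
frequency: letters cannot distinguish a strand flip from an allele
swap, so the frequency side (<0.5 vs >0.5) decides whether a sign flip
is needed; within ±0.08 of 0.5 (configurable window) the variant is
dropped as unresolvable. This conservative window is standard
practice; the bundled data contain no palindromic instrument.

Instrument tables that print only the effect allele are handled by a
documented degradation (`allow_assumed_alignment`, on by default):
matching letters pass through as `assumed_aligned`; distinct
non-complementary letters are necessarily the two alleles of one
biallelic SNP and flip; complementary letters are ambiguous and drop.
Multi-base alleles are rejected at ingest — the package is SNP-only.

## Bundled study data

The package ships transcriptions of the per-SNP tables from a
published MR study of diet/lifestyle and glycemic traits: 15
instrument records across seven exposures (carbohydrate, protein and
fat intake from macronutrient GWAS; cigarettes per day, smoking
initiation and smoking cessation; sleep duration), and their
associations with seven outcomes (T2D from DIAGRAM; HOMA-IR, HOMA-B,
fasting insulin, fasting glucose, HbA1c, 2-hour glucose from MAGIC).
rs838145 is instrument for both carbohydrate (allele G) and fat
(allele A); outcome panels keep one orientation per rsID and
harmonization recovers the mirror. Since the outcome tables print no
alleles, each outcome row is recorded on the lifestyle-raising allele
of its matching instrument row, which is how the source reports them.

Recomputing the full 7×7 grid reproduces, at printed precision, every
cell whose inputs are fully printed — notably the smoking-cessation
Wald ratios on HOMA-IR (0.165), fasting insulin (0.132) and fasting
glucose (0.132), and the IVW pools for carbohydrate→T2D (0.0516, printed
0.051 — the source evidently truncates) and sleep→T2D (0.0051). Other
published cells — protein→T2D (computed 0.650 vs published 0.806),
fat→T2D (−0.095 vs −0.079), smoking-initiation→T2D (0.164 vs 0.249)
among them — cannot be derived from the printed inputs under any SE
order, presumably because the original analysis used unrounded
consortium values. The pipeline therefore compares every recomputed
cell against the published estimate and attaches a
`published_value_mismatch` flag when they differ by more than one unit
in the last printed decimal (10⁻³); discrepancies are surfaced, never
reconciled by hand.

## Synthetic data generator

`simulate_two_sample` draws the data-generating process the estimator
assumes: independent biallelic SNPs in Hardy–Weinberg proportions
(binomial(2, maf), maf uniform on a configurable range), two
non-overlapping samples from the same population, a shared
standard-normal confounder U, exposure X = Σα<sub>j</sub>G<sub>j</sub>
+ γ<sub>x</sub>U + ε<sub>x</sub> observed only in sample 1, and
outcome Y = βX* + γ<sub>y</sub>U + Σδ<sub>j</sub>G<sub>j</sub> +
ε<sub>y</sub> in sample 2, where X* is regenerated from the same
structural equation (the essence of the two-sample design) and
δ<sub>j</sub> ~ N(pleiotropy_mean, pleiotropy_sd²) are direct effects
that break the exclusion restriction when nonzero. Per-SNP simple
linear regressions in each sample emit beta/SE/p records, so the
generator's output is consumed by exactly the same code path as real
consortium data, harmonization included.

Defaults — 20 000 individuals per sample, 4 instruments, maf ∈
[0.2, 0.4], α = 0.3 (per-SNP F ≈ 600), confounder loading 0.3 on both
traits, unit residual SDs — describe a strong-instrument, moderately
confounded regime. A binary/log-odds outcome option is deliberately
absent: the estimator consumes beta/SE pairs identically regardless of
the outcome scale, so a continuous outcome exercises the full stack.
What the generator does not emulate: linkage disequilibrium between
instruments, realistic allele-frequency spectra, case-control
ascertainment, or sample overlap between the two GWAS. Calibration
results therefore validate the estimator under its own assumptions;
they do not certify robustness to those real-data features.

`recovery_experiment` runs simulate → harmonize → Wald → IVW per
replicate (child seeds spawned deterministically from the root seed)
and reports mean estimate, empirical SD, 95% CI coverage and the
rejection rate of the nominal 0.05 test, each with its Monte-Carlo
standard error. At the defaults with 500 replicates: type-I error
within 3 MC SEs of 0.05, mean estimate at β = 0.5 within 3 MC SEs,
coverage ≈ 0.95.

## Numerical choices and edge cases

- Exposure betas with |b<sub>x</sub>| < 10⁻¹² raise a
  degenerate-instrument error (the ratio is undefined); instruments
  with (b<sub>x</sub>/s<sub>x</sub>)² below 10 are estimated but
  flagged and warned as weak.
- A single-instrument pool returns the Wald estimate bit-for-bit.
- Printed-style numerics ("4.40 × 10^−11", Unicode minus) are parsed
  on ingest so the bundled tables transcribe their source exactly.
- Duplicate detection keys on (trait, snp_id, effect_allele): the same
  SNP may legitimately appear in two orientations.
- Simulated p-values are clipped away from exact 0 to respect the
  record invariant p ∈ (0, 1].
- All file outputs are byte-deterministic given config + inputs.

## Known limitations

Single-SNP exposures make pleiotropy undetectable and heterogeneity
undefined (reported as not-applicable, never a crash). No MR-Egger,
weighted-median or mode estimators, no random-effects pooling, no
Steiger filtering, no LD-aware instrument selection or proxy lookup —
instrument lists are taken as given.
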