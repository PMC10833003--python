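# Methods

This note documents the statistical model behind each stage of `ptmr`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical and design decisions a maintainer should
know about. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Summary-statistics model

Every stage consumes per-variant marginal statistics (β, se, z = β/se, p, n)
for one trait, a per-feature cis-SNP weight vector w, and an LD correlation
matrix R (allelic correlations r, not r²) over the cis window. Stored z and
p are cross-checked against β/se (relative 1e-8) and the two-sided normal
tail (absolute 1e-6); rows that fail are dropped with a logged count rather
than aborting, because real summary files are dirty. Missing z or p is
back-filled from (β, se). Positions are 1-based; chromosome labels carry no
"chr" prefix.

Allele harmonization follows common two-sample-MR practice: swapped alleles
flip β's sign and the effect-allele frequency; opposite-strand records are
resolved by base complement; palindromic variants (A/T, C/G) are resolvable
only through allele frequency, and are flagged non-harmonizable when either
frequency is missing or falls in [0.42, 0.58] — the conventional ambiguity
window. Non-harmonizable variants are dropped (logged), never fatal.
`align_alleles` is idempotent.

## Association screen

The feature-level statistic is the usual weighted-burden form
Z = wᵀz / √(wᵀRw), standard normal under no feature effect. Weighted SNPs
missing from the GWAS are dropped jointly from w and R without renormalizing
the surviving weights, matching the behaviour of the standard TWAS toolchain
this stage mirrors; a predictor variance wᵀRw ≤ 1e-12 is a degeneracy error.
Duplicate weight models per feature (multiple aptamers/probes) collapse to
the smallest unadjusted p **before** the Benjamini–Hochberg adjustment,
which runs separately per layer and per outcome — this reproduces
one-row-per-feature report tables; whether the FDR should instead run over
all uncollapsed measurements is genuinely open, and collapsing first is this
package's choice. BH itself delegates to
`statsmodels.stats.multitest.multipletests`.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor computed from
(β, se) alone — no MAF-based variance reconstruction — with prior effect-SD
0.15 on the quantitative (QTL) side and 0.2 on the binary (GWAS) side, the
canonical defaults. Hypothesis weights use per-SNP priors p₁ = p₂ = 1e-4 and
p₁₂ = 1e-5, exposed in configuration. All sums run in log space
(log-sum-exp); the H3 cross term L1·L2 − L12 is evaluated with `log1p` and
clamped at zero, so a single shared SNP yields PPH3 = 0 exactly and
posteriors always sum to 1 within 1e-8. Agreement with an exhaustive
enumeration over the 1 + m + m + m(m−1) + m causal configurations is a
tested invariant (1e-10) for m ≤ 6.

The evidence point for tiering uses PPH4 > 0.75 strictly; 0.7 and 0.8 are
conventional report-level annotations only and play no role in the score.

## Evidence tiering

Per layer with data: +1 for adjusted p < 0.05 (strict), +1 for PPH4 > 0.75
(strict); the 0–6 total maps to tiers {0} → None, {1,2} → Weak,
{3,4} → Moderate, {5,6} → Strong. The None tier is this package's totality
extension: in the pipeline the scorer only sees plasma-significant features
(which have ≥ 1 point), but the function must be defined for a
non-significant plasma layer too. The score is monotone in the evidence — a
property test asserts that lowering any adjusted p or raising any PPH4 never
lowers it.

Direction consistency is a separate flag that never changes the score: a
feature is inconsistent when any *significant* non-plasma layer's z-score
disagrees in sign with the plasma z (insignificant layers carry no
directional evidence); with only one layer present the flag is NA. The flag
gates MR follow-up instead of rescoring. On the packaged 25-protein table
this rule flags MST1 (plasma +4.194 vs both transcriptome layers negative);
it also flags ABO, whose significant breast-tissue z (+2.127) opposes its
plasma z (−3.442) — the table's own annotation marks only MST1, suggesting
its authors applied a narrower (unstated) criterion, but the sign rule as
specified is kept because it is the conservative gate for causal follow-up.
The printed table rounds adjusted p-values to four decimals, so one
displayed "0.0000" is loaded as the smallest positive float; any value below
5e-5 scores identically.

## Mendelian randomization

Instruments: exposure variants at p < 5e-8, falling back to p < 5e-6 when
none pass (the relaxed threshold used when a protein lacks genome-wide
instruments); an empty set is a logged "no-instrument" status, not an error.
Greedy clumping keeps the most significant remaining variant and discards
same-chromosome variants within 10 Mb at r² > 0.001 — the conventional
"default parameters" — both exposed in configuration.

Estimators:

- **Wald ratio** (one instrument): β = β_out/β_exp, first-order delta-method
  se = se_out/|β_exp|.
- **IVW** (k ≥ 2): ratio meta-analysis with weights w_j = β_exp,j²/se_out,j²;
  fixed-effect se 1/√Σw inflated by √(Q/(k−1)) when the dispersion exceeds 1
  (multiplicative random effects — the common default of the standard
  two-sample-MR toolchain). With k = 1 it reduces exactly to the Wald ratio.
- **MR-Egger** (k ≥ 3): weighted regression of β_out on β_exp with intercept,
  weights 1/se_out², exposure pairs jointly oriented positive; residual
  dispersion multiplies the coefficient variances when > 1, and intercept/
  slope p-values use t(k−2). A design with no spread in β_exp is
  unidentifiable and reported as IVW alone.

First-order ratio SEs ignore exposure-side sampling noise; with strong
instruments that noise surfaces as apparent heterogeneity, which the
multiplicative random-effects inflation absorbs — the coverage calibration
test runs under exactly this regime.

Steiger directionality: per-instrument variance explained r² = z²/(z²+n−2)
on each side, aggregated by summation (assumes post-clumping independence;
`aggregate="max"` available), direction correct when the exposure aggregate
exceeds the outcome aggregate. The p-value is a two-sample Fisher-z test on
the implied correlations with se = √(1/(n_exp−3) + 1/(n_out−3)); the exact
test the original analyses used is not specified anywhere authoritative, so
this standard construction is the package's choice. Steiger runs both as a
per-instrument filter (default, dropping reverse-direction instruments) and
as a whole-feature aggregate test reported on the result.

The MR stage is tier-gated: only Strong/Moderate features whose direction
flag is not False are analysed; requesting MR for anything else raises a
gating error, and the pipeline's reports therefore never contain an MR row
for a Weak/None or direction-inconsistent feature (a tested invariant).
Replication against an external cohort is "replicated" when some validation
estimate shares the sign at p < 0.05, "trend" on sign agreement alone, else
"not-replicated".

## Synthetic data

LD panels are AR(1), r[i,j] = ρ^|i−j| (default ρ = 0.6, block size m = 50,
mimicking a cis window) — analytically tractable, strictly positive
definite, and deterministic given (m, ρ).

GWAS z-scores follow the standard multivariate-normal summary-statistic
model: z = α·√n·(Rw)/√(wᵀRw) + ε with ε ~ MVN(0, R), so the screen's Z is
exactly N(0,1) under α = 0 and the ε = 0 closed form is testable. Effects
stay in per-SD units with se = 1/√n even for the binary outcome — every
downstream statistic consumes (β, se, z, n) identically and case/control
counts are metadata. Default sample sizes mirror the scale of the large
published resources this emulates: ~229k (122,977 cases / 105,974 controls)
for the outcome GWAS, 7,213 / 31,684 / 396 for the plasma, whole-blood and
tissue QTL layers.

Colocalization scenarios place causal SNPs with expected marginal |z| =
`effect` (default 8, comfortably past genome-wide significance); H3 requires
a SNP pair at r² < 0.2 and errors when ρ and m make that impossible. MR
instrument sets draw true exposure effects from N(0, 0.15²), add sampling
noise, and keep a variant only when its *observed* p passes 5e-8 —
mimicking selection, including its mild winner's curse. Outcome effects are
α·β_true + pleiotropy + noise, with default n_exp = 35k and n_out = 230k
(pQTL-cohort and GWAS scale).

The full study scenario plants exactly one causal cis-SNP per feature — the
single-pQTL regime that dominates plasma-protein data — shared across the
three layers, so a causal feature shows a significant, colocalizing signal
everywhere and its confirmatory MR routes through the Wald ratio; the
multi-instrument IVW/Egger paths are exercised by the instrument-set
generator instead. Features occupy independent loci. Because the causal SNP
is shared by construction, MR here estimates the outcome effect per SD of
the feature (α divided by the per-allele QTL effect), and recovery is judged
by the CI excluding OR = 1 rather than by the numerical value of α.

What the generators do **not** emulate: realistic MAF spectra (frequencies
are constant), trans effects, multi-causal cis architecture, sample overlap
between exposure and outcome, population stratification, and binary-trait
effect-size attenuation. Passing calibration here therefore demonstrates
internal statistical correctness of the estimators and the gating logic,
not robustness to those real-data complications.

## Problem sizes and determinism

Calibration tests use 100 replicates for scenario recovery and the
end-to-end study, and 500 for estimator calibration — large enough that the
asserted bands are several Monte-Carlo SEs wide, small enough for an
interactive test run. All generators are pure functions of (parameters,
seed); the pipeline's report tables are byte-identical across reruns at a
fixed seed (a tested invariant).

## Known limitations

- Single-causal-variant colocalization only; no SuSiE-style multi-signal
  decomposition or conditioning on secondary signals.
- No MR-PRESSO, weighted-median/mode estimators or multivariable MR.
- Weight-model training is out of scope: weights are inputs (or synthetic).
- The tier vocabulary ("Weak/Moderate/Strong") quantifies evidence
  convergence across layers, not effect size.
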