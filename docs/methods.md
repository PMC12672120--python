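# Methods

## Design and assumptions

The package implements two-sample summary-data Mendelian randomization: the
exposure and the outcome associations come from different GWAS samples, and
causal effects are estimated from per-variant summary effects alone. The
three instrumental-variable assumptions apply throughout — instruments are
(i) associated with the exposure (relevance, enforced by the p/MAF/F
filters), (ii) independent of confounders, and (iii) affect the outcome only
through the exposure (exclusion). Assumptions (ii) and (iii) are not
verifiable from summary data; the sensitivity suite (Egger intercept,
Cochran's Q, MR-PRESSO, leave-one-out, Steiger) probes their failure modes.

All binary-trait effects are log odds ratios end to end; exponentiation to
odds-ratio scale happens only in reporting containers (`MREstimate.or_*`).

## Harmonization

Shared variants are aligned to the exposure's effect allele: identical
codings are kept, swapped codings sign-flip the outcome beta and complement
its allele frequency, strand-complement codings are complemented first.
Palindromic variants (A/T, G/C) carry no strand information in their allele
codes, so they are resolved by allele frequency alone: both frequencies
(expressed for the exposure effect allele) must fall outside the ambiguous
zone 0.5 ± `palindromic_eaf_window` (default 0.08, the de-facto standard of
summary-data MR tooling) and lie on the same side of 0.5; every other case —
a frequency inside the zone, a missing frequency, or frequencies on opposite
sides — is dropped as unresolvable. Dropping the opposite-side case is
deliberately conservative: some tools interpret it as a strand flip, but a
frequency disagreement of that kind can equally indicate a population or
annotation mismatch. Variants whose allele sets are incompatible between
the two traits are likewise dropped.

Genomic control computes λ_GC = median((β/se)²)/0.4549 (the χ²₁ median).
It is an inflation correction only: λ ≤ 1 leaves the set unchanged; λ > 1
multiplies every SE by √λ and recomputes p-values. It is applied per trait
set, so in a many-mediator analysis each mediator GWAS gets its own λ.

## Instrument selection

Defaults: p < 5×10⁻⁸, MAF > 0.01 (MAF = min(eaf, 1−eaf)), F ≥ 20 with
R² = 2(1−MAF)·MAF·β² and F = R²(N−2)/(1−R²), and an inclusive cis window of
±`cis_kb`·1000 bp (default 1,000 kb) around the gene footprint. Clumping is
greedy by p-value (ties: larger F, then lexicographic variant id, for
deterministic output) with r² < 0.1 within 10,000 kb. The clumping r² is
the squared pairwise LD correlation, supplied as an `LDMatrix` — a distinct
quantity from the instrument-strength R² above. LD is an input; the package
does not estimate it from genotype panels.

## Estimators

Weights are first-order everywhere: the Wald-ratio SE is se_out/|β_exp| and
the IVW/median/mode weight is β_exp²/se_out², ignoring exposure-side
uncertainty. This matches the dominant convention of summary-data MR
software; its cost (the NOME approximation) is visible in the Egger
validation below.

- **IVW** (primary). Fixed model ≡ weighted least squares of β_out on β_exp
  through the origin. The default multiplicative random-effects model
  inflates the SE by √max(1, Q/(k−1)): heterogeneity widens intervals but
  can never narrow them. Because of that one-sided floor the RE test is
  conservative by construction, so the null-calibration check in the
  acceptance suite exercises the fixed model, which is the exactly
  calibrated member of the family.
- **MR-Egger.** Rows are oriented so all exposure betas are non-negative
  before fitting (the InSIDE convention); SEs carry the over-dispersion
  factor √max(1, RSS_w/(k−2)) and inference uses t with k−2 df. The
  intercept estimates mean directional pleiotropy. Egger's consistency
  additionally requires negligible exposure measurement error; with noisy
  exposure betas regression dilution attenuates the slope and leaks a small
  positive bias into the intercept, which is why the intercept-recovery
  validation uses a very large exposure panel.
- **Weighted median.** Ratios are ordered; the estimate interpolates the
  ratio at cumulative normalized weight 0.5 using the midpoint convention
  s*ⱼ = sⱼ − pⱼ/2. SE from a seeded parametric bootstrap (default 5,000
  draws) resampling both exposure and outcome betas from normals with their
  reported SEs.
- **Mode estimators.** Normal-kernel density over the ratios with bandwidth
  h = φ·0.9·min(sd, IQR/1.349)·k^(−1/5) (φ = `bandwidth_factor`, default 1),
  maximised on a 512-point grid spanning the ratio range; simple mode uses
  uniform weights, weighted mode inverse-variance ratio weights. If all
  ratios coincide the common value is returned directly. SE by the same
  seeded bootstrap.
- **Wald ratio** for k = 1; IVW defers to it automatically.

### Sensitivity suite

- **Cochran's Q** on the ratio estimates about the fixed-effect IVW slope;
  χ²_{k−1} under homogeneity.
- **MR-PRESSO.** Observed residual sum RSS = Σⱼ wⱼ(β_out,ⱼ − b₍₋ⱼ₎β_exp,ⱼ)²
  with leave-one-out IVW slopes b₍₋ⱼ₎. The null distribution comes from
  `n_sim` seeded parametric simulations (default 1,000 — a desk-scale
  default; the add-one smoothing (1+#{RSS* ≥ RSS})/(n_sim+1) keeps p-values
  in (0,1]). Per-variant outlier p-values compare each observed contribution
  with its simulated distribution, Bonferroni-corrected at α/k. When
  outliers are found: a corrected IVW on the pruned set, and a distortion
  p-value comparing the observed estimate shift against shifts from removing
  equally many randomly chosen variants.
- **Leave-one-out** IVW re-estimates, one per excluded instrument.
- **Steiger.** Compares variance explained in the exposure (Σ per-variant
  R²) versus the outcome; for a binary outcome the outcome-side R² applies
  the same formula to log-odds effects, an approximation flagged as such.
  The p-value uses the Fisher z-transform of the two implied correlations
  with the respective sample sizes. Equal explained variance reports
  direction = false.
- **Power.** Two-sided asymptotic approximation
  Φ(|log OR|·√(N·R²·φ(1−φ)) − z_{0.975}) for a binary outcome with case
  fraction φ. At OR = 1 it returns α/2, the one-tailed margin of the
  approximation.

## Mediation

Three steps, each with the primary-method policy (IVW multiplicative-RE for
k ≥ 2, Wald ratio for k = 1): β₁ from exposure→mediator using the exposure's
instruments, β₂ from mediator→outcome using the mediator's own instruments,
β₀ from exposure→outcome using the exposure's instruments. Indirect effect
β₁β₂ with Sobel SE; mediated proportion β₁β₂/β₀.

The proportion's 95% interval treats β₀ as fixed: SE_prop = |indirect SE/β₀|,
equivalently SE = estimate/Z. This is the only rule consistent with a
symmetric interval whose half-width is 1.96·estimate/Z, and it is what the
package reports by default; a full two-term delta method (propagating se₀)
is available via the `se0` argument. Proportions outside [0,1]
(inconsistent mediation, sign-discordant paths) are reported verbatim with
an `inconsistent_mediation` flag — never truncated.

Screening across many exposures uses the primary method per exposure, raw
p < 0.05 flags, and Benjamini–Hochberg q-values (via statsmodels) whose
family is exactly the set of exposures that yielded an estimate in that
scan; exposures without instruments appear as NA rows with a reason and do
not enter the family. Entry into mediation is gated on raw p < 0.05 for
both the exposure→outcome and mediator→outcome scans; FDR flags are
reported alongside but do not gate.

## Synthetic data generator

`simulate_triple` generates summary statistics directly — no individual-level
genotypes — for one cis region under the structural model

    mediator = β₁·exposure + …,   logit(outcome) = direct·exposure + β₂·mediator + …

so the implied total effect obeys total = direct + β₁β₂ exactly, and the
true mediated proportion is β₁β₂/total.

Per-variant architecture: a `strong_fraction` of variants are exposure
QTLs with effect magnitude `strong_effect` (default 0.15 per allele, plus
N(0, `instrument_effect_sd`²) background), coded positive — the effect
allele is the trait-increasing allele, the usual QTL reporting convention,
which also makes "directional" pleiotropy directional on the ratio scale.
A disjoint `med_strong_fraction` are mediator QTLs with direct mediator
effects (`med_strong_effect`, default 0.8): these are the mediator's own
instruments, and their outcome effect flows through β₂. Without such
variants the mediator→outcome step is unidentifiable — every
mediator-associated variant would act through the exposure and the MR would
estimate total/β₁ rather than β₂. The large default magnitude emulates the
outsized metabolite-QTL effects that let even a 291-sample metabolite GWAS
yield genome-wide-significant instruments. Invalid instruments (an
`invalid_fraction` of variants) receive direct variant→outcome pleiotropy:
balanced (zero mean) or directional (mean-shifted), drawn independently of
the exposure effects so InSIDE holds.

Standard errors use the standard GWAS approximations
se = 1/√(N·2·maf(1−maf)) for continuous traits and
se = 1/√(N·φ(1−φ)·2·maf(1−maf)) for the binary outcome (logistic score with
case fraction φ). Observed betas are drawn independently per variant around
their true values; the AR(1) LD matrix (r = ρ^|i−j|, positive semi-definite
for ρ ∈ [0,1)) feeds clumping only. This is a documented simplification:
real summary statistics have LD-correlated effect noise, so the generator
exercises the clumping logic but not LD-induced estimator correlation.

Defaults mirror the emulated study regimes: exposure panel n = 31,684
(blood cis-eQTL scale), mediator n = 291 (small CSF metabolite GWAS),
binary outcome n = 431,880 with case fraction 0.0025 (a heavily imbalanced
biobank cohort; both published case-count presets are shipped as
`FINNGEN_ABSTRACT` and `FINNGEN_TABLE`). MAF uniform on (0.05, 0.5),
positions 5 kb apart on one chromosome, non-palindromic allele pairs, and
a gene region spanning the variant footprint so all variants are cis.

### What the generator does and does not emulate

It reproduces the statistical skeleton — effect/SE/p tables, allele coding,
sample-size regimes, pleiotropy structure, LD for clumping — but not
metabolite correlation structure, real LD patterns, population
stratification, sample overlap, or winner's-curse-inducing discovery
pipelines beyond the package's own selection step. Passing recovery tests
therefore demonstrates correctness of the estimators and workflow under the
stated model, not robustness to every artefact of real GWAS data.

## Validation regimes and problem sizes

The test suite validates at sizes chosen to make each property measurable:

- *Null calibration*: 1,000 replicates at 30 variants under the paper-scale
  regimes with all causal effects zero; fixed-effect IVW (see above) must
  hold its 5% size with uniform p-values.
- *Parameter recovery*: 200 replicates at 30 variants in a high-precision
  regime — balanced outcome (case fraction 0.5), mediator panel n = 200,000,
  MAF ∈ (0.1, 0.5). Chosen from a power calculation: with the imbalanced
  outcome default the IVW SE on the total effect (≈0.06 at β₀ = 0.2) makes a
  0.02 mean-bias bound unattainable for any estimator (the ratio's Jensen
  bias alone is ≈0.05), so the precise regime is the one in which estimator
  bias — the thing under test — dominates sampling artefacts.
- *Egger intercept recovery*: exposure panel n = 10⁶ so the NOME condition
  holds (see the estimator notes); directional pleiotropy mean 0.05 on all
  instruments.
- *Weighted-median robustness*: 40% invalid instruments with directional
  pleiotropy mean 0.06 — enough to bias IVW by >0.1 while valid instruments
  retain the weight majority.
- *MR-PRESSO*: 100 replicates at 10 variants; a planted 10·SE outcome
  outlier must be flagged in ≥95%, clean data in ≤5% per variant.

## Numerical choices and degenerate inputs

- All normal/χ²/t tail probabilities from scipy; p-values floored at 1e-300
  to stay in (0,1].
- z₀.₉₇₅ = 1.959964 (scipy's exact quantile) for every Wald interval.
- Bootstrap and simulation SEs are always seeded; the CLI fans a single
  config seed out to per-component seeds via `numpy.random.SeedSequence`
  spawning, so one integer reproduces a full run.
- Egger with no spread in (oriented) exposure betas raises a rank-deficiency
  error; weighted-median/mode SEs are floored at 1e-12 to keep the
  z-statistic defined for degenerate consensus inputs.
- Clumping tie-breaks (equal p: larger F, then variant id) make output order
  deterministic; results follow selection order.
- TSV round-trips serialize floats at 17 significant digits (exact for
  binary64) and missing values as `NA`; coordinates are 1-based inclusive,
  including the BED-like region files (a documented divergence from 0-based
  BED).

## Known limitations

- No multivariable MR, colocalization, LD-score regression, GWAS-VCF,
  liftover, or LD estimation from reference panels.
- One mediator at a time; no joint multi-mediator decomposition.
- The Steiger outcome-side R² and the power formula both use log-odds-scale
  approximations for binary traits.
- First-order weights throughout; very weak instruments (low F) violate the
  underlying approximation — the F ≥ 20 default filter is the guard.
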