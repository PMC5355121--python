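# Methods

## Scope and data model

`thiometa` synthesizes published evidence on *NUDT15* rs116855232 (T = risk
allele) and thiopurine toxicity. The unit of analysis is a cohort record:
genotype counts (TT/CT/CC) for a myelotoxicity case arm and a control arm,
and/or per-genotype summaries (n, mean, SD) of maintenance thiopurine dose
in mg/m² azathioprine equivalents. The packaged table holds 20 such records
from 11 articles: 7 case-control studies (602 cases, 1150 controls) and 13
dose cohorts. Articles contributing to both endpoints appear as two records
so each endpoint's study set is explicit; dose-only records carry no
case/control arms, and their per-genotype n counts every genotyped patient
with dose data (case and control arms combined where a study published
both, the only reading consistent with the published dose-arm total of
2745 patients). Absent cells are absent — never zero — throughout the TSV
dialect.

Two transcription choices worth knowing: cohorts that published dose only
for the combined carrier group are stored under a `T_CARRIER` label rather
than invented per-genotype splits, and groups printed as a bare mean (single
or near-single patients) store no SD. One source cell is internally
inconsistent (a raw SD of 13.4 that its own normalized column implies
should be 23.4); we transcribe the raw column verbatim, and the pooled dose
result is unchanged to 3 decimals either way.

## Genetic models

Each model maps an arm's genotype counts to (exposed, unexposed): allele
(2·TT+CT vs 2·CC+CT — the two alleles of an individual treated as
independent observations, which is what makes the allele-model denominators
reproducible), dominant (TT+CT vs CC), recessive (TT vs CT+CC), and the
genotype contrasts. For heterozygotes we provide both CT-vs-rest (CT vs
TT+CC) and the restricted CT-vs-CC; the per-genotype odds ratios published
for this literature follow the genotype-vs-rest convention (the recessive
contrast *is* TT-vs-rest), so CT-vs-rest is the default heterozygote
contrast in reports.

## Pooling conventions

* **Continuity correction.** Any 2×2 table containing a zero gets 0.5 added
  to all four cells, consistently in the per-study log OR and in the MH
  sums. A table with zero exposed (or zero unexposed) in *both* arms is
  uninformative about the OR and is excluded, with the reason carried on the
  result. These are the conventions of the classic dichotomous-outcome
  meta-analysis software, and they are required to reproduce the published
  pooled ORs to the printed precision.
* **Mantel–Haenszel fixed effects** with the Robins–Breslow–Greenland
  variance; MH is the default fixed method, inverse-variance is available.
  Heterogeneity for an MH analysis is computed from the per-study log ORs
  with IV weights around the IV-fixed estimate (standard practice; the two
  fixed estimates agree within 2% on the packaged table).
* **DerSimonian–Laird random effects**: τ² = max(0, (Q−df)/C),
  C = Σw − Σw²/Σw; random weights 1/(se²+τ²). When Q ≤ df this reduces
  exactly to the IV fixed result.
* **Model selection**: fixed iff I² < 50% and heterogeneity p > 0.1;
  anything else (including the boundary combinations the rule leaves
  unstated) falls to random effects, the conservative side.
* CIs use the 1.96 normal quantile; p-values are two-sided normal. JSON
  outputs keep full precision; rounding (2 dp for ORs/MDs, 4 dp for
  proportions) is display-only.

## Dose pipeline

Doses are made comparable in three steps: 6-MP → azathioprine equivalents
(×2.08, configurable), mg/kg → mg/m² via Meeh–Rubner A = k·W^(2/3)/10⁴
(k defaults to 10.1, the common human value; the packaged table already
stores mg/m², so this utility matters only for new data), and within-study
normalization by the CC mean (CC ≡ 1). Normalization is scale-invariant and
makes the drug conversion cancel within a study.

The T-carrier group is the published `T_CARRIER` row when one exists,
otherwise the CT and TT summaries combined by the exact pooled mean and
variance of concatenated samples ([(n₁−1)s₁² + (n₂−1)s₂² +
n₁n₂(m₁−m₂)²/N]/(N−1)). TT groups published without an SD cannot enter that
formula; the default policy (`drop_sd_less`) uses the CT summary alone,
and an alternative (`zero_sd`) folds the singleton in with SD 0. The two
policies move the pooled MD by about 0.013 on the normalized scale
(−0.262 vs −0.274), both within the reporting tolerance of the headline
result. Per-study effects are unstandardized mean differences on the
normalized scale (carrier − CC) with se = √(s₁²/n₁ + s₂²/n₂); groups
without n ≥ 2 and an SD are excluded with a reason. The dose endpoint pools
with DL random effects, matching the high heterogeneity (I² ≈ 67%) of the
13 cohorts.

## Bias and sensitivity

Egger's test regresses θᵢ/seᵢ on 1/seᵢ by OLS (the classic 1997 form) and
t-tests the intercept on k−2 df. Begg's test rank-correlates the
variance-stabilized deviates (θᵢ−θ̂_fixed)/√(vᵢ−1/Σw) with the variances
using Kendall τ_b; the p-value is the tie-corrected normal approximation,
with full-permutation exact inference available for k ≤ 8. Leave-one-out
re-pools with each study omitted and reports the min/max range; because the
MH estimator is a convex combination of per-study ORs, those estimates
always lie inside the hull of the single-study ORs. Funnel output is
plot-ready coordinates (points plus the θ̂ ± 1.96·se triangle); rendering is
an optional matplotlib layer.

## eQTL scan

Expression is regressed on additive dosage (0/1/2; any non-reference allele
counts, so indels behave like SNVs) with an intercept; slope t-test on n−2
df. Variants with fewer than 3 carriers are excluded before testing;
missing dosages drop the sample for that variant only. The scan is
vectorized (moment accumulation with missingness masks) and verified
variant-by-variant against `scipy.stats.linregress` in the tests. Raw
p-values are reported, mirroring how such scans are published;
Benjamini–Hochberg is an optional column. Coordinates are 1-based hg19. No
ancestry covariates are fitted — a known limitation, as the underlying
panel mixes populations. Reproducing the published top promoter signal
(P = 0.004 for rs554405994) requires the external expression/genotype
accessions and is out of scope; the stage is validated on simulated panels
instead.

## Synthetic generators

All generators are pure functions of their config, seeded through NumPy's
`default_rng` (PCG64), so outputs are bitwise reproducible for a NumPy
version. Case-control cohorts: per-study ln OR ~ N(ln OR₀, τ²), control
genotypes Hardy–Weinberg at the chosen MAF (default 0.1, East-Asian-like),
case genotypes Hardy–Weinberg at the logit-tilted allele frequency — the
tilt matches the allele-model OR definition, so pooled estimates are
directly comparable to the truth. Defaults mirror the packaged ensemble:
k = 7 with the fixture's arm sizes and OR₀ = 8. Dose cohorts: Gaussian
patient-level doses around a nominal CC dose (default 2.5 mg/m²,
IBD-scale; SD 35% of nominal) with carriers at (1−r)× nominal. eQTL
panels: independent Hardy–Weinberg variants (no linkage disequilibrium —
deliberately simpler than real panels), one causal variant, Gaussian noise,
n = 447 by default.

What passing simulation tests show: unbiased pooled log ORs and calibrated
CIs under the generator's assumptions (independent studies, binomial
sampling, no confounding), near-nominal type-I error for the bias tests,
and power to rank a planted eQTL first. What they do not show: behaviour
under linkage disequilibrium, population stratification, selective
reporting, or non-Gaussian dose distributions.

## Numerical and testing notes

Simulation-backed tests use fixed seeds and modest replicate counts
(100–500) chosen so Monte-Carlo error bounds, not wall-clock, set the
tolerances; the full suite runs in seconds. Statistical assertions are
stated as 2-Monte-Carlo-SE brackets or binomial coverage bounds rather than
single-draw events. The published dominant-model pooled OR is the one
headline number the packaged counts do not reproduce exactly under any
consistent convention (we obtain 9.37 vs 9.48 published, a 1.2% gap;
all other pooled ORs and CIs match to the printed precision) — the
acceptance test for that band records the discrepancy rather than papering
over it.
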