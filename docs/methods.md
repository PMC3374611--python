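# Methods

This note documents the statistical model behind each stage, the defaults
and their rationale, what the synthetic cohort generator does and does not
emulate, and the numerical conventions adopted where the design was open.

## Expression QC

Inputs are assumed to be normalized log2 test/reference ratios; background
correction and between-array normalization are upstream concerns and are
deliberately out of scope. Two steps are implemented:

* **Absent-probe filter.** A probe is removed only when *every* per-array
  quality flag is strictly below the threshold (default −50); a single
  array at or above the threshold retains it. The alternative reading —
  dropping a probe if *any* array flags it — would remove far more probes;
  the all-arrays reading is the adopted convention. The filter is
  idempotent and order-preserving.
* **Technical-duplicate averaging.** Replicate arrays are averaged
  columnwise (arithmetic mean of log2 ratios); missing values propagate as
  the mean of the non-missing replicates. Flags of merged arrays keep the
  elementwise maximum (most-present call).

Missing values elsewhere propagate as not-available; downstream
correlations use pairwise-complete observations.

## SAM differential expression

For a two-class unpaired comparison with groups A and B,

    d_i = (x̄_iB − x̄_iA) / (s_i + s0),
    s_i = sqrt(a (Σ_A (x − x̄_iA)² + Σ_B (x − x̄_iB)²)),
    a   = (1/n_A + 1/n_B) / (n_A + n_B − 2),

so with s0 = 0, d is exactly the pooled-variance t statistic (asserted
against scipy at 1e-10). The fudge factor s0 is chosen from the
0,5,…,100th percentiles of s to minimize the coefficient of variation of
the median absolute deviation of d within 20 equal-count windows of s;
fixed-percentile and zero overrides exist. Expected order statistics d̄
come from label permutations — all distinct class assignments are
enumerated when there are no more of them than the requested permutation
count (default 200), making small balanced designs seed-independent.
Calling uses Tusher-style asymmetric slabs: scanning outward from the
origin of the d vs d̄ plot, the up (down) cut is the smallest (largest)
observed d whose sorted value exceeds its expected order statistic by at
least Δ, and every probe beyond the cut is called. FDR(Δ) is the median
across permutations of the number of permuted d values beyond the cuts,
divided by the number called (0 when nothing is called); q_i is the
smallest FDR at which probe i is called. The fold-change gate (default
linear 1.5, i.e. |mean difference| ≥ log2 1.5) applies to observed *and*
permuted calls, since selection imposes both criteria jointly; the π0
multiplier of later SAM versions is off by default. Permutations are
unrestricted (the unequal group sizes make balanced blocks inapplicable).
The three pairwise phenotype comparisons are reduced by set union, with
the seven Venn region counts reported.

## Gene clustering

The probe dissimilarity is D = 1 − Pearson r between expression profiles.
Ward linkage operates by default on d′ = √(2D): for profiles centered and
scaled to unit norm, ‖z_i − z_j‖² = 2(1 − r_ij), so d′ is a genuine
Euclidean distance and Ward's minimum-variance objective is well defined.
Running Ward directly on D is available by flag (`linkage_input="raw"`)
since the published analysis does not state which convention it used.
Agglomeration is delegated to scipy's nearest-neighbor-chain Ward, which
is deterministic; merge ties are vanishingly rare on continuous data.
The R² curve reports 1 − SS_within(k)/SS_total on row-standardized
profiles; it is 0 at k = 1, 1 at k = n, and nondecreasing. The number of
clusters is a user input — the published choices (43 for the selected
set, 265 for the full set) came from visual inspection — and an advisory
elbow (maximal second difference of R²) is reported on request, never
applied silently. Centroids: per-sample median (default), mean, or the
first-principal-component score vector of the cluster submatrix
(sign-oriented to correlate positively with the cluster mean). A
concentration check cross-tabulates a selected-probe clustering against
an all-probe clustering: for each coarse cluster, the fraction of its
probes inside its two most-populated fine clusters, flagging clusters at
or below 40%.

When the SAM union is too small to support the requested cut (fewer than
max(2k, 20) probes), the pipeline driver clusters the full QC'd probe set
instead and records that in the manifest — pre-selection is a
dimension-reduction aid, not a prerequisite.

## Composition and CLR

Genus counts are summed into the seven fixed categories; relative
frequencies close each sample to 1. The MANCOVA response is the CLR of
the six-category sub-vector (Other excluded): clr_c = ln p_c − mean ln p
over the six, natural log (Aitchison convention; the base only rescales
the response, and pseudo-F is scale-invariant, which a test asserts).
CLR is closure-invariant, so renormalizing the six frequencies after
dropping Other is immaterial (also asserted). Zeros are handled before
closing by a multiplicative pseudocount: default +0.5 reads per category
count; alternatives add half the smallest nonzero entry, or refuse zeros.

## Permutational MANCOVA

With response Y (n samples × 6 CLR coordinates) and an ordered term list,
design matrices carry an intercept; categorical terms are dummy-coded
against the first sorted level with their levels−1 columns pooled into
one term. Sequential SS of term t is tr(Y′(H_t − H_{t−1})Y) with H_t the
hat matrix of the design through term t; for Euclidean geometry this
equals the pairwise-distance form of permutational MANOVA, and for a
univariate response the classical ANOVA decomposition (asserted at
1e-10). Partial R² = SS_t/SS_total; pseudo-F_t uses the full-model
residual. Permutation P values use (1 + #{F* ≥ F})/(1 + n_perm) — never
zero — except under exhaustive enumeration of all n! row permutations
(small n), where P = #{F* ≥ F}/n! including the identity, reproducing
exact small-sample values such as 2/20 for the (1,2,3)/(4,5,6) worked
example. The default scheme is Freedman–Lane: residuals of the
reduced model (terms before t) are permuted and added back to its fitted
values, keeping the test's size correct in the presence of strong
covariates (asserted by simulation); raw response permutation is
available, and the two coincide exactly when the reduced model is
intercept-only. n_perm defaults to 999.

**Stepwise selection** is forward-only by default: each round offers every
remaining candidate as the last term of the current model; all candidates
in a round share one set of permutations (and one reduced model), so
their P values are directly comparable. The candidate with the smallest
P enters (ties: larger F, then name order) if P ≤ α_enter (default 0.05);
selection stops when none qualifies. Aliased candidates (no rank added —
e.g. a copy of an entered term) get F = 0, P = 1 and can never enter.
An optional backward pass drops entered terms whose conditional-last P
rises above the threshold; `forced_first` supports designs where, e.g.,
phenotype is entered unconditionally (the published account does not say
whether phenotype was forced or won entry). Samples with missing
candidate covariates are dropped listwise with a logged count. The final
model is re-reported as a sequential table in entry order.

## Correlation screen

Within each phenotype stratum, Pearson (default; Spearman optional)
correlation between each selected transcript and each genus relative
frequency on pairwise-complete observations; cells with n < 3 or zero
variance are marked unavailable. Two-sided P from
t = r√((n−2)/(1−r²)) on n−2 df (|r| = 1 ⇒ P = 0), which matches a
permutation oracle within Monte-Carlo error. Flags are +1/−1 for
positive/negative correlations at P < α (default 0.05), else 0 — the
red/green square display. BH q values are computed over the whole grid by
default (the screen is one family); per-stratum families are selectable.
The BH step-up rule is implemented directly (q_(i) = min_{j≥i} p_(j)m/j,
capped at 1) and cross-checked against statsmodels.

## Cohort summary

Pearson chi-square without continuity correction for categorical
covariates (three-group tables dominate; correction selectable),
Kruskal–Wallis with tie correction for age and BMI, BH over the table's
12 tests, significance flag at FDR ≤ 0.05. Censored published P values
("<0.001") are represented at the censoring bound for the BH column;
with that representation the five censored entries share q = 0.0024
(12/5 × 0.001 is dominated by the next entry's 0.006), while the true
uncensored P values would yield q below the censoring bound. All
uncensored FDR values reproduce exactly at printed rounding.

## Synthetic cohort generator

The generator emulates the paired design the pipeline was built for:

* **Cohort**: 34/27/23 subjects (CD/UC/Control). Covariates are sampled
  independently per subject from the published marginal frequencies
  (e.g. NOD2 risk-allele carriage 35%/19%/13%); age and BMI are drawn
  from truncated normals matching the published medians and ranges, so
  the age–phenotype confounding of the real cohort is present (switchable
  via `age_shift`). Covariate–covariate correlation beyond phenotype is
  not modeled.
* **Expression**: each of the (default 400) probes loads on exactly one
  of (default 10) latent factors with loading U(0.6, 1.4), plus a probe
  intercept N(0, 0.3) and N(0, noise_sd²) noise (default sd 0.1 log2
  units). Latent factor scores are standard normal per sample.
* **Composition**: per-sample category log-abundance = log baseline +
  phenotype effect + effect_matrix′ · factor scores, softmaxed to
  category probabilities, split uniformly across each category's genera
  (35 named ileal genera, 5 per category), and realized as
  Dirichlet–multinomial counts: Dirichlet concentration 50 × genus
  probabilities (454-scale overdispersion), multinomial depth 5000
  reads/sample. Depth is a configurable guess — per-sample depths were
  not published. The default baseline composition
  (0.05, 0.25, 0.20, 0.25, 0.05, 0.15, 0.05) is a plausible ileal
  profile, not a published value. Default phenotype effects encode
  CD-like dysbiosis (Clostridium IV down, Proteobacteria up); the default
  effect matrix plants one factor→Proteobacteria association.
* **Truth**: factor scores, probe→factor assignment and the effect matrix
  are recorded (and written as tab-separated truth files) for recovery
  tests.

Two canned configurations support the simulation studies: `null_config`
zeroes every composition effect (type-I calibration) and
`planted_config` keeps a single factor→Proteobacteria effect (default
0.7 on the log scale) whose truth-assignment centroid explains roughly
20–30% of the CLR variance — comfortably above the ≥15% floor the
recovery study assumes.

What the generator does **not** emulate: raw 16S reads (chimeras,
classification error), probe-level microarray artifacts, genotype-driven
composition effects (NOD2 acts only as a generic covariate), or
covariate correlation structure. Passing calibration/recovery tests
therefore demonstrates correctness of the statistical machinery under
the stated generative model, not robustness to those real-data
complications.

## Calibration and recovery studies

* **Stepwise size**: the published 2–9% acceptance band is the binomial
  95% interval for one 5%-level test over 200 replicates. A forward
  round over k candidates fires with probability ≈ 1 − 0.95^k, so the
  calibration offers a single candidate per null cohort (the first latent
  cluster's centroid, which has no composition effect): the calibrated
  unit is the per-candidate entry test. With 999 permutations the entry
  P is uniform on {1/1000, …, 1} and P ≤ 0.05 has probability exactly
  0.05.
* **Per-term size**: 3-term MANCOVA (phenotype, age, gender) on null
  cohorts; rejection rate pooled over terms.
* **Recovery**: 100 planted cohorts (200 probes each); candidates are the
  ten truth-assignment centroids plus four clinical covariates; the run
  stops after the first entry, which must be the planted centroid. Ward
  recovery of the planted probe blocks (ARI = 1 at noise sd 0.05) is
  asserted separately at the full cut, so chaining clustering into the
  100-replicate loop would add runtime without adding evidence.
* Replicate cohorts for the calibration studies use 40–60 probes — the
  composition response and one centroid are all these studies consume —
  keeping each study in the tens of seconds on one CPU.

## Numerical conventions

* Hat matrices via SVD orthonormal bases; rank tolerance 1e-10 relative.
* Permutation F comparisons use a 1e-9 relative slack so that
  permutations reproducing the observed partition count as hits.
* Stepwise candidate ties break by smaller P, then larger F, then name.
* The correlation dissimilarity matrix is symmetrized and clipped to
  [0, 2] before linkage to absorb floating-point drift.
* Pipeline stage seeds derive from the global seed by stage-name CRC
  mixing, so a stage re-run in isolation reproduces its in-pipeline
  stream; all seeds stay below 2³¹.

## Known limitations

* SAM's Δ grid is capped at 100 quantile points of |d − d̄|; q values are
  step functions of that grid.
* The stepwise entry P values are not selection-adjusted; with many
  candidates the familywise entry rate exceeds α by design (forward
  selection's usual behavior), which the calibration section quantifies.
* The permutational MANCOVA supports Euclidean (CLR) geometry only; no
  Bray–Curtis or strata-restricted permutations.
* Exhaustive permutation enumeration is limited to n ≤ 9 samples.
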