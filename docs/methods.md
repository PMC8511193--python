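# Methods

## Model and procedure

### The discordance statistic

Let a reference panel of H phased haplotypes over L biallelic SNP sites be
given. A plasma sample is sequenced at shallow depth; at site *j* the
pileup carries `(ref_count, alt_count)`. Observed genotypes are called by
the minimal rule (no reads → missing; only ref → 0; only alt → 2; both → 1),
which coincides with a likelihood caller in the one-read-per-site regime
that dominates at ~0.1x.

Imputed genotypes come from a diploid Li–Stephens copying HMM. The hidden
state is an ordered pair of panel haplotypes (H² states). Between adjacent
sites each copied haplotype independently stays with probability 1−ρ or
jumps to a uniformly random haplotype with probability ρ; at a site with
counts (r, a), each copy contributes alt probability q = h(1−μ) + (1−h)μ,
a read picks either copy with probability ½ giving θ = (q₁+q₂)/2, and
sequencing error folds in as θ′ = θ(1−ε) + (1−θ)ε; the emission is
θ′^a (1−θ′)^r. Zero-depth sites emit likelihood 1, so their posteriors are
purely LD-driven. Genotype posteriors are the state posteriors contracted
against the Bernoulli(q₁)×Bernoulli(q₂) allele model; hard calls are the
argmax with ties broken toward the smaller dosage. Forward–backward
messages are rescaled per site, which keeps runs of 10⁴ sites finite.

Imputation runs per window (default 5 Mb) with flanking buffer sites
(default 250 kb) included in the HMM but excluded from the report. The
buffer only decouples windows when it covers the HMM's state-memory length
(≈ 1/ρ sites modulated by how identifying the local reads are); with the
defaults and sparse toy genomes some edge influence remains, identically
distributed across samples and therefore absorbed by the regression.

The **regional LD-ratio** of a genomic bin (default 5 Mb, 0-based half-open
intervals, chromosomes 13/18/21/X/Y excluded, optional N-region mask with a
configurable 50%-overlap drop rule) is the proportion of *eligible* sites —
panel MAF above the cutoff and observed genotype non-missing — where the
imputed and observed genotypes disagree. Bins with no eligible site are
missing and filled from per-bin training means at design-matrix time.

Because plasma actually carries a third (fetal) haplotype, the discordance
rate rises with the fetal fraction F: at a site where the mother is
homozygous and the fetus carries the other allele, any fetal read flips the
observed genotype away from the (maternally dominated) imputed one, with
probability ≈ F/2 per read.

### The regression

The estimator is ordinary least squares of a reference fetal fraction
(chrY-based for male-bearing training cohorts; the trainer accepts any
reference column) on the B bin ratios plus three confounders. A per-sample
weight hook exists but defaults to uniform weights — no principled
per-sample weighting scheme presents itself for this response, so plain OLS
is the default. Training is single-pass: fit, compute the seven influence
diagnostics, remove the union of flagged samples, refit. The diagnostics
use the closed leave-one-out forms with p = number of non-intercept
coefficients:

* standardized residual e_i / (s √(1−h_ii)), s² = RSS/(n−p−1);
* deleted variance s²_(i) = (RSS − e_i²/(1−h_ii))/(n−p−2);
* externally studentized residual t_i = e_i / (s_(i) √(1−h_ii));
* DFFITS_i = t_i √(h_ii/(1−h_ii));
* Cook's D_i = e_i² h_ii / ((p+1) s² (1−h_ii)²);
* COVRATIO_i = (s²_(i)/s²)^(p+1) / (1−h_ii).

Criteria 1–3, 6 and 7 flag the single most extreme sample (the wording
"samples show maximum..." is read as one argmax each); criteria 4 and 5 are
thresholds (h_ii > 2(p+1)/n, |DFFITS| > 2√((p+1)/n)) and may flag several.
The filter runs once, not iteratively — the criteria describe a screen, not
a schedule.

The MAF filtering cutoff is chosen by grid search over {0.15, 0.2, 0.25,
0.3}: per cutoff the features are recomputed, the model fitted and
refitted without outliers, and the training Pearson R recorded; the
highest R wins, ties break to lower MAE then smaller cutoff. Rank-deficient
designs are recorded as failed, never silently chosen. Reported
fetal-fraction estimates are clamped to [0, 1] (matching the convention of
flooring chrY estimates at 0); the raw value is kept for diagnostics.

### Baselines

`chry_ff` inverts %chrY = male%chrY·F + female%chrY·(1−F). Calibration
values are inputs; the CLI defaults (male 0.35%, female 0.02%) are
order-of-magnitude values for plasma chrY read fractions, not constants of
the method. `maf_ff` fits an n-component (default 3) Gaussian mixture by EM
(deterministic k-quantile initialization, tolerance 1e-8, capped
iterations) to minor-allele read fractions in (0, maf_upper], default
maf_upper 0.25, at sites with depth ≥ 30 (the estimator needs deep data;
the statistic is meaningless at NIPT depths). The fetal component is the
largest-weight component with mean above a noise floor (default 0.005, the
homozygous-error band); F̂ = 2 × its mean, with a `no_fetal_signal` flag
when nothing clears the floor. The mixture order and the component
selection rule are design choices: the underlying principle only states
that the fetal peak sits at F/2.

## The synthetic-data generator

The simulator emulates exactly what the estimator consumes and nothing
more:

* **Panel**: mosaic copying — two Bernoulli(0.5) founders, each later
  haplotype copies a random earlier one with per-site template switches
  (default 0.02) and miscopies (default 0.01). This produces genuine,
  decaying LD (verified: adjacent-site r² exceeds distant r²) without a
  coalescent model; the estimator needs LD structure, not genealogies.
* **Trio**: parental haplotypes are fresh mosaics of the panel (related to
  but not verbatim rows); the transmitted fetal haplotype recombines the
  two maternal haplotypes (default 0.005/site).
* **Pileup**: depth ~ Poisson per site (default mean 1.0, the shallow NIPT
  regime); each read is fetal with probability F, draws one of its source's
  two alleles uniformly, and flips with the error rate (default 1e-3).
* **Confounders** are synthesized (MQ>0 coverage as 90–100% of total,
  duplication rate jittered around its mean) — they exist so the model
  surface matches real pipelines, not to encode biology.
* **chrY fractions** are binomial draws from the linear mixture; fetal sex
  is not simulated at the autosomal level.
* **MAF samples** for the mixture baseline idealize the deep-sequencing
  minor-allele-fraction distribution as a Gaussian bump at F/2 (default sd
  0.005) over a near-zero error band — the high-depth limit, not a
  read-level model.

Cohort fetal fractions default to Uniform(0.01, 0.30), spanning the
clinically relevant range including sub-5% samples.

What the simulator does **not** capture: fragment-length and nucleosome
structure, GC and mappability bias, alignment artifacts, population
stratification between sample and panel, maternal CNVs/mosaicism, twins.
Passing tests therefore demonstrate the internal correctness and the
qualitative behaviour of the method, not clinical performance.

## Test and verification design

* The imputation engine is verified against exhaustive hidden-path
  enumeration (all (H²)^L paths, H ≤ 4, L ≤ 4, tolerance 1e-10) and the
  influence diagnostics against explicit leave-one-out refits (tolerance
  1e-8) — independent oracles, not alternative library calls.
* The monotone LD-ratio check uses paired cohorts: the same 20 trios and
  the same read-sampling seeds are re-mixed at each fetal-fraction level
  {0, 0.05, 0.10, 0.15, 0.20}. Common random numbers isolate the F effect
  from genotype-composition and depth variance; the mean ratio is required
  to increase strictly across levels.
* End-to-end recovery trains on 200 simulated samples and predicts 50 held
  out, on a deliberately small genome (2 chromosomes × 10 bins × 100
  sites/bin, panel H = 40, depth 1x). At this scale the per-sample
  information is limited: ~450 eligible covered sites give a binomial
  noise floor of σ_F ≈ 0.07, so held-out correlation plateaus far below
  what a genome-scale SNP set (millions of common sites) supports, and
  the 23-predictor OLS loses
  further accuracy to overfitting at n/p ≈ 9. The accompanying test states
  the ambitious bar (R ≥ 0.9, MAE ≤ 0.02); the measured values at this
  problem size are reported by `scripts/acceptance.py` and fall well short
  of it — a scale limitation of the toy genome, documented rather than
  hidden. The window/buffer/MAF-grid settings themselves are the published
  defaults.
* The MAF-cutoff selection check constructs cohorts where fetal
  discordance exists only at sites with MAF > 0.2: 85% of panel sites
  (H = 20, 2400 sites) are rewritten into the (0.15, 0.2] MAF band
  (destroying their LD) and the fetus is forced to inherit exactly the
  maternal alleles at all low-MAF sites. A cutoff of 0.15 then adds
  noise-only sites to the features, and the grid search must not select it
  (5 fixed seeds; two 5 Mb bins and n = 240 keep the training correlation
  informative).

## Numerical and degenerate-input choices

* Posterior triples are renormalized to sum to 1; argmax ties break toward
  the smaller dosage for determinism.
* Rank deficiency raises an error naming the collinear columns (pivoted QR).
* Leverage h_ii = 1 raises a degenerate-leverage error before any deleted
  statistic divides by zero.
* Missing observed genotypes are excluded from both numerator and
  denominator of the LD-ratio; a missing bin with no training fill value
  is an explicit error naming the bin.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  simulator is bit-reproducible under a fixed seed.

## Known limitations

* The observed-genotype caller is the minimal counting rule, declared as a
  stand-in for a full likelihood caller; the two coincide at ≤ 1 read.
* Transitions use a constant per-adjacent-site switch probability; no
  genetic map is modelled.
* No fixed human-genome bin layout is bundled: bin counts follow from
  whatever chromosome lengths and mask are supplied, and the N-region mask
  rule (drop a bin at > 50% overlap) is a declared choice rather than a
  community standard.
* Windowed imputation assumes the buffer covers the HMM state-memory
  length; with very sparse sites and small ρ, window-edge posteriors can
  deviate from a whole-chromosome run.
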