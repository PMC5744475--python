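# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the limits of what the test suite demonstrates.

## Study design being modeled

The package targets dry-seed stored-mRNA studies with a four-group design:
wild type (WT), a dormant mutant (D), the same mutant after long dry
after-ripening (AR), and a genetic rescue line (GID1bOE), each in triplicate
on an ATH1-like gene-level array (~22,810 genes plus control probesets).
Contrasts are two-group comparisons named `AvsB` with logFC = mean(A) −
mean(B); "up in AvsB" means higher in A.  The three default contrasts chain
through the design (DvsWT, ARvsD, GIDvsD), which lets the simulator define
group effects consistently: each group's additive log2 effect is the
previous group's effect plus the contrast's planted logFC, so realized
differences equal planted values exactly in the zero-noise limit.

## Differential abundance

Gene-level log2 matrices are cleaned of control probes (case-sensitive id
prefix, default `AFFX`) and quantile-normalized: every sample's sorted
vector is replaced by the across-sample mean of sorted vectors; tied values
receive the mean of their tied target positions (implemented via average
ranks and linear interpolation into the target vector).  This stands in for
probe-level RMA normalization because the package deliberately starts at
gene-level matrices.

The per-gene test is a two-group empirical-Bayes moderated t.  Sample
variances are pooled within the two groups (d_g = n_A + n_B − 2).  Under
the hierarchical model s²_g ~ s₀²·F(d_g, d₀), log s²_g has closed-form mean
and variance in digamma/trigamma functions; matching the empirical moments
of log s²_g gives d₀ (via Newton inversion of the trigamma function, 50
iterations, relative tolerance 1e−10) and s₀².  When the observed spread of
log-variances does not exceed the chi-squared sampling spread, d₀ = ∞ and
every gene receives the common variance (p-values then use the normal
distribution).  `prior_df=0` reduces exactly to the ordinary pooled t and
`prior_df=∞` to the common-variance t — both covered by tests, and the
default estimator is verified against the Bioconductor limma `eBayes`
implementation (agreement ~1e−11 relative on t-statistics in the
cross-check test, asserted at 1e−6).

Multiple testing uses Benjamini–Hochberg step-up (statsmodels) at α = 0.05;
classification splits significant genes by logFC sign (exact zeros are
excluded as directionless).  Distribution skew is the adjusted
Fisher–Pearson coefficient G1 with the (n−1)-denominator standard
deviation; it requires n ≥ 3 and nonzero variance, and is antisymmetric
under negation.

## Gene-set analyses

**Term enrichment** is the one-sided hypergeometric upper tail
P(X ≥ observed) with margins (genome N, term K, query n), equal to the
one-sided Fisher exact test; `expected = n·K/N` is reported for
Observed-vs-Expected tables.  Query genes outside the genome and terms with
no genome members raise errors rather than scoring silently.  BH adjustment
across terms; default significance cutoff adjusted p < 0.01.

**TF-target enrichment** reuses the identical raw p-value but adjusts with
Benjamini–Yekutieli (BH inflated by c(m) = Σ 1/i), appropriate because
target sets of different TFs overlap arbitrarily; TFs with fewer than 5
target hits inside the query are excluded before testing, preventing
spuriously small p-values for TFs with few known targets.  The hit minimum
counts query∩targets, not target-set size.

**TF databases** merge by id union; family-label conflicts keep every label
with source tags, and the primary family follows source input order (the
merge is membership-associative; only the primary label depends on order).
Family counting uses primary labels only, with non-TF query genes reported
as a residual so counts always partition the query.

**TAGGIT** assigns a gene every category whose id list contains it *or*
whose keyword matches its description (case-insensitive substring);
multi-category membership is allowed and each matched category counts once.
Profiles report per-category percentages of the full direction totals
(classified + unclassified), matching how up/down TAGGIT panels are scaled.
The 26-category schema ships with default keywords; id lists are pluggable
data because the original curated lists are external.  The random control
draws disjoint up/down sets uniformly from the genome and summarizes
per-category |up% − down%| over repeated seeded draws.

## Overlap and mRNA-stability association

Directional overlap intersects two up/down pairs requiring direction
agreement; discordant genes (up in one, down in the other) are reported
separately.  Shared percentages are of the first dataset's direction totals,
rounded half-away-from-zero to integers to match how such percentages are
conventionally quoted.

Half-life binning uses edges {1, 3, 6, 12, 24} h, left-closed/right-open
with a closed top bin; half-lives above 24 h map into the 12–24 h bin
because the source stability scores cap there (an explicit package
decision).  Stability association computes per-bin up/down fractions over
scored genes only and reports coverage (scored/queried).  Heatmap ordering
is descending half-life, ties broken lexicographically by id, unscored genes
appended in input order.

## Dry-storage decay model

Stored transcripts decay with first-order kinetics parameterized by
half-life h (hours): N_i(t) = N_i(0)·2^(−t/h_i).  The hypothesis being
formalized is that dry-seed "regulation" can arise from preferential
degradation alone; exponential decay is the simplest model consistent with
a half-life parameterization.  Optional renormalization rescales the
decayed vector to the initial total mass on the linear scale, emulating
hybridization of equal RNA amounts: relative to t = 0 the most stable
transcripts then show positive apparent log2 ratios.  With equal starting
abundances the apparent logFC is strictly increasing in half-life
(Spearman ρ = +1 in the noiseless limit) and total mass is conserved to
machine precision — both asserted in tests.

## qPCR ΔΔCt

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the calibrator
condition's mean ΔCt; RQ = 2^(−ΔΔCt) assuming amplification efficiency
exactly 2 (justified when the dilution-curve screen passes: efficiency
E = 10^(−1/slope) − 1 within ±10% of 1 and pairwise spread ≤ 10%;
an efficiency-corrected Pfaffl mode is deliberately deferred).  Condition
means are taken on the ΔΔCt (log) scale, which makes the calibrator's mean
RQ exactly 1 by construction; per-replicate RQs and their sd are also
reported.  RQ is invariant to adding a per-sample constant to every Ct
(plate shifts cancel through the reference).  Pairwise condition tests are
Welch t (no equal-variance assumption) with Bonferroni–Holm step-down; the
default α = 0.07 preserves the convention of the validation experiments
this workflow accompanies and is configurable.

## Synthetic data: what it emulates and what it does not

Defaults mirror the study design: 22,810 genes + 64 control probes, 4
groups × 3 replicates, 3.5% of genes DE per contrast, planted |logFC| ~
|N(1.5, 0.6)| with sign imbalance π_down = 0.65, replicate noise Gaussian
on the log2 scale (sd 0.25), log-normal half-lives (median 4 h, σ_log 0.8)
with ~57% of transcripts scored, TF membership for ~7.5% of genes across 12
families, and per-category TAGGIT prevalence 0.8%.  Storage ages are 336 h
(2 weeks) for WT/D/GID1bOE and ~19 months for AR.  Category members carry a
genuine category keyword in their generated description, so keyword matching
is exercised for real; descriptions of unrelated genes use a vocabulary
disjoint from the keyword schema so membership is controlled.

Each generator operation draws from its own seed-derived stream
(`default_rng([seed, key])`), making every table a deterministic function of
the configuration and regeneration of one table independent of the others.

Not emulated: probe-level effects (PM/MM, background, spatial artifacts),
heavy-tailed or intensity-dependent noise, correlated genes, batch effects,
annotation errors, and any real biological coupling between TF families,
categories, half-life and differential abundance (memberships are planted
independently).  Passing recovery tests therefore demonstrates correctness
of the statistical machinery under the stated generative model, not
performance on real arrays.

The magnitude distribution of real after-ripening effects is not published;
the default (mean 1.5, sd 0.6 log2 units) was chosen once so that planted
effects are comfortably detectable at triplicate scale — a testability
choice, not a biological estimate.

## Problem sizes and tolerances

Tests and the acceptance script run the simulator at 800–2,000 genes for
property suites and once at full chip scale (22,810 genes) for the
end-to-end run — the full design completes in a few seconds, so these sizes
are chosen simply to keep each check focused.  Key tolerances: Fisher vs
enumeration 1e−10 relative over all margins with genome ≤ 60; moderated-t
pooled limit 1e−10 relative; limma cross-check 1e−6 relative; mass
conservation 1e−12 relative; ΔΔCt fold recovery 10% at 0.05-cycle noise;
TAGGIT random control mean |up%−down%| ≤ 2 points over 100 draws; null
mean false-discovery proportion ≤ 0.05 + 3·MC error over 100 null
datasets.  For the planted-skew property, a power calculation (documented
in the test) shows ≥ ~130 planted effects are required at the default
magnitudes for the G1 sign to be determined with 99% probability at
n = 800, so that test plants a 25% DE fraction.

## Known limitations

- Pairwise contrasts only; no joint linear model across all four groups,
  no paired designs, no array quality weights.
- Flat gene sets: no GO DAG propagation or term redundancy pruning.
- The shipped 26-category keyword schema is a functional stand-in; analyses
  of real data should plug in a curated id/keyword map (GMT + keyword TSV).
- ΔΔCt assumes efficiency 2; use the efficiency screen before trusting RQs.
- Half-lives above the 24 h cap are indistinguishable from 24 h in binning.
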