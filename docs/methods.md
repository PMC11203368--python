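# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic cohort does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Aneuploidy scoring (GWZ)

Arm-level amplicon sequencing of plasma cfDNA yields one read count per
chromosome arm.  We treat a sample as a vector of arm fractions (counts over
total retained reads — the only normalization computable from these inputs)
and studentize each arm against a panel of healthy diploid donors: subtract
the panel mean, divide by the panel SD (n−1 denominator, since panels are
small), square, and sum over arms.  Classification is inclusive at the
threshold (GWZ ≥ 5), a level associated with tumor fractions above ~10%.

Defaults: mapping-quality cutoff 15 (boundary kept), arm universe = 22
autosomes × 2 arms minus 13p/14p/15p/22p (40 arms; too few LINE-1 elements
on the acrocentric short arms), sex chromosomes excluded (all-female cohort,
avoids X-dosage artifacts).  21p is acrocentric too but is retained to match
the stated exclusion list; the list is configurable.

Null behaviour: a held-out healthy sample scored against an m-donor panel
gives per-arm squared studentized deviates with expectation
(1 + 1/m)(m − 1)/(m − 3) — a t-variate inflated by the sqrt(1 + 1/m)
prediction spread — so E[GWZ] ≈ n_arms · that factor (≈ 46.9 at m = 20,
40 arms).  The acceptance suite verifies the simulated null mean lands
within 20% of this; at seed 1 the ratio is 1.004.

## TSS-window methylation and DMR calling

Site counts are aggregated into half-open 1-based windows
[TSS − 1000, TSS + 1000); the 2-kb convention does not fix half-openness or
strandedness, so we fix them here: half-open, strand-independent, with a
site inside k overlapping windows contributing to all k.  BED input is
0-based half-open; the TSS of a feature is its 5′ end by strand.

Region filters: autosomes only; a region is dropped when it has zero counts
in strictly more than 75% of samples (zero in exactly 75% is kept).  The
missingness filter is applied globally over all samples, not per comparison.

Size factors are plain median-of-ratios over regions positive in every
sample.  The DMR test is a documented simplification of the standard NB
count-model workflow, not a numerical clone of it:

- per-region method-of-moments dispersion on size-factor-normalized counts,
  pooled across the two groups with (n_g − 1) weights;
- a log-linear trend log α ~ a + b·log(mean) fitted across regions, with the
  median dispersion as fallback when fewer than 10 regions are usable;
- 50/50 geometric shrinkage of the region estimate toward the trend,
  clipped to [1e-6, 10] — enough to stabilize n=8-per-side estimates
  without empirical-Bayes machinery;
- a two-parameter NB GLM (intercept + case indicator, log size factor as
  offset) fitted by vectorized IRLS across regions (tolerance 1e-8 on the
  coefficients, 50 iterations, natural-log coefficients clipped at ±30 so
  one-sided all-zero regions stay finite);
- Wald p from the normal reference, BH step-up across tested regions,
  DMR ⇔ q < α (default 0.05), direction = sign of the coefficient.

There is no outlier replacement, independent filtering or fold-change
shrinkage.  Calibration at the design size (8 vs 8, region mean ≈ 100,
dispersion 0.1): the null fraction of raw p < 0.05 is ≈ 0.06 and power at
planted |log2FC| = 1 is ≈ 0.87.  Smaller case groups (the 4–5-sample
subsets of the simulated cohort) are visibly more anticonservative — the
drivers report empirical FDRs of 0.10–0.18 at nominal 0.05 — which is the
expected cost of the Wald/normal reference at those sizes and worth keeping
in mind for real subsets that small.  Regions with all-zero counts on both
sides are excluded and carry no record.

## Hallmark derivation and downstream statistics

Hallmarks are pure set algebra over per-subset DMR id sets, each restricted
to the tumor-tissue DMR set so blood-only (e.g. leukocyte) methylation
changes cannot enter: DTE from pre vs post treatment, PP from resistant vs
sensitive before treatment, PR from the same contrast after.  Per-region
provenance (which side of the comparison it was unique to) is kept, and the
hallmark size always equals the sum of its provenance-side counts.
Fold changes attached to hallmark regions are case-vs-HBD by default; the
between-subset contrast is also supported.

Cox TTF screen: single covariate (sqrt-normalized region counts — the
transform is sqrt(count / size factor)), Breslow tie handling, damped Newton
on the partial likelihood to gradient < 1e-8, Wald p.  All subjects are
events by default because TTF ends at progression or at stopping therapy;
an event indicator is accepted for censored designs.  The estimate matches
a 1e-4-step grid-search oracle and lifelines to ≈1e-4, type-I error is
0.03–0.07 in null simulation, and the mean estimate at planted log HR =
log 2 (binary covariate, n = 200, 100 replicates) is within 0.1.

2×2 tests: Pearson chi-square N(ad−bc)²/(r₁r₂c₁c₂) without continuity
correction by default — the printed cohort p-values (0.372 / 0.843 / 0.583 /
0.04) reproduce exactly under the uncorrected statistic — with Yates
optional; Fisher's exact two-sided p sums hypergeometric probabilities not
exceeding the observed table's (small relative tolerance against
floating-point ties).

Enrichment: upper-tail hypergeometric p and enrichment factor (k/n)/(K/N)
per term; default filter p < 0.01, overlap ≥ 3, factor > 1.5; BH column
reported.  The background defaults to genes with a tested TSS region rather
than the whole genome, avoiding inflation from untestable genes.  Term
clustering uses Cohen's kappa between binary gene-membership vectors over
the union of query-overlapping genes, average linkage, tree cut where
linkage distance exceeds 1 − 0.3; the cluster representative is the most
significant member; DMR→gene mapping is the TSS region's own gene (no
distal assignment), and a cancer-hallmark pathway is flagged from 3 linked
DMRs (inclusive).

Sample clustering: distance 1 − Spearman ρ between sample columns, average
linkage, deterministic input-order tie-breaking; constant columns are an
error (rank correlation undefined).

## Variant filtering and signature refitting

The VAF filter keeps variants with ≥ 10 alt-supporting reads ("mutant
reads", so the support threshold applies to the alt allele) and VAF < 0.45
or 0.55 ≤ VAF ≤ 0.70: strictly below 0.45, closed high window — the verbal
definition does not fix inclusivity, so the boundaries are documented here
and configurable.  Donor-panel subtraction removes exact
(chrom, pos, ref, alt) matches.  SNVs are classified into the 96
pyrimidine-centred channels (substitution-major order C>A…T>G, then 5′ and
3′ base), reverse-complementing purine-reference records; the catalog total
always equals the retained SNV count.

Exposures solve min_{e≥0} ‖counts − P·e‖₂ by non-negative least squares;
fractions are exposures over the sample's total mutation count, so
unexplained spectrum mass lowers the fraction sum below 1 rather than being
redistributed.  Presence is called at ≥ 5% of attributed mutations — a
stand-in criterion, configurable, since assignment tools rarely state one.
Indel (ID83) channels are not classified from sequence (that requires a
reference genome and repeat annotation); precomputed ID count tables can be
refitted with the same solver.  The shipped 3-signature catalog is
synthetic (block-concentrated profiles with a flat floor), built for
identifiability in tests, and is not any published signature set.

## Synthetic cohort: what it emulates, what it does not

- Arm counts: multinomial draws at depth 1e5 over length-proportional
  GRCh38 arm fractions; cases perturb arm a's weight by
  (1 − tf) + tf·CN_a/2 (diploid CN 2) before renormalizing.  No GC or
  mappability bias, no overdispersion beyond multinomial.
- Methylation: NB counts (gamma-Poisson) with lognormal region means
  (median ≈ 90, spread ×e), uniform sample size factors in [0.7, 1.4],
  dispersion 0.1; a fixed fraction of regions (10%) carries ±1 log2FC in
  designated groups, each group affected independently with probability
  0.6, 70% hypermethylated (cancer methylomes show a hyper excess at TSS
  windows).  The effect-size distribution of real cohort DMRs is unknown;
  log2FC=1 and dispersion 0.1 are calibration choices, fixed once.  No per-CpG
  structure, no batch effects.
- Variants: somatic alt reads ~ Binomial(depth, tf/2) (heterozygous,
  copy-neutral — the simplest model consistent with the <45% VAF window);
  germline VAFs at 0.5 or 1.0 (30% homozygous); somatic channels from the
  planted signature mixture, germline channels uniform.  No sequencing
  error model, no indels, no read-level simulation.
- Survival: exponential TTF with hazard h0·exp(βx), h0 = 0.1, all events
  (optional censoring fraction).

Passing tests therefore demonstrate correct recovery under these idealized
conditions, not robustness to alignment artifacts, contamination, batch
structure or copy-number-driven VAF distortion.

## Problem sizes and determinism

The simulations run at: GWZ null 1000 replicates (panel 20, depth 1e5); DMR
null and power at 2000 regions, 8 vs 8; NNLS recovery over 20 seeds × 500
mutations; Cox recovery over 100 replicates at n = 200; cohort drivers at
2000 regions, 8 patients × 1000 variants.  These sizes give Monte-Carlo
error comfortably below the stated tolerances while keeping a full run in
seconds.  Every generator consumes an explicit integer seed
(numpy default_rng); the pipeline derives per-stage seeds from the run seed
with fixed offsets, and identical configurations produce byte-identical
outputs (each table carries the configuration hash and seed in a leading
comment line).

## Known limitations

- The DMR test's normal-reference Wald p is anticonservative below ~6
  samples per side; an exact or resampling reference would be needed there.
- GWZ assumes the panel and test samples share a depth regime; extreme
  depth imbalance changes the null spread.
- Kappa clustering recomputes all pairwise kappas (O(T²) in filtered
  terms), fine for hundreds of terms, not tens of thousands.
- Tumor fractions are consumed as externally estimated numbers (sample
  sheet column); no copy-number HMM is included.
- The resistant/sensitive dichotomy (progression within 6 months) is
  carried in the sample sheet, never computed.
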