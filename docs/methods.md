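# Methods

This note documents the statistical models behind `hermetia`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter when
comparing output against other tools.

## Coordinates and containers

VCF positions are 1-based; every internal interval (RoH segments,
consensus regions, truth tracts, BED output) is 0-based half-open.
`vcfio.region_to_bed` / `bed_to_region` convert between the two. The core
container is an unphased diploid dosage matrix (0/1/2, −1 missing) —
every statistic in the package is frequency- or dosage-based, so phasing
is never needed and never inferred.

## Site and genotype filters

Defaults follow common short-read SNP practice for a ~20–25× panel:
site QUAL > 75, per-genotype depth within 10–34×, site missingness
≤ 15%, biallelic SNPs only, and an optional minor-allele-frequency
filter at 0.1 (used upstream of RoH calling, where rare-variant noise
inflates heterozygote interruptions). The depth rule is applied
*per genotype* (out-of-range genotypes are set missing) before site
missingness is evaluated; applying it per site-mean instead would keep
individually unreliable genotypes, and GATK-style pipelines treat depth
as a genotype-level property. A site whose genotypes all fail depth is
removed by the missingness rule — the MAF rule never divides by zero.

The allelic-balance report flags samples whose mean minor-read fraction
at heterozygous calls falls below a threshold (default 0.25). Strongly
unbalanced het calls are the classic signature of cross-sample
contamination; the default is deliberately lenient and exposed as a
flag, and the report never removes samples automatically.

## LD pruning and LD decay

Pruning reproduces plink's `--indep-pairwise 50 10 0.1` semantics:
within a 50-SNP window advanced by 10 SNPs, any retained pair with
genotypic r² > 0.1 loses its later member (larger position) — a
deterministic greedy sweep. r² is the squared Pearson correlation of
dosage vectors over jointly non-missing samples; a monomorphic SNP has
undefined r², treated as 0, so it is never pruned for correlation.
LD decay averages the same genotypic r² in distance bins (100 bp by
default) up to 50 kb.

## Diversity and differentiation

Per-site, with n the observed allele copies (missingness-aware) and
n_A, n_a the alt/ref copy counts:

- π = 2 n_A n_a / (n (n − 1)) — the unbiased pairwise estimator;
- d_XY = p₁(1 − p₂) + p₂(1 − p₁) on sample frequencies (unbiased for
  between-population divergence because the two samples are
  independent);
- window F_ST = (Σ d_XY − Σ π̄_within) / Σ d_XY as a **ratio of sums**
  over the window, with π̄_within the mean of the two within-population
  per-site π values. This is the Hudson-style estimator in the
  convention of the popular windowed-statistics scripts; ratio-of-sums
  avoids the instability of averaging per-site ratios.

Windows tile each chromosome from coordinate 0 in `step` increments
(study settings 20 kb/20 kb with ≥ 100 genotyped sites, or the 100 kb
variant); windows below the site minimum are omitted rather than
reported with inflated variance. The outlier scan flags windows at or
above the empirical 99th percentile (linear-interpolation quantile,
ties all included) and merges adjacent flagged windows.

## Runs of homozygosity

Detection is the sliding-window scheme of detectRUNS-class tools. A
window of 20 consecutive SNPs advances one SNP at a time and counts as
homozygous if it contains at most 1 heterozygous and at most 1 missing
call. Each SNP is scored by the fraction of windows covering it that
are homozygous; SNPs above the threshold (0.05) are run candidates, and
maximal candidate stretches — split where consecutive SNPs are more
than 1 Mb apart — become runs if they hold ≥ 20 SNPs, span ≥ 250 kb and
reach ≥ 1 SNP per 100 kb. Window size, minimum SNPs and minimum length
are the study's stated settings; the remaining parameters follow the
detection tool's documented defaults and are all exposed in
`RoHParams`. The X-flagged chromosome is excluded by name (males are
hemizygous there, so "homozygosity" is not informative).

Consensus semantics: each captivity-status group's runs are
union-merged; the intersection of the two unions is "shared", and the
set differences are "captive-unique" / "wild-unique". The stricter
reading — intersection across every individual of a group — is
available behind `strict_intersection`, but union-merge is the reading
consistent with group spans far exceeding any single individual's span,
and it makes coverage decompose exactly:
|unique| + |shared| = |group union| (asserted in tests).

The clustering permutation test measures the number of 1 Mb genome bins
overlapped by at least one region. Under the null, each region is
independently re-placed (length preserved) uniformly on a chromosome
drawn with probability proportional to its length, restricted to
chromosomes long enough to hold it. Z standardizes the observed bin
count against the null; tightly clustered regions hit fewer bins than
expected, so clustering yields negative Z. The empirical two-sided p is
(1 + #{null draws at least as far from the null mean}) / (n + 1), which
is valid (never zero) and calibrated: under its own null the rejection
rate at α = 0.05 is 5% within Monte-Carlo error (checked over 200
repetitions of 1,000 randomizations in the acceptance suite; the
full-scale analysis uses 10,000). "Bins hit" was chosen as the
dispersion statistic because the input regions are already merged and
mutually disjoint — their raw union length is invariant under
re-placement and carries no clustering information.

Group comparisons (per-individual run counts and mean lengths, captive
vs wild) use the two-sided Wilcoxon rank-sum test, reporting the
Mann–Whitney U of the captive group: exact p for small tie-free groups,
normal approximation with tie correction otherwise (scipy's switching
policy, exact up to 8 per group or so in practice). Individuals with no
detected runs are excluded, mirroring the study's treatment.

## Introgression statistics

All four-taxon statistics use population alt-allele frequencies in the
arrangement (((P1, P2), P3), O) with frequency-based polarization: the
outgroup frequency p₄ enters the products directly,

    ABBA = (1 − p₁) p₂ p₃ (1 − p₄),  BABA = p₁ (1 − p₂) p₃ (1 − p₄),

so no hard ancestral call is made and sites where the outgroup is fixed
for the alternate allele contribute nothing.

- **D** = Σ(ABBA − BABA) / Σ(ABBA + BABA) over all complete sites. The
  standard error comes from a delete-one block jackknife over 20
  contiguous blocks of equal informative-site counts (block count
  exposed; contiguity is what makes the SE robust to linkage);
  Z = |D|/SE with a two-sided normal p. Across trios, p-values are
  Benjamini–Hochberg adjusted and a trio is retained only with adjusted
  p ≤ 0.05 **and** Z ≥ 3.
- **f_dM** is computed in windows of 50 informative SNPs (ABBA+BABA > 0)
  advanced by 25, as Σ(ABBA − BABA) over a dynamic-donor denominator:
  for sites where ABBA ≥ BABA the denominator substitutes
  p_D = max(p₂, p₃) into both P2 and P3 slots; otherwise the mirrored
  substitution p_D = max(p₁, p₃) with a sign flip. This bounds the
  statistic in [−1, 1] and makes it antisymmetric under P1↔P2 (asserted
  exactly in tests). Outlier tracts merge the top-1% windows.
- **f-branch**: for each branch b with sister clade a in a rooted
  population tree, and each donor C not below a or b,
  f_b(C) = median over P2 ∈ leaves(b) of min over P1 ∈ leaves(a) of
  f̂(P1, P2, C, O), where f̂ is the admixture-fraction estimator with
  the positive-branch donor substitution and negative estimates clamped
  to 0 (the statistic measures *excess* sharing). Cells the topology
  disallows are undefined (NaN), exactly as a correlation-reducing
  summary over trios should leave them. On a four-leaf tree with
  singleton clades the median and min collapse and f_b equals f̂
  exactly.
- **Mito-nuclear discordance** is computed from label maps: a sample is
  discordant when its (nuclear lineage, mito clade) pair is outside the
  allowed relation (study: a → {A, B1}, b → {B2}). A convenience helper
  derives leaf labels from a newick tree by nearest labelled reference
  leaf; the statistic itself never traverses trees.

The number of jackknife blocks and the exact f̂ variant inside external
f-branch implementations are not standardized; this package therefore
validates D/f_dM/f-branch against explicit brute-force oracles and
planted-tract simulations rather than against any published genome-scale
values, which would require the original data.

## Synthetic data model

Allele frequencies are drawn hierarchically under Balding–Nichols beta
drift: an ancestral frequency per site from a symmetric Beta(0.8, 0.8)
truncated to [0.05, 0.95] (so downstream MAF filtering has work to do),
a lineage frequency p_l ~ Beta(p(1−F_L)/F_L, (1−p)(1−F_L)/F_L), and a
population frequency drifted again with F_pop — multiplied by a
bottleneck factor for captive populations. Genotypes are Binomial(2, f)
per diploid; DP is negative-binomial around 22× (shape 100, near-Poisson,
matching depth-filtered short-read data where the 10–34× window retains
almost all genotypes); AD splits DP binomially at het sites.

Planted truth: autozygous tracts force the named sample homozygous
across the tract (one allele drawn per site at its population
frequency); introgression tracts re-draw the recipient's genotypes from
the donor population's frequencies. Overlapping tracts for one sample
and tracts outside their chromosome are rejected.

Only sites polymorphic in the emitted sample are written — a VCF holds
variants. Two consequences, both intended: (i) genome-wide
ratio-of-sums Hudson F_ST is unaffected by this ascertainment (excluded
sites contribute zero to both numerator and denominator), so the
closed-form calibration F_tot = 1 − (1 − F_L)(1 − F_pop), with the
expected between-population F_ST the mean of the two F_tot values,
holds exactly and `f_lineage_for_target_fst` inverts it; (ii) mean
per-site d_XY between lineages *increases* with F_L, as divergence
should — under pure drift the unconditional expectation of d_XY is
constant, and it is the variant-only ascertainment that restores the
monotone relationship seen in real variant data.

Defaults are the study conditions at desk scale: seven 5 Mb chromosomes
(S7 flagged as the X), two lineages with F_L calibrated to F_ST = 0.18
at wild F_pop = 0.05, a captive bottleneck factor of 8.4 reproducing
the ≈ 39% heterozygosity reduction (0.031 vs 0.051 in per-bp terms;
the generator reproduces the ratio on a per-variant-site scale), one
SNP per ~1.7 kb giving ≈ 20k SNPs, and 8 diploids per population.

What the generator does **not** emulate: recombination and linkage
(sites are exchangeable given the frequency hierarchy, so LD decay on
simulated data is flat), mutation-rate heterogeneity, selection,
realistic site-frequency spectra from a coalescent, sequencing error in
genotypes, and indels/multiallelics. Passing recovery tests therefore
demonstrates correctness of the estimators and detection machinery
under the assumed frequency model, not robustness to everything real
data can do. (msprime is a suitable independent oracle for
coalescent-based cross-checks and is deliberately not a dependency of
the package itself.)

## Experiment sizes

The built-in experiments use desk-scale problem sizes chosen to leave
comfortable Monte-Carlo margins: ~20k SNPs for F_ST/heterozygosity
targets, five replicate simulations for tract recovery (recall ≥ 0.9,
false-positive RoH span ≤ 5%), a 250 Mb genome for the f_dM recovery so
a 2 Mb tract is ~1% of the genome (matching the top-1% window budget),
100 replicate trios for the D null, and 200 × 1,000 randomizations for
the permutation calibration. The real study operates at ~1 Gb × 55
samples and 34M SNPs; its genome-scale values (RoH counts, consensus
tallies, Z = −45.4, specific f_b values) depend on that data and are
not targets here.

## Known limitations

- `ld_decay` enumerates SNP pairs in Python; at genome scale it should
  be driven per-chromosome or subsampled (the study itself subsampled
  three individuals per population).
- The f-branch implementation assumes a bifurcating rooted tree with
  the outgroup attached at the root; polytomies are skipped rather than
  resolved.
- The permutation test treats regions as independently placeable; if
  input regions nearly tile the genome the null becomes degenerate
  (sd → 0), reported as Z = NA with a tail-only p.
- `filter_sites` counts each removed site under the first rule that
  rejects it (QUAL, then missingness, then MAF); totals are therefore
  additive but rule counts are order-dependent.
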