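# Methods

## The problem

Genome-wide association studies identify *lead SNPs* — representative
variants of genomic regions associated with human traits — while
coalescent-based dating assigns each variant an age: the estimated time to
the most recent common ancestor of the haplotypes carrying it, in years
before present. Joining the two asks *when in human evolution the genetic
variants underlying present-day traits emerged*. `paleogwas` implements
that analysis end to end: a lead-SNP selection funnel, time-binned
enrichment of variant emergence against a frequency-matched null,
phenotype and gene dating with permutation nulls, and regional brain
expression mapping of recently modified genes. Because the real inputs are
multi-gigabyte downloads, the package ships a synthetic generator that
reproduces the statistical structure the analysis relies on, so every
stage is testable offline.

## Data model

A *dated-variant atlas* row holds a variant id, position, an age in years
before present (the combined median TMRCA estimate of a dating database),
a dating-confidence quality score in [0, 1], and the minor allele
frequency (MAF) in (0, 0.5]. Associations carry a 4-level phenotype
hierarchy (domain → chapter → subchapter → trait) and the GWAS sample
size. Internally all coordinates are 1-based inclusive; BED input is
converted at the boundary. Ages stay in years; a `GenerationScale`
(default 25 years/generation) converts for display only.

## Selection funnel

Five filters reduce a raw association export to the analysis set, in
fixed order (the first four commute; the minimum-support count depends on
the survivors, so it runs last):

1. atlas matching, annotation, and collapse of duplicate (variant, trait)
   records to the largest-sample-size GWAS;
2. dating quality **strictly above 0.7** and GWAS sample size **strictly
   over 50,000** — both bounds read literally as "above"/"over";
3. exclusion of the MHC (default chr6:25–34 Mb; the region's extreme LD
   makes lead-SNP independence meaningless there; bounds are configurable
   because they are build-dependent);
4. LD pruning, either greedy keep-first across phenotypes at r² < 0.1
   (lexicographic id order as the deterministic tie-break — the upstream
   convention is unspecified) or a stricter within-phenotype rule that
   drops both ends of any listed pair;
5. phenotypes with fewer than 25 distinct variants (inclusive bound:
   "at least 25") are removed at the chosen hierarchy level.

Every stage logs its input/output counts and returns a `FilterReport`, so
the funnel is fully auditable.

## Matched permutation nulls

All hypothesis tests share one scheme. The observed statistic of a
variant (or gene) set is compared against `n_perm` (default 10,000)
random sets drawn **without replacement within a draw** from a candidate
pool, matched in size and — for variant sets — in per-stratum MAF
composition. Matching matters because allele frequency and allele age are
strongly coupled (drift needs time to raise a frequency): a
frequency-blind null would mistake a set's MAF profile for a temporal
signal. Two stratification presets are used: a fine 9-stratum scheme
(log-spaced below 10% MAF) for the timeline test, and a coarse 5-stratum
scheme (deciles of the folded frequency axis, 0.1 wide) for phenotype
dating. Gene-level nulls are size-matched only; there is no MAF at gene
level.

From the null sample the package reports the mean, the sample SD (ddof 1),
`z = (obs − mean)/sd`, a two-sided normal-tail p from z, and the
one-tailed empirical p `(1 + #{null at least as extreme})/(n_perm + 1)`
with the tail chosen by the side of the observation. A statistic that is
exactly constant across draws (a target exhausting its pool) is treated
as sd = 0 with z = 0 and p = 1 when the observation equals the null mean.

**Which p to trust.** The empirical p carries the permutation test's
exact-size guarantee; doubling it gives a calibrated two-sided decision
rule. The normal-tail p is an approximation whose quality depends on the
statistic: per-bin counts and medians of near-Gaussian expression values
are close to normal and the z-based rule holds its nominal size, but the
median age of a set drawn from a strongly bimodal age distribution has a
non-Gaussian null, for which the z-based rule is conservative (measured
rejection ≈1% at |z| > 1.96 under the generator's defaults). The package
reports both; z exists mainly because the analyses this package supports
operate in a regime where observed z-scores are enormous and p-values far
below any feasible permutation resolution must be quoted.

## Timeline enrichment and peaks

The analysis window is the last 2 Myr (ages at the boundary are excluded
— "younger than" is strict), split into 100 half-open bins of 20,000
years. Both the observed set and the pool are restricted to the window,
so every null draw conserves the in-window total. Significance uses
Bonferroni correction across bins (0.05/100 = 5 × 10⁻⁴).

Peaks of the binned density are scored by **topographic prominence**: a
peak's height minus the higher of the two valley floors separating it
from taller terrain. Peaks are interior strict local maxima after plateau
merging (a plateau counts once, at its leftmost bin — a determinism
choice); the k = 2 most prominent are returned, ties broken toward the
lower bin. Normalising counts to a density rescales heights and
prominences together, so locations and ordering are scale-invariant. The
implementation is independent of `scipy.signal`, which serves as the
oracle in tests.

## Phenotype and gene dating

A phenotype's age is the median age of its distinct associated variants
(duplicates from merged GWAS count once); negative z means younger than
expected. Hierarchy sweeps Bonferroni-correct by the number of phenotypes
actually tested at the level — 24 domains give 0.05/24 ≈ 2.1 × 10⁻³, 31
chapters 1.6 × 10⁻³, 361 traits 1.4 × 10⁻⁴ at the catalogue sizes.
Pairwise phenotype contrasts use Welch's unequal-variance t-test.

A gene's age is the median age of the dated SNPs inside its transcription
region, optionally widened by a symmetric window (1 kb in sensitivity
analyses). SNPs hitting ≥2 genes are ambiguous and SNPs hitting none are
uninformative; both are excluded. Extreme-age fractions use **ceiling
rounding** — the only rule consistent with selecting 1833 of 18,328 dated
genes and 1635 of 16,344 expressed genes at 10% — with age ties broken by
gene id. Gene-level contrasts: a size-matched null test for gene-set
ages, a Welch contrast between the top decile of loss-of-function-intolerant
genes and the rest, an upper-tail hypergeometric test for enrichment of a
variant set within a gene set (a permutation scheme was considered; the
hypergeometric is exact and assumption-light for a fixed urn), and a
diagnostic Pearson correlation between gene length and age.

## Expression mapping

Per region, the observed statistic is the median expression of the gene
set; the null draws same-size gene sets from **all genes present in the
matrix** (the expressed-gene universe, not the dated-gene universe), one
draw reused across regions. Bonferroni corrects across regions; the
region count is a config input because it is parcellation-dependent.
Region-set tests fix a named set of regions and take the median over the
(regions × genes) submatrix. The prenatal/postnatal contrast takes
per-gene medians within each stage and applies a paired two-sided
Wilcoxon signed-rank across the genes of the set (the source analyses do
not name their test; a paired rank test is the conservative default for
per-gene paired summaries).

## The synthetic generator

`simulate_atlas` draws ages from a two-component log-normal mixture,
truncated to the dating atlas's plausible envelope (87.5 y – 5.14 Myr).
Defaults: modes at 1.1 Myr ("old peak") and 55 kyr ("young peak"),
weights 0.35/0.65, log-sd 0.08 (old) and 0.90 (young). The young-dominant
weights follow the emulated atlas's interquartile envelope (young side
~40 kyr, old side ~660 kyr), and they keep the population median inside
the young mode — an equal-weight mixture would park the median on the
empty shelf between modes, a degenerate regime for any median statistic.
The old mode's log-sd is set so that, at the default n = 2 × 10⁵, the
histogram mode is localisable to a single 20-kyr bin (a 20-kyr bin at
1.1 Myr is 1.8% in relative age; a broader component leaves the argmax
bin undetermined by sampling noise). This deliberately narrows the old
peak relative to the broad span real data show; the young peak, where
bins are log-wide, keeps a realistic spread.

MAF is a scaled Beta (concentration 4) whose mean rises with standardised
log-age through a logistic link (intercept −1.0); the slope default 0.45
was calibrated once, numerically, so the default spec yields a sample
Pearson r(MAF, age) ≈ 0.38 at n = 2 × 10⁵ — the coupling strength the
matched nulls exist to neutralise. MAF is generated through a
common-uniform Beta quantile, making the realised correlation monotone in
the slope at a fixed seed. Quality is an independent Beta(5, 1.5).

Null associations are uniform draws without replacement from the atlas,
so every matched permutation test is calibrated *by construction*.
Planted effects (`age_shift`) keep the MAF-stratum counts of a uniform
draw but re-weight variants within each stratum by a log-normal kernel
(log-sd 0.35) centred on `shift × stratum median age` — a signal the
matched nulls cannot explain away, which is exactly what the tests should
recover. Gene models are placed disjointly with random gaps, with a
configurable fraction slid into their neighbour to exercise multi-gene
exclusion. Expression matrices are Gaussian baseline noise (mean 5,
sd 1) plus an additive effect on enriched (region × gene) cells, with
optional prenatal/postnatal stage labels and a prenatal boost.

What the generator does **not** emulate: linkage disequilibrium structure
(LD pairs are sampled independently of position), selection, demography,
genotyping error, and the spatial covariance of real expression data.
Passing tests therefore demonstrate the statistical machinery — matching,
calibration, recovery, determinism — not robustness to those real-data
features.

## Problem sizes and numerics

Default test and acceptance runs use: 20k-variant atlases for
calibration (100 replicate seeds, 1000 permutations), 200k-variant
atlases for planted-trait recovery (20 seeds, 10,000 permutations) and
peak recovery, 2000-gene expression universes with 10 regions. These
sizes put binomial confidence intervals around every calibration claim
while keeping the whole suite in a few minutes on one core. Null-moment
computations guard the exactly-constant case so degenerate pools give
sd = 0 rather than float-noise near-zeros; medians of even-sized sets
average the two central values; all randomness flows from a single seed
through spawned generators, so every result table is reproducible
byte-for-byte.

## Known limitations

- Gene dating inherits the location-based assumption that SNPs inside a
  transcription region reflect the gene's history; regulatory variants
  outside it are ignored.
- The within-window restriction discards the ~0.5%-style tail of
  associations older than the window; their count is logged, not
  analysed.
- Covariate adjustment for gene length is not implemented; only the
  diagnostic length–age correlation is reported.
- Multi-clock reconciliation of age estimates is upstream of this
  package; the atlas carries a single combined age per variant.
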