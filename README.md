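# paleogwas

**When did the genetic variants underlying human traits emerge?**

Coalescent dating assigns each variant in the human genome an age — the
estimated time to the most recent common ancestor (TMRCA) of the
haplotypes carrying it. Joining such a dated-variant atlas with GWAS lead
SNPs places every trait on an evolutionary timeline and asks whether the
variants behind a phenotype are younger or older than chance predicts.
`paleogwas` implements that analysis for researchers in population
genetics and neurogenomics:

- a **lead-SNP selection funnel** (atlas matching, dating-quality > 0.7,
  GWAS sample size > 50,000, MHC exclusion, LD pruning at r² < 0.1,
  ≥ 25 SNPs per phenotype), fully audited;
- **time-binned emergence enrichment**: counts per 20,000-year bin over
  the last 2 Myr tested against 10,000 permuted variant sets matched to
  the observed set's minor-allele-frequency (MAF) profile — matching is
  essential because MAF and allele age are strongly coupled (r ≈ 0.38);
- **peak detection** by topographic prominence on the binned density;
- **phenotype dating**: the median variant age of each phenotype in a
  domain/chapter/subchapter/trait hierarchy against size- and MAF-matched
  nulls, with per-level Bonferroni correction;
- **gene dating**: per-gene median SNP age over the transcription region,
  extreme-age decile selection, loss-of-function-intolerance contrasts,
  and hypergeometric variant-in-gene-set enrichment;
- **regional expression mapping**: null-random-gene tests of whether a
  gene set is over-expressed in particular brain regions, region sets, or
  developmental stages;
- a **synthetic-data generator** reproducing the structure the analysis
  relies on (bimodal age distribution with modes near 1.1 Myr and 55 kyr,
  positive MAF–age coupling, planted phenotype age shifts), so the whole
  pipeline runs and is tested without any external download.

For a variant set with observed statistic *T* (a per-bin count or a
median age), each test draws `n_perm` random same-size sets from the
matched pool and reports

    z = (T − mean(T_null)) / sd(T_null)

with a two-sided normal-tail p, alongside the exact empirical permutation
p `(1 + #{null ≥ T}) / (n_perm + 1)`. See `docs/methods.md` for the full
model description and the calibration properties of each p-value.

## Worked example

```python
from paleogwas import (
    AtlasSpec, PhenotypeSpec, TraitSpec, TimeBinGrid,
    simulate_atlas, simulate_associations, match_to_atlas,
    bin_counts, detect_peaks, phenotype_age_test,
)

atlas = simulate_atlas(AtlasSpec(n_variants=200_000, seed=1))
grid = TimeBinGrid()  # 100 bins x 20,000 y over the last 2 Myr
counts = bin_counts(atlas.frame["age_years"].to_numpy(), grid)
density = counts / counts.sum() / grid.width
for peak in detect_peaks(density, k=2, grid=grid):
    print(f"peak at {peak.age:>12,.0f} y BP  (prominence {peak.prominence:.3g})")

spec = PhenotypeSpec((
    TraitSpec("fluid_intelligence", n_snps=200, age_shift=0.1),  # planted young
    TraitSpec("standing_height",    n_snps=200),                 # null
))
assocs = simulate_associations(atlas, spec, seed=2)
annotated, report = match_to_atlas(assocs, atlas)
for trait in ("fluid_intelligence", "standing_height"):
    res = phenotype_age_test(
        annotated[annotated["trait"] == trait], atlas,
        n_perm=10_000, seed=3, phenotype=trait,
    )
    print(f"{trait:20s} median {res.median_age:>10,.0f} y  "
          f"null {res.null_mean:>10,.0f} y  z = {res.z:+.2f}  p = {res.p:.2e}")
```

prints

```
peak at       40,000 y BP  (prominence 2.75e-06)
peak at    1,100,000 y BP  (prominence 1.58e-06)
fluid_intelligence   median     33,320 y  null    241,161 y  z = -5.50  p = 3.81e-08
standing_height      median    229,912 y  null    283,589 y  z = -0.95  p = 3.40e-01
```

The atlas's two emergence peaks are recovered at the grid's resolution
(bin left edges 40 kyr and 1.10 Myr for planted modes at 55 kyr and
1.1 Myr). The planted-young trait's median variant age (33 kyr) sits far
below its size- and MAF-matched null expectation (241 kyr), giving a
strongly negative z — "younger than chance" — while the null trait is
indistinguishable from its matched expectation. The two traits have
different null means because the null is matched to each trait's own MAF
profile and size.

The same stages are available from the shell:

```sh
paleogwas simulate --out-dir fixtures --seed 1
paleogwas filter   --atlas fixtures/atlas.tsv --associations fixtures/associations.tsv \
                   --ld fixtures/ld.tsv --out filtered.tsv --report audit.tsv
paleogwas timeline --atlas fixtures/atlas.tsv --associations fixtures/associations.tsv \
                   --out timeline.tsv --peaks-out peaks.tsv
paleogwas phenoage --atlas fixtures/atlas.tsv --associations fixtures/associations.tsv \
                   --level trait --out phenoage.tsv
```

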