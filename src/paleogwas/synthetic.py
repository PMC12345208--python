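"""Synthetic fixtures with the statistical structure the analysis assumes.

The generator is the package's stand-in for the real inputs (a dated-variant
atlas, GWAS lead-SNP tables, gene models, LD pairs, brain-expression
matrices), built so that every downstream stage is exercisable and its null
behaviour holds *by construction*:

* **Ages** come from a two-component log-normal mixture with modes near
  1.1 Myr and 55 kyr before present — the two emergence peaks the timeline
  analysis is designed to detect — truncated to the dating atlas's
  plausible envelope (87.5 y to 5.14 Myr).
* **MAF** is a scaled Beta whose mean increases with standardised log-age
  through a logistic link; the default coupling is calibrated so the
  sample Pearson correlation between MAF and age is ~0.38 at n = 200,000.
  This reproduces the frequency-age coupling the matched nulls exist to
  neutralise, without claiming population-genetic realism.
* **Associations** for a null trait are a uniform draw from the atlas, so
  every matched permutation test is calibrated by construction.  Planted
  effects (``age_shift``) re-weight sampling toward ages near
  ``shift x stratum median`` *within* each MAF stratum, leaving the trait's
  MAF profile untouched — exactly the signal the tests should recover and
  the only kind matching cannot explain away.

Determinism: one integer seed; per-stage generators are spawned from it,
so identical specs produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpecError
from .io import ExpressionMatrix, GeneModel, VariantAtlas

__all__ = [
    "AtlasSpec",
    "TraitSpec",
    "PhenotypeSpec",
    "simulate_atlas",
    "simulate_associations",
    "simulate_gene_models",
    "simulate_ld_pairs",
    "simulate_expression",
]

# default mixture: (weight, log-age mean, log-age sd); the mean of each
# component is placed so the component *mode* exp(mu - sd^2) sits at the
# target age.  Weights favour the young mode — the dating atlas this
# emulates is young-dominant (its printed interquartile envelope reaches
# only ~660 kyr on the old side) — which also keeps the population median
# inside the young mode rather than on the empty shelf between modes.
_OLD_MODE, _OLD_SD = 1.1e6, 0.08
_YOUNG_MODE, _YOUNG_SD = 55e3, 0.90
DEFAULT_MIXTURE = (
    (0.35, math.log(_OLD_MODE) + _OLD_SD**2, _OLD_SD),
    (0.65, math.log(_YOUNG_MODE) + _YOUNG_SD**2, _YOUNG_SD),
)

#: logistic slope on standardised log-age; calibrated once so the default
#: spec yields sample r(maf, age) ~ 0.38 at n = 200,000
DEFAULT_COUPLING = 0.45


@dataclass(frozen=True)
class AtlasSpec:
    """Recipe for a synthetic dated-variant atlas."""

    n_variants: int = 200_000
    mixture: tuple = DEFAULT_MIXTURE
    maf_age_coupling: float = DEFAULT_COUPLING
    maf_intercept: float = -1.0
    maf_concentration: float = 4.0
    quality_dist: tuple[float, float] = (5.0, 1.5)  # Beta(a, b)
    age_min: float = 87.5
    age_max: float = 5_140_625.0
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 1:
            raise SpecError("n_variants must be >= 1")
        weights = [w for w, _, _ in self.mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise SpecError(f"mixture weights must sum to 1, got {sum(weights)}")
        if any(sd <= 0 for _, _, sd in self.mixture):
            raise SpecError("mixture components need positive log-age sd")
        if not (0 < self.age_min < self.age_max):
            raise SpecError("need 0 < age_min < age_max")
        if self.maf_concentration <= 0:
            raise SpecError("maf_concentration must be positive")


def simulate_atlas(spec: AtlasSpec = AtlasSpec()) -> VariantAtlas:
    """Draw a synthetic atlas from an :class:`AtlasSpec`.

    MAF is generated through a common-uniform Beta quantile, which makes
    the sample MAF-age correlation monotone in ``maf_age_coupling`` at a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_variants
    weights = np.array([w for w, _, _ in spec.mixture])
    mus = np.array([m for _, m, _ in spec.mixture])
    sds = np.array([s for _, _, s in spec.mixture])
    comp = rng.choice(len(weights), size=n, p=weights)
    log_age = rng.normal(mus[comp], sds[comp])
    # truncate by re-drawing out-of-envelope ages within their component
    lo, hi = math.log(spec.age_min), math.log(spec.age_max)
    bad = (log_age < lo) | (log_age > hi)
    while bad.any():
        log_age[bad] = rng.normal(mus[comp[bad]], sds[comp[bad]])
        bad = (log_age < lo) | (log_age > hi)
    age = np.exp(log_age)

    s = (log_age - log_age.mean()) / log_age.std()
    mean_maf = stats.logistic.cdf(spec.maf_intercept + spec.maf_age_coupling * s)
    kappa = spec.maf_concentration
    u = rng.random(n)
    maf = 0.5 * stats.beta.ppf(u, mean_maf * kappa, (1.0 - mean_maf) * kappa)
    maf = np.clip(maf, 1e-9, 0.5)

    a, b = spec.quality_dist
    quality = rng.beta(a, b, size=n)

    frame = pd.DataFrame(
        {
            "variant_id": [f"rs{i:08d}" for i in range(n)],
            "chrom": rng.choice([f"chr{c}" for c in range(1, 23)], size=n),
            "pos": rng.integers(1, 250_000_000, size=n),
            "age_years": age,
            "quality": quality,
            "maf": maf,
        }
    )
    return VariantAtlas(frame, provenance=f"synthetic atlas (seed={spec.seed})")


@dataclass(frozen=True)
class TraitSpec:
    """One synthetic trait: hierarchy path, size, and optional age shift."""

    trait: str
    n_snps: int
    subchapter: str = ""
    chapter: str = ""
    domain: str = ""
    age_shift: float = 1.0  # multiplier on target ages; 1 = null
    sample_size: int = 100_000
    gwas_id: str = ""

    def __post_init__(self):
        if self.n_snps < 1:
            raise SpecError(f"trait {self.trait}: n_snps must be >= 1")
        if self.age_shift <= 0:
            raise SpecError(f"trait {self.trait}: age_shift must be > 0")


@dataclass(frozen=True)
class PhenotypeSpec:
    """A flat list of traits; hierarchy labels default to the trait name."""

    traits: tuple[TraitSpec, ...] = ()

    def resolved(self) -> list[TraitSpec]:
        out = []
        for t in self.traits:
            out.append(
                TraitSpec(
                    trait=t.trait,
                    n_snps=t.n_snps,
                    subchapter=t.subchapter or t.trait,
                    chapter=t.chapter or t.trait,
                    domain=t.domain or t.trait,
                    age_shift=t.age_shift,
                    sample_size=t.sample_size,
                    gwas_id=t.gwas_id or f"GWAS_{t.trait}",
                )
            )
        return out


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Efraimidis-Spirakis: top-k of u^(1/w) keys."""
    u = rng.random(len(weights))
    keys = np.power(u, 1.0 / weights)
    return np.argpartition(-keys, k - 1)[:k]


def simulate_associations(
    atlas: VariantAtlas,
    spec: PhenotypeSpec,
    seed: int = 0,
    shift_concentration: float = 0.35,
) -> pd.DataFrame:
    """Draw association tables for every trait in ``spec``.

    Null traits (``age_shift == 1``) are uniform draws without replacement
    from the atlas — their MAF composition matches the atlas by
    construction, so matched permutation nulls hold exactly.  Shifted
    traits keep the stratum counts of a uniform draw but re-weight variants
    within each MAF stratum by a log-normal kernel centred on
    ``age_shift x stratum median age`` with log-sd ``shift_concentration``.
    """
    from .temporal import PHENOTYPE_MAF_SCHEME  # local import to avoid a cycle

    frame = atlas.frame
    n_atlas = len(frame)
    ages = frame["age_years"].to_numpy(dtype=float)
    strata = PHENOTYPE_MAF_SCHEME.assign(frame["maf"].to_numpy())
    rng = np.random.default_rng(seed)
    rows = []
    for t in spec.resolved():
        if t.n_snps > n_atlas:
            raise SpecError(
                f"trait {t.trait}: n_snps {t.n_snps} exceeds atlas size {n_atlas}"
            )
        base = rng.choice(n_atlas, size=t.n_snps, replace=False, shuffle=False)
        if t.age_shift == 1.0:
            chosen = base
        else:
            chosen = []
            for s in np.unique(strata[base]):
                count = int((strata[base] == s).sum())
                pool_idx = np.flatnonzero(strata == s)
                med = np.median(ages[pool_idx])
                target_log = math.log(t.age_shift * med)
                d = (np.log(ages[pool_idx]) - target_log) / shift_concentration
                w = np.exp(-0.5 * d * d) + 1e-300
                pick = _weighted_sample_without_replacement(rng, w, count)
                chosen.append(pool_idx[pick])
            chosen = np.concatenate(chosen)
        for vid in frame["variant_id"].to_numpy()[chosen]:
            rows.append(
                {
                    "variant_id": vid,
                    "trait": t.trait,
                    "subchapter": t.subchapter,
                    "chapter": t.chapter,
                    "domain": t.domain,
                    "gwas_id": t.gwas_id,
                    "sample_size": t.sample_size,
                }
            )
    from .io import ASSOCIATION_COLUMNS

    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)


def simulate_gene_models(
    n_genes: int,
    chrom_length: int = 100_000_000,
    mean_len: int = 20_000,
    seed: int = 0,
    overlap_fraction: float = 0.0,
    chrom: str = "chr1",
) -> list[GeneModel]:
    """Place genes on one chromosome; a fraction overlap their neighbour.

    Disjoint placement distributes the free space as random gaps between
    genes; for ``overlap_fraction > 0`` the chosen genes are slid left into
    the previous gene's interval (exercising multi-gene SNP exclusion).
    """
    if n_genes < 0:
        raise SpecError("n_genes must be >= 0")
    if not (0.0 <= overlap_fraction <= 1.0):
        raise SpecError("overlap_fraction must lie in [0, 1]")
    if n_genes == 0:
        return []
    rng = np.random.default_rng(seed)
    lengths = np.maximum(rng.poisson(mean_len, size=n_genes), 200)
    total = int(lengths.sum())
    if total > chrom_length:
        raise SpecError(
            f"{n_genes} genes of mean length {mean_len} do not fit in {chrom_length}"
        )
    free = chrom_length - total
    gaps = rng.multinomial(free, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    starts = np.empty(n_genes, dtype=int)
    cursor = 1
    for i in range(n_genes):
        cursor += int(gaps[i])
        starts[i] = cursor
        cursor += int(lengths[i])
    if overlap_fraction > 0 and n_genes > 1:
        n_overlap = int(round(overlap_fraction * n_genes))
        which = rng.choice(np.arange(1, n_genes), size=min(n_overlap, n_genes - 1),
                           replace=False, shuffle=False)
        for i in which:
            prev_end = starts[i - 1] + int(lengths[i - 1]) - 1
            starts[i] = max(1, prev_end - int(lengths[i]) // 2)
    strands = rng.choice(["+", "-"], size=n_genes)
    return [
        GeneModel(
            gene_id=f"G{i:05d}",
            chrom=chrom,
            tx_start=int(starts[i]),
            tx_end=int(starts[i] + lengths[i] - 1),
            strand=str(strands[i]),
        )
        for i in range(n_genes)
    ]


def simulate_ld_pairs(
    variant_ids: Sequence[str],
    n_pairs: int,
    seed: int = 0,
    r2_dist: tuple[float, float] = (0.5, 0.5),
):
    """Random LD pairs among the given ids with Beta-distributed r2."""
    from .io import LdTable

    rng = np.random.default_rng(seed)
    ids = np.asarray(variant_ids)
    if len(ids) < 2 and n_pairs > 0:
        raise SpecError("need at least 2 variant ids to form LD pairs")
    table = LdTable()
    a, b = r2_dist
    for _ in range(n_pairs):
        i, j = rng.choice(len(ids), size=2, replace=False, shuffle=False)
        table.add(str(ids[i]), str(ids[j]), float(rng.beta(a, b)))
    return table


def simulate_expression(
    n_regions: int,
    gene_ids: Sequence[str],
    enriched_regions: Sequence[str] = (),
    enriched_gene_set: Sequence[str] = (),
    effect: float = 0.0,
    seed: int = 0,
    baseline: float = 5.0,
    noise_sd: float = 1.0,
    stage_labels: Sequence[str] | None = None,
    prenatal_boost: float = 0.0,
) -> ExpressionMatrix:
    """Baseline Gaussian noise plus an additive effect on enriched cells.

    Region ids are ``region000 ...``; ``enriched_regions`` and
    ``enriched_gene_set`` must be subsets of the generated/declared ids.
    With ``stage_labels`` (one of {prenatal, postnatal} per row) a
    ``prenatal_boost`` is added to the enriched gene set's prenatal rows.
    """
    rng = np.random.default_rng(seed)
    regions = [f"region{i:03d}" for i in range(n_regions)]
    genes = [str(g) for g in gene_ids]
    unknown_r = set(enriched_regions) - set(regions)
    unknown_g = set(enriched_gene_set) - set(genes)
    if unknown_r:
        raise SpecError(f"unknown enriched regions: {sorted(unknown_r)}")
    if unknown_g:
        raise SpecError(f"unknown enriched genes: {sorted(unknown_g)[:5]}")
    values = baseline + rng.normal(0.0, noise_sd, size=(n_regions, len(genes)))
    frame = pd.DataFrame(values, index=regions, columns=genes)
    if effect != 0.0 and enriched_regions and enriched_gene_set:
        frame.loc[list(enriched_regions), list(enriched_gene_set)] += effect
    stages = None
    if stage_labels is not None:
        if len(stage_labels) != n_regions:
            raise SpecError("stage_labels must have one entry per row")
        stages = pd.Series(list(stage_labels), index=regions, name="stage")
        if prenatal_boost and enriched_gene_set:
            pre = stages[stages == "prenatal"].index
            frame.loc[pre, list(enriched_gene_set)] += prenatal_boost
    return ExpressionMatrix(frame, stages=stages)
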