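"""Lead-SNP selection funnel.

The funnel turns a raw association export into the analysis set:

1. **match** — keep associations whose variant exists in the dated atlas,
   annotate them with age / quality / MAF / position, and collapse
   duplicate (variant, trait) records left by merged GWAS;
2. **thresholds** — dating quality strictly above 0.7 and GWAS sample size
   strictly over 50,000;
3. **region exclusion** — drop variants inside an excluded region
   (default: the MHC, chr6:25-34 Mb, configurable — the extreme LD there
   makes lead-SNP independence meaningless);
4. **LD pruning** — either greedy keep-first pruning across phenotypes at
   r2 < 0.1, or the stricter within-phenotype rule that drops *both* ends
   of any listed LD pair;
5. **minimum support** — phenotypes with fewer than 25 distinct variants
   at the chosen hierarchy level are removed entirely.

Stages 1-4 commute; the minimum-support count depends on what survived, so
it runs last.  Every stage logs its input/output counts and returns a
:class:`FilterReport` for the audit trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ContractError, IntegrityError, ParameterError
from .io import HIERARCHY_LEVELS, LdTable, VariantAtlas

logger = logging.getLogger("paleogwas")

__all__ = [
    "FilterReport",
    "GenomicRegion",
    "MHC_REGION",
    "match_to_atlas",
    "apply_threshold_filters",
    "exclude_region",
    "ld_prune",
    "min_snps_per_phenotype",
    "run_filter_funnel",
    "reports_to_frame",
]


@dataclass
class FilterReport:
    """Audit record of one funnel stage."""

    stage: str
    n_in: int
    n_out: int
    removed_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.n_out > self.n_in:
            raise IntegrityError(
                f"{self.stage}: n_out {self.n_out} exceeds n_in {self.n_in}"
            )


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "MHC"

    def __post_init__(self):
        if self.start > self.end:
            raise IntegrityError(f"region {self.name}: start > end")

    def contains(self, chrom, pos) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


#: default MHC bounds — round build-agnostic numbers, override per build
MHC_REGION = GenomicRegion("chr6", 25_000_000, 34_000_000, "MHC")


def _report(stage: str, before: pd.DataFrame, after: pd.DataFrame) -> FilterReport:
    removed = sorted(set(before["variant_id"]) - set(after["variant_id"]))
    rep = FilterReport(stage=stage, n_in=len(before), n_out=len(after),
                       removed_ids=tuple(removed))
    logger.info("%s: %d -> %d associations", stage, rep.n_in, rep.n_out)
    return rep


def match_to_atlas(
    assocs: pd.DataFrame, atlas: VariantAtlas
) -> tuple[pd.DataFrame, FilterReport]:
    """Annotate associations with atlas fields; drop unmatched variants.

    Duplicate (variant, trait) pairs — e.g. the same lead SNP reported by
    two merged GWAS of one trait — collapse to the record with the largest
    sample size (ties: smallest gwas_id).
    """
    annotated = assocs.merge(
        atlas.frame[["variant_id", "chrom", "pos", "age_years", "quality", "maf"]],
        on="variant_id",
        how="inner",
    )
    annotated = (
        annotated.sort_values(
            ["variant_id", "trait", "sample_size", "gwas_id"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        .drop_duplicates(["variant_id", "trait"])
        .reset_index(drop=True)
    )
    return annotated, _report("match_to_atlas", assocs, annotated)


def _require_annotation(assocs: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in assocs.columns]
    if missing:
        raise ContractError(
            f"associations lack annotation columns {missing}; run match_to_atlas first"
        )


def apply_threshold_filters(
    assocs: pd.DataFrame, min_quality: float = 0.7, min_sample: int = 50_000
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep quality strictly above and sample size strictly over threshold."""
    _require_annotation(assocs, ("quality",))
    kept = assocs[
        (assocs["quality"] > min_quality) & (assocs["sample_size"] > min_sample)
    ].reset_index(drop=True)
    return kept, _report("threshold_filters", assocs, kept)


def exclude_region(
    assocs: pd.DataFrame, region: GenomicRegion = MHC_REGION
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop associations whose variant lies inside the region (inclusive)."""
    _require_annotation(assocs, ("chrom", "pos"))
    inside = (
        (assocs["chrom"] == region.chrom)
        & (assocs["pos"] >= region.start)
        & (assocs["pos"] <= region.end)
    )
    kept = assocs[~inside].reset_index(drop=True)
    return kept, _report(f"exclude_{region.name}", assocs, kept)


def ld_prune(
    assocs: pd.DataFrame,
    ld: LdTable,
    r2_max: float = 0.1,
    scope: str = "across_phenotypes",
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove variants in linkage disequilibrium.

    ``across_phenotypes``: greedy keep-first over the pooled variant set in
    lexicographic id order — a variant is dropped iff it has r2 >= r2_max
    with an already-kept one.  The surviving set contains no pair at or
    above the threshold.

    ``within_phenotype``: inside each trait, drop *every* variant with any
    listed LD partner (r2 > 0) in the same trait, regardless of magnitude.
    """
    if not (0.0 < r2_max <= 1.0):
        raise ParameterError(f"r2_max must lie in (0, 1], got {r2_max}")
    if scope == "across_phenotypes":
        kept_ids: set[str] = set()
        for vid in sorted(assocs["variant_id"].unique()):
            partners = ld.partners(vid)
            if any(u in kept_ids and ld.r2(vid, u) >= r2_max for u in partners):
                continue
            kept_ids.add(vid)
        kept = assocs[assocs["variant_id"].isin(kept_ids)].reset_index(drop=True)
        stage = f"ld_prune_across(r2<{r2_max:g})"
    elif scope == "within_phenotype":
        drop_pairs = set()
        for trait, sub in assocs.groupby("trait"):
            ids = set(sub["variant_id"])
            for vid in ids:
                if any(u in ids and ld.r2(vid, u) > 0 for u in ld.partners(vid)):
                    drop_pairs.add((vid, trait))
        mask = [
            (vid, trait) not in drop_pairs
            for vid, trait in zip(assocs["variant_id"], assocs["trait"])
        ]
        kept = assocs[mask].reset_index(drop=True)
        stage = "ld_prune_within"
    else:
        raise ParameterError(f"unknown scope {scope!r}")
    return kept, _report(stage, assocs, kept)


def min_snps_per_phenotype(
    assocs: pd.DataFrame, level: str = "trait", k: int = 25
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove phenotypes with fewer than ``k`` distinct variants (>= k kept)."""
    if level not in HIERARCHY_LEVELS:
        raise ContractError(f"level must be one of {HIERARCHY_LEVELS}")
    if len(assocs) == 0:
        return assocs, _report(f"min_{k}_snps_per_{level}", assocs, assocs)
    counts = assocs.groupby(level)["variant_id"].nunique()
    keep_levels = counts[counts >= k].index
    kept = assocs[assocs[level].isin(keep_levels)].reset_index(drop=True)
    return kept, _report(f"min_{k}_snps_per_{level}", assocs, kept)


def run_filter_funnel(
    assocs: pd.DataFrame,
    atlas: VariantAtlas,
    ld: LdTable | None = None,
    min_quality: float = 0.7,
    min_sample: int = 50_000,
    region: GenomicRegion = MHC_REGION,
    r2_max: float = 0.1,
    ld_scope: str = "across_phenotypes",
    min_snps: int = 25,
    level: str = "trait",
) -> tuple[pd.DataFrame, list[FilterReport]]:
    """The full funnel in its fixed order; returns the set and audit trail."""
    reports = []
    out, rep = match_to_atlas(assocs, atlas)
    reports.append(rep)
    out, rep = apply_threshold_filters(out, min_quality, min_sample)
    reports.append(rep)
    out, rep = exclude_region(out, region)
    reports.append(rep)
    if ld is not None:
        out, rep = ld_prune(out, ld, r2_max, ld_scope)
        reports.append(rep)
    out, rep = min_snps_per_phenotype(out, level, min_snps)
    reports.append(rep)
    return out, reports


def reports_to_frame(reports: list[FilterReport]) -> pd.DataFrame:
    """Audit trail as a table (removed ids comma-joined)."""
    return pd.DataFrame(
        {
            "stage": [r.stage for r in reports],
            "n_in": [r.n_in for r in reports],
            "n_out": [r.n_out for r in reports],
            "n_removed": [r.n_in - r.n_out for r in reports],
            "removed_ids": [",".join(r.removed_ids) for r in reports],
        }
    )
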