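"""Location-based gene dating and gene-level contrasts.

A gene's evolutionary age is proxied by the median age of the dated SNPs
falling inside its transcription region (optionally widened by a
symmetric window).  SNPs overlapping several genes are ambiguous and SNPs
hitting none are uninformative; both are excluded before aggregation.

Downstream contrasts operate on the per-gene ages: extreme-age fractions
(the "youngest 10%" style selections, with ceiling rounding — the only
rule consistent with printed set sizes 1833/18,328 and 1635/16,344),
size-matched null tests for gene sets, a Welch contrast between
loss-of-function-intolerant and tolerant genes, hypergeometric enrichment
of a variant set within a gene set, and the gene-length diagnostic
(gene length and age are nearly uncorrelated, which supports using an
unnormalised median).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._permutation import empirical_p, stratified_null, z_and_p
from .errors import ContractError
from .io import GeneModel, VariantAtlas

__all__ = [
    "INTERGENIC",
    "MULTI_GENE",
    "GeneSetAgeResult",
    "assign_snps_to_genes",
    "estimate_gene_ages",
    "select_age_fraction",
    "gene_set_age_test",
    "lof_age_contrast",
    "variant_in_geneset_enrichment",
    "gene_length_age_check",
]

INTERGENIC = "__intergenic__"
MULTI_GENE = "__multi_gene__"


def assign_snps_to_genes(
    atlas: VariantAtlas, genes: Sequence[GeneModel], window_bp: int = 0
) -> pd.DataFrame:
    """Assign every atlas SNP to a gene, or a sentinel outcome.

    A SNP maps to gene G iff ``tx_start - window <= pos <= tx_end + window``
    on the same chromosome.  Hitting >= 2 genes yields ``MULTI_GENE``,
    hitting none ``INTERGENIC``; each SNP gets exactly one outcome.
    """
    if window_bp < 0:
        raise ContractError("window_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # half-open tree interval [start, end+1) == inclusive [start, end]
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.tx_start - window_bp, g.tx_end + window_bp + 1, g.gene_id
        )
    frame = atlas.frame
    outcomes = []
    for chrom, pos in zip(frame["chrom"], frame["pos"]):
        tree = trees.get(chrom)
        hits = tree[pos] if tree is not None else ()
        if not hits:
            outcomes.append(INTERGENIC)
        elif len(hits) == 1:
            outcomes.append(next(iter(hits)).data)
        else:
            outcomes.append(MULTI_GENE)
    return pd.DataFrame({"variant_id": frame["variant_id"], "gene_id": outcomes})


def estimate_gene_ages(
    assignments: pd.DataFrame, atlas: VariantAtlas
) -> pd.DataFrame:
    """Per-gene median SNP age with support counts.

    Sentinel assignments are excluded; genes without any assigned SNP are
    simply absent from the output.  Columns: ``gene_id``, ``median_age``,
    ``n_snps``, ``min_age``, ``max_age``.
    """
    merged = assignments.merge(
        atlas.frame[["variant_id", "age_years"]], on="variant_id", how="left"
    )
    if merged["age_years"].isna().any():
        raise ContractError("assignments reference variants missing from the atlas")
    merged = merged[~merged["gene_id"].isin([INTERGENIC, MULTI_GENE])]
    if len(merged) == 0:
        return pd.DataFrame(
            columns=["gene_id", "median_age", "n_snps", "min_age", "max_age"]
        )
    grouped = merged.groupby("gene_id")["age_years"]
    table = grouped.agg(
        median_age="median", n_snps="size", min_age="min", max_age="max"
    ).reset_index()
    return table.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def select_age_fraction(
    gene_ages: pd.DataFrame, fraction: float = 0.10, side: str = "young"
) -> list[str]:
    """The youngest/oldest ``ceil(fraction * n)`` genes by median age.

    Ties at the boundary break by gene id for determinism.  Returns gene
    ids in selection order (extreme first).
    """
    if not (0.0 < fraction <= 0.5):
        raise ContractError("fraction must lie in (0, 0.5]")
    if side not in {"young", "old"}:
        raise ContractError("side must be 'young' or 'old'")
    n = len(gene_ages)
    if n == 0:
        raise ContractError("no dated genes to select from")
    k = math.ceil(fraction * n)
    ordered = gene_ages.sort_values(
        ["median_age", "gene_id"], ascending=[side == "young", True], kind="mergesort"
    )
    return ordered["gene_id"].head(k).tolist()


@dataclass
class GeneSetAgeResult:
    """Size-matched null test of a gene set's median age."""

    n_genes: int
    median_age: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    p_empirical: float


def gene_set_age_test(
    set_ids: Iterable[str],
    gene_ages: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    return_draws: bool = False,
):
    """Is a gene set younger/older than random same-size sets of dated genes?

    The null draws gene sets without replacement from the full dated-gene
    universe (size-matched; there is no MAF at gene level, so matching
    stops at size).  Algebraically this is the phenotype test with a single
    stratum, and it shares that permutation core.
    """
    set_ids = list(set_ids)
    universe = gene_ages.set_index("gene_id")["median_age"]
    missing = [g for g in set_ids if g not in universe.index]
    if missing:
        raise ContractError(f"gene set ids not in dated universe: {missing[:5]}")
    if not set_ids:
        raise ContractError("gene set is empty")
    if len(set_ids) > len(universe):
        raise ContractError("gene set larger than the dated universe")
    observed = float(np.median(universe.loc[set_ids].to_numpy()))
    summary, log = stratified_null(
        [universe.to_numpy(dtype=float)],
        [len(set_ids)],
        n_perm,
        np.median,
        seed,
        return_draws=return_draws,
    )
    z, p = z_and_p(observed, float(summary.mean), float(summary.sd))
    p_emp = empirical_p(observed, summary.stats, float(summary.mean))
    if not np.isfinite(z):
        p = p_emp
    result = GeneSetAgeResult(
        n_genes=len(set_ids),
        median_age=observed,
        null_mean=float(summary.mean),
        null_sd=float(summary.sd),
        z=z,
        p=p,
        p_empirical=p_emp,
    )
    if return_draws:
        return result, log
    return result


def lof_age_contrast(
    gene_ages: pd.DataFrame,
    lof_rank: Mapping[str, float],
    top_fraction: float = 0.10,
) -> tuple[float, float, float, float]:
    """Welch contrast: most LoF-intolerant genes vs the rest.

    ``lof_rank`` maps gene id to an intolerance rank (1 = most intolerant)
    and must cover every dated gene.  Returns (t, p, median age of the
    intolerant group, median age of the rest); negative t means the
    intolerant group is younger.
    """
    missing = [g for g in gene_ages["gene_id"] if g not in lof_rank]
    if missing:
        raise ContractError(f"lof_rank misses dated genes: {missing[:5]}")
    ranked = gene_ages.assign(rank=[lof_rank[g] for g in gene_ages["gene_id"]])
    n = len(ranked)
    k = math.ceil(top_fraction * n)
    ranked = ranked.sort_values(["rank", "gene_id"], kind="mergesort")
    top = ranked.head(k)["median_age"].to_numpy(dtype=float)
    rest = ranked.iloc[k:]["median_age"].to_numpy(dtype=float)
    if len(top) < 2 or len(rest) < 2:
        raise ContractError("each LoF group needs at least 2 genes")
    t, p = stats.ttest_ind(top, rest, equal_var=False)
    return float(t), float(p), float(np.median(top)), float(np.median(rest))


def variant_in_geneset_enrichment(
    variant_set: Iterable[str],
    gene_set: Iterable[str],
    assignments: pd.DataFrame,
    universe: Iterable[str],
) -> tuple[int, float]:
    """Hypergeometric (upper-tail) enrichment of variants in a gene set.

    The urn is ``universe`` (variant ids with an assignment outcome); a
    success is assignment to a gene in ``gene_set``.  Returns the overlap
    count and P(X >= overlap).
    """
    gene_set = set(gene_set)
    universe = list(dict.fromkeys(universe))
    assigned = assignments.set_index("variant_id")["gene_id"]
    missing = [v for v in universe if v not in assigned.index]
    if missing:
        raise ContractError(f"universe variants without assignments: {missing[:5]}")
    variant_set = set(variant_set)
    if not variant_set <= set(universe):
        raise ContractError("variant_set must be a subset of the universe")
    in_set = assigned.loc[universe].isin(gene_set)
    N = len(universe)
    K = int(in_set.sum())
    drawn = [v for v in universe if v in variant_set]
    n = len(drawn)
    k = int(in_set.loc[drawn].sum()) if n else 0
    if n == 0:
        return 0, 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, min(p, 1.0)


def gene_length_age_check(
    gene_ages: pd.DataFrame, genes: Sequence[GeneModel]
) -> tuple[float, float]:
    """Diagnostic Pearson correlation between gene length and median age."""
    lengths = {g.gene_id: g.length for g in genes}
    missing = [g for g in gene_ages["gene_id"] if g not in lengths]
    if missing:
        raise ContractError(f"gene models missing for dated genes: {missing[:5]}")
    if len(gene_ages) < 3:
        raise ContractError("need at least 3 dated genes")
    x = np.array([lengths[g] for g in gene_ages["gene_id"]], dtype=float)
    y = gene_ages["median_age"].to_numpy(dtype=float)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ContractError("zero variance in lengths or ages")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
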