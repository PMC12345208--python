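from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from paleogwas import errors
from paleogwas.genes import (
    INTERGENIC,
    MULTI_GENE,
    assign_snps_to_genes,
    estimate_gene_ages,
    gene_length_age_check,
    gene_set_age_test,
    lof_age_contrast,
    select_age_fraction,
    variant_in_geneset_enrichment,
)
from paleogwas.io import GeneModel, VariantAtlas
from paleogwas.phenotype import phenotype_age_test
from .conftest import make_atlas_frame, make_uniform_atlas

GENES = [
    GeneModel("GA", "chr1", 100, 200),
    GeneModel("GB", "chr1", 180, 300),  # overlaps GA on [180, 200]
    GeneModel("GC", "chr2", 50, 150),
]


def atlas_at(positions):
    """Atlas with one variant per (chrom, pos, age)."""
    rows = [
        (f"v{i:02d}", chrom, pos, age, 0.9, 0.3)
        for i, (chrom, pos, age) in enumerate(positions)
    ]
    return VariantAtlas(make_atlas_frame(rows))


class TestAssignment:
    def test_single_gene_containment(self):
        atlas = atlas_at([("chr1", 150, 1e4)])
        table = assign_snps_to_genes(atlas, [GENES[0]])
        assert list(table["gene_id"]) == ["GA"]

    def test_multi_gene_hits_are_excluded_sentinels(self):
        atlas = atlas_at([("chr1", 190, 1e4), ("chr1", 250, 2e4), ("chr3", 5, 3e4)])
        table = assign_snps_to_genes(atlas, GENES)
        assert list(table["gene_id"]) == [MULTI_GENE, "GB", INTERGENIC]

    def test_window_extends_the_transcription_region(self):
        atlas = atlas_at([("chr1", 99, 1e4)])
        assert list(assign_snps_to_genes(atlas, [GENES[0]])["gene_id"]) == [INTERGENIC]
        with_window = assign_snps_to_genes(atlas, [GENES[0]], window_bp=1000)
        assert list(with_window["gene_id"]) == ["GA"]

    def test_widening_the_window_never_loses_snps(self):
        # genes spaced far enough apart that no window creates multi-gene hits
        rng = np.random.default_rng(0)
        atlas = atlas_at(
            [("chr1", int(p), 1e4) for p in rng.integers(1, 150_000, size=200)]
        )
        genes = [
            GeneModel(f"G{i}", "chr1", 1 + 10_000 * i, 2_000 + 10_000 * i)
            for i in range(15)
        ]
        previous = None
        for window in (0, 50, 200, 1000):
            table = assign_snps_to_genes(atlas, genes, window_bp=window)
            ages = estimate_gene_ages(table, atlas)
            counts = ages.set_index("gene_id")["n_snps"]
            if previous is not None:
                joined = previous.reindex(counts.index).fillna(0)
                assert (counts >= joined).all()
            previous = counts


class TestGeneAges:
    def test_hand_computed_median(self):
        atlas = atlas_at([("chr1", 110, 1e4), ("chr1", 120, 2e4), ("chr1", 130, 9e4)])
        table = assign_snps_to_genes(atlas, [GENES[0]])
        ages = estimate_gene_ages(table, atlas)
        assert ages.loc[0, "median_age"] == 2e4
        assert ages.loc[0, "n_snps"] == 3
        assert ages.loc[0, "min_age"] == 1e4 and ages.loc[0, "max_age"] == 9e4

    def test_gene_without_snps_is_absent(self):
        atlas = atlas_at([("chr1", 150, 1e4)])  # inside GA only
        ages = estimate_gene_ages(assign_snps_to_genes(atlas, GENES), atlas)
        assert set(ages["gene_id"]) == {"GA"}  # GB and GC have no SNPs

    def test_sentinels_never_contribute_and_medians_match_brute_force(self):
        rng = np.random.default_rng(1)
        positions = [("chr1", int(p), float(a)) for p, a in
                     zip(rng.integers(1, 5_000, 300), rng.uniform(1e3, 1e6, 300))]
        atlas = atlas_at(positions)
        genes = [GeneModel(f"G{i}", "chr1", 1 + 300 * i, 280 + 300 * i) for i in range(12)]
        table = assign_snps_to_genes(atlas, genes)
        ages = estimate_gene_ages(table, atlas)
        frame = atlas.frame.set_index("variant_id")
        for _, row in ages.iterrows():
            vids = table.loc[table["gene_id"] == row["gene_id"], "variant_id"]
            expected = np.median(frame.loc[vids, "age_years"])
            assert row["median_age"] == pytest.approx(expected, rel=1e-12)
        excluded = table[table["gene_id"].isin([INTERGENIC, MULTI_GENE])]
        assert not set(excluded["variant_id"]) & set(
            table[~table["gene_id"].isin([INTERGENIC, MULTI_GENE])]["variant_id"]
        )


def gene_age_frame(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n)],
            "median_age": rng.uniform(4e3, 3e6, n),
            "n_snps": rng.integers(1, 200, n),
        }
    )


class TestAgeFractionSelection:
    @pytest.mark.parametrize("n,expected", [(18_328, 1833), (16_344, 1635), (10, 1)])
    def test_ceiling_rule_reproduces_printed_set_sizes(self, n, expected):
        ages = gene_age_frame(n)
        assert len(select_age_fraction(ages, 0.10, "young")) == expected

    def test_young_and_old_deciles_are_disjoint_and_extreme(self):
        ages = gene_age_frame(500, seed=2)
        young = select_age_fraction(ages, 0.10, "young")
        old = select_age_fraction(ages, 0.10, "old")
        assert not set(young) & set(old)
        lookup = ages.set_index("gene_id")["median_age"]
        assert lookup.loc[young].max() < lookup.loc[old].min()

    def test_ties_break_by_gene_id(self):
        ages = pd.DataFrame(
            {"gene_id": ["B", "A", "C"], "median_age": [5.0, 5.0, 9.0]}
        )
        assert select_age_fraction(ages, 0.5, "young") == ["A", "B"]

    def test_empty_and_bad_fraction_are_rejected(self):
        with pytest.raises(errors.ContractError):
            select_age_fraction(gene_age_frame(0), 0.1)
        with pytest.raises(errors.ContractError):
            select_age_fraction(gene_age_frame(10), 0.8)


class TestGeneSetAgeTest:
    def test_single_stratum_identity_with_phenotype_test(self):
        # same values, same ids, one MAF stratum -> byte-identical null moments
        atlas = make_uniform_atlas(300, seed=3)
        frame = atlas.frame.copy()
        frame["maf"] = 0.45
        atlas = VariantAtlas(frame)
        target = frame.sort_values("variant_id").iloc[:40]
        ages = pd.DataFrame(
            {
                "gene_id": frame.sort_values("variant_id")["variant_id"].to_numpy(),
                "median_age": frame.sort_values("variant_id")["age_years"].to_numpy(),
            }
        )
        pheno = phenotype_age_test(target, atlas, n_perm=80, seed=21)
        geneset = gene_set_age_test(
            target["variant_id"].tolist(), ages, n_perm=80, seed=21
        )
        assert geneset.null_mean == pheno.null_mean
        assert geneset.null_sd == pheno.null_sd
        assert geneset.median_age == pheno.median_age

    def test_null_moments_match_brute_force(self):
        ages = gene_age_frame(200, seed=4)
        result, log = gene_set_age_test(
            ages["gene_id"].iloc[:30].tolist(), ages, n_perm=120, seed=5,
            return_draws=True,
        )
        null = np.array([np.median(log.pools[0][d[0]]) for d in log.draws])
        assert result.null_mean == pytest.approx(null.mean(), rel=1e-12)
        assert result.null_sd == pytest.approx(null.std(ddof=1), rel=1e-12)

    def test_whole_universe_is_degenerate(self):
        ages = gene_age_frame(40, seed=6)
        result = gene_set_age_test(ages["gene_id"].tolist(), ages, n_perm=30, seed=7)
        assert result.z == 0.0 and result.p == 1.0

    def test_planted_young_decile_is_strongly_negative(self):
        ages = gene_age_frame(600, seed=8)
        young = select_age_fraction(ages, 0.10, "young")
        result = gene_set_age_test(young, ages, n_perm=500, seed=9)
        assert result.z < -3 and result.p < 0.005

    def test_unknown_ids_are_rejected(self):
        ages = gene_age_frame(10)
        with pytest.raises(errors.ContractError):
            gene_set_age_test(["nope"], ages)


class TestLofContrast:
    def test_planted_young_intolerant_group_gives_negative_t(self):
        ages = gene_age_frame(300, seed=10)
        ranks = {g: i + 1 for i, g in enumerate(ages["gene_id"])}
        shifted = ages.copy()
        top = ages["gene_id"].iloc[:30]
        shifted.loc[shifted["gene_id"].isin(top), "median_age"] *= 0.5
        t, p, med_top, med_rest = lof_age_contrast(shifted, ranks)
        assert t < 0 and med_top < med_rest

    def test_swapping_group_labels_negates_t(self):
        ages = gene_age_frame(100, seed=11)
        n = len(ages)
        ranks = {g: i + 1 for i, g in enumerate(ages["gene_id"])}
        flipped = {g: n - r + 1 for g, r in ranks.items()}
        t_a, *_ = lof_age_contrast(ages, ranks, top_fraction=0.5)
        t_b, *_ = lof_age_contrast(ages, flipped, top_fraction=0.5)
        assert t_a == pytest.approx(-t_b, rel=1e-9)

    def test_incomplete_ranks_are_rejected(self):
        ages = gene_age_frame(10)
        with pytest.raises(errors.ContractError):
            lof_age_contrast(ages, {"G00000": 1})


class TestVariantInGenesetEnrichment:
    @staticmethod
    def assignment_table(mapping):
        return pd.DataFrame(
            {"variant_id": list(mapping), "gene_id": list(mapping.values())}
        )

    def test_hand_computed_hypergeometric_tail(self):
        # urn N=10, successes K=5, draw n=4, overlap k=4 -> 5/210
        mapping = {f"v{i}": ("Gin" if i < 5 else "Gout") for i in range(10)}
        table = self.assignment_table(mapping)
        k, p = variant_in_geneset_enrichment(
            ["v0", "v1", "v2", "v3"], ["Gin"], table, list(mapping)
        )
        assert k == 4
        assert p == pytest.approx(5 / 210, rel=1e-12)

    def test_tail_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        mapping = {f"v{i}": f"G{rng.integers(0, 4)}" for i in range(12)}
        table = self.assignment_table(mapping)
        universe = list(mapping)
        variant_set = [u for u in universe[:5]]
        gene_set = ["G0", "G1"]
        k, p = variant_in_geneset_enrichment(variant_set, gene_set, table, universe)
        # enumerate all same-size draws from the urn, count >= k successes
        success = {v for v in universe if mapping[v] in gene_set}
        total = hits = 0
        for combo in combinations(universe, len(variant_set)):
            total += 1
            hits += len(set(combo) & success) >= k
        assert p == pytest.approx(hits / total, rel=1e-12)

    def test_saturated_and_empty_cases(self):
        mapping = {f"v{i}": "G0" for i in range(6)}
        table = self.assignment_table(mapping)
        k, p = variant_in_geneset_enrichment(
            ["v0", "v1"], ["G0"], table, list(mapping)
        )
        assert p == 1.0  # gene set covers the whole urn
        k, p = variant_in_geneset_enrichment([], ["G0"], table, list(mapping))
        assert (k, p) == (0, 1.0)

    def test_inconsistent_universe_is_rejected(self):
        table = self.assignment_table({"v0": "G0"})
        with pytest.raises(errors.ContractError):
            variant_in_geneset_enrichment(["v9"], ["G0"], table, ["v0", "v9"])


class TestGeneLengthCheck:
    def test_perfect_negative_linear_relation(self):
        genes = [GeneModel(f"G{i}", "chr1", 1, 100 + 10 * i) for i in range(5)]
        ages = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "median_age": [1000.0 - g.length for g in genes],
            }
        )
        r, _ = gene_length_age_check(ages, genes)
        assert r == pytest.approx(-1.0, rel=1e-12)

    def test_constant_lengths_are_degenerate(self):
        genes = [GeneModel(f"G{i}", "chr1", 1, 100) for i in range(5)]
        ages = pd.DataFrame(
            {"gene_id": [g.gene_id for g in genes], "median_age": [1.0, 2, 3, 4, 5]}
        )
        with pytest.raises(errors.ContractError):
            gene_length_age_check(ages, genes)

    def test_independent_lengths_and_ages_are_uncorrelated(self):
        rng = np.random.default_rng(13)
        n = 10_000
        genes = [
            GeneModel(f"G{i:05d}", "chr1", 1, 2 + int(l))
            for i, l in enumerate(rng.integers(100, 100_000, n))
        ]
        ages = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "median_age": rng.uniform(4e3, 3e6, n),
            }
        )
        r, _ = gene_length_age_check(ages, genes)
        assert abs(r) < 0.03
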