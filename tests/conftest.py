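import numpy as np
import pandas as pd
import pytest

from paleogwas.io import VariantAtlas, LdTable
from paleogwas.synthetic import AtlasSpec, simulate_atlas


def make_atlas_frame(rows):
    """Atlas frame from (variant_id, chrom, pos, age, quality, maf) tuples."""
    return pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "age_years", "quality", "maf"]
    )


def make_uniform_atlas(n, seed, age_max=2_000_000.0):
    """Flat-age, flat-MAF atlas for calibration checks on the test machinery."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "variant_id": [f"rs{i:07d}" for i in range(n)],
            "chrom": "chr1",
            "pos": np.arange(1, n + 1),
            "age_years": rng.uniform(1.0, age_max, n),
            "quality": 1.0,
            "maf": rng.uniform(1e-3, 0.5, n),
        }
    )
    return VariantAtlas(frame)


@pytest.fixture(scope="session")
def sim_atlas():
    """Default-condition synthetic atlas, shared across tests (read-only)."""
    return simulate_atlas(AtlasSpec(n_variants=20_000, seed=0))


@pytest.fixture(scope="session")
def sim_atlas_200k():
    """Full-size default atlas for peak-recovery style checks."""
    return simulate_atlas(AtlasSpec(n_variants=200_000, seed=0))


def build_funnel_fixture():
    """Hand-built 20-association fixture with one known violation per filter.

    Returns (atlas, associations, ld, expectations) where expectations maps
    each funnel stage to the set of variant ids it must remove.
    """
    # trait "big" has 25 distinct clean variants is too many to hand-write;
    # the min-count filter is instead exercised with k=3: trait "keep3" has
    # 3 distinct variants, trait "drop2" has 2.
    rows = []
    atlas_rows = []

    def add(vid, chrom, pos, age, quality, maf, trait, n, in_atlas=True):
        if in_atlas:
            atlas_rows.append((vid, chrom, pos, age, quality, maf))
        rows.append(
            {
                "variant_id": vid,
                "trait": trait,
                "subchapter": f"sub_{trait}",
                "chapter": f"ch_{trait}",
                "domain": f"dom_{trait}",
                "gwas_id": f"g_{trait}",
                "sample_size": n,
            }
        )

    # clean backbone for trait keep3
    add("v01", "chr1", 1_000, 50_000, 0.90, 0.30, "keep3", 60_000)
    add("v02", "chr1", 2_000, 60_000, 0.80, 0.25, "keep3", 60_000)
    add("v03", "chr1", 3_000, 70_000, 0.95, 0.20, "keep3", 60_000)
    # quality violations (strict > 0.7)
    add("v04", "chr1", 4_000, 80_000, 0.70, 0.30, "keep3", 60_000)  # exactly 0.7
    add("v05", "chr1", 5_000, 90_000, 0.69, 0.30, "keep3", 60_000)
    add("v06", "chr1", 6_000, 95_000, 0.71, 0.30, "keep3", 60_000)  # survives
    # sample-size violations (strict > 50,000)
    add("v07", "chr2", 1_000, 40_000, 0.90, 0.30, "keep3", 50_000)  # exactly
    add("v08", "chr2", 2_000, 45_000, 0.90, 0.30, "keep3", 49_999)
    add("v09", "chr2", 3_000, 42_000, 0.90, 0.30, "keep3", 50_001)  # survives
    # MHC containment (chr6:25-34 Mb inclusive)
    add("v10", "chr6", 30_000_000, 30_000, 0.90, 0.30, "keep3", 60_000)  # inside
    add("v11", "chr6", 25_000_000, 31_000, 0.90, 0.30, "keep3", 60_000)  # boundary in
    add("v12", "chr6", 24_999_999, 32_000, 0.90, 0.30, "keep3", 60_000)  # outside
    add("v13", "chr7", 30_000_000, 33_000, 0.90, 0.30, "keep3", 60_000)  # other chrom
    # LD structure: v14-v15 r2=0.5 (later id dropped), v16-v17 r2=0.05 (kept)
    add("v14", "chr3", 1_000, 20_000, 0.90, 0.30, "keep3", 60_000)
    add("v15", "chr3", 2_000, 21_000, 0.90, 0.30, "keep3", 60_000)
    add("v16", "chr3", 3_000, 22_000, 0.90, 0.30, "keep3", 60_000)
    add("v17", "chr3", 4_000, 23_000, 0.90, 0.30, "keep3", 60_000)
    # unmatched variant (absent from atlas)
    add("v18", "chr4", 1_000, 10_000, 0.90, 0.30, "keep3", 60_000, in_atlas=False)
    # small trait removed by the min-count filter (k=3)
    add("v19", "chr5", 1_000, 15_000, 0.90, 0.30, "drop2", 60_000)
    add("v20", "chr5", 2_000, 16_000, 0.90, 0.30, "drop2", 60_000)

    atlas = VariantAtlas(make_atlas_frame(atlas_rows))
    assocs = pd.DataFrame(rows)
    ld = LdTable([("v14", "v15", 0.5), ("v16", "v17", 0.05)])
    expectations = {
        "match": {"v18"},
        "thresholds": {"v04", "v05", "v07", "v08"},
        "mhc": {"v10", "v11"},
        "ld": {"v15"},
        "min_count": {"v19", "v20"},
    }
    return atlas, assocs, ld, expectations


@pytest.fixture()
def funnel_fixture():
    return build_funnel_fixture()
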