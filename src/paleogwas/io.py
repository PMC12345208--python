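"""Data model, validation and readers/writers for pipeline tables.

The pipeline's tables are plain tab-delimited files with fixed headers:

* **atlas** — one row per dated variant: ``variant_id  chrom  pos
  age_years  quality  maf``.  Ages are years before present (the dating
  database's combined median TMRCA estimate), ``quality`` is a confidence
  score in [0, 1], ``maf`` the minor allele frequency in (0, 0.5].
* **associations** — GWAS lead SNPs with the 4-level phenotype hierarchy:
  ``variant_id  trait  subchapter  chapter  domain  gwas_id  sample_size``.
* **LD pairs** — ``id_a  id_b  r2`` with symmetric lookup; absent pairs
  are treated as r2 = 0.
* **gene models** — BED (0-based half-open), converted at the boundary to
  the 1-based inclusive coordinates used internally.
* **expression** — region x gene matrix; first column ``region_id``,
  optional second column ``stage`` ({prenatal, postnatal}).

Malformed rows abort with row numbers by default; ``permissive=True`` logs
and skips them instead, so silent data loss never happens unnoticed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, IntegrityError, SchemaError

logger = logging.getLogger("paleogwas")

ATLAS_COLUMNS = ["variant_id", "chrom", "pos", "age_years", "quality", "maf"]
ASSOCIATION_COLUMNS = [
    "variant_id",
    "trait",
    "subchapter",
    "chapter",
    "domain",
    "gwas_id",
    "sample_size",
]
HIERARCHY_LEVELS = ("domain", "chapter", "subchapter", "trait")
LD_COLUMNS = ["id_a", "id_b", "r2"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatedVariant:
    """A single dated-atlas entry."""

    variant_id: str
    chrom: str
    pos: int
    age_years: float
    quality: float
    maf: float

    def __post_init__(self):
        _check_variant_row(self.__dict__, context=f"variant {self.variant_id}")


def _check_variant_row(row: Mapping, context: str) -> str | None:
    """Return an error message for an invalid atlas row, else None."""
    try:
        pos = int(row["pos"])
        age = float(row["age_years"])
        quality = float(row["quality"])
        maf = float(row["maf"])
    except (TypeError, ValueError) as exc:  # non-numeric field
        if context.startswith("variant "):
            raise IntegrityError(f"{context}: non-numeric field ({exc})")
        return f"non-numeric field ({exc})"
    msg = None
    if pos < 1:
        msg = f"pos must be >= 1, got {pos}"
    elif not age > 0:
        msg = f"age_years must be > 0, got {age}"
    elif not (0.0 <= quality <= 1.0):
        msg = f"quality must lie in [0, 1], got {quality}"
    elif not (0.0 < maf <= 0.5):
        msg = f"maf must lie in (0, 0.5], got {maf}"
    if msg is not None and context.startswith("variant "):
        raise IntegrityError(f"{context}: {msg}")
    return msg


class VariantAtlas:
    """Immutable-by-convention collection of dated variants.

    Wraps a DataFrame with :data:`ATLAS_COLUMNS`; lookups by ``variant_id``
    are total over stored ids and O(1) through an index.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = ""):
        missing = [c for c in ATLAS_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"atlas is missing columns: {missing}")
        frame = frame.loc[:, ATLAS_COLUMNS].reset_index(drop=True)
        dup = frame["variant_id"].duplicated()
        if dup.any():
            dup_ids = frame.loc[dup, "variant_id"].unique()[:5]
            raise IntegrityError(f"duplicate variant_id values: {list(dup_ids)} ...")
        self._frame = frame
        self._index = pd.Index(frame["variant_id"])
        self.provenance = provenance

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    @property
    def frame(self) -> pd.DataFrame:
        """Underlying table (treat as read-only)."""
        return self._frame

    def get(self, variant_id: str) -> DatedVariant:
        loc = self._index.get_indexer([variant_id])[0]
        if loc < 0:
            raise KeyError(variant_id)
        row = self._frame.iloc[loc]
        return DatedVariant(
            variant_id=row["variant_id"],
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            age_years=float(row["age_years"]),
            quality=float(row["quality"]),
            maf=float(row["maf"]),
        )

    def subset(self, variant_ids: Iterable[str]) -> pd.DataFrame:
        """Rows for the given ids, in atlas order; unknown ids raise."""
        ids = pd.Index(variant_ids)
        unknown = ids.difference(self._index)
        if len(unknown):
            raise KeyError(f"unknown variant ids: {list(unknown[:5])}")
        return self._frame[self._frame["variant_id"].isin(ids)]


@dataclass(frozen=True)
class Association:
    """One lead-SNP / phenotype association record."""

    variant_id: str
    trait: str
    subchapter: str
    chapter: str
    domain: str
    gwas_id: str
    sample_size: int

    def __post_init__(self):
        for level in HIERARCHY_LEVELS:
            if not getattr(self, level):
                raise IntegrityError(f"association {self.variant_id}: empty {level}")
        if self.sample_size < 1:
            raise IntegrityError(
                f"association {self.variant_id}: sample_size must be >= 1"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene transcription region, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str = "unknown"

    def __post_init__(self):
        if self.tx_start > self.tx_end:
            raise IntegrityError(
                f"gene {self.gene_id}: tx_start {self.tx_start} > tx_end {self.tx_end}"
            )
        if self.strand not in {"+", "-", "unknown"}:
            raise IntegrityError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start + 1


class LdTable:
    """Symmetric r2 lookup; missing pairs read as 0."""

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[tuple[str, str], float] = {}
        self._partners: dict[str, set[str]] = {}
        for a, b, r2 in pairs:
            self.add(a, b, float(r2))

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise IntegrityError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a == b:
            return  # self-LD carries no pruning information
        self._r2[self._key(a, b)] = r2
        self._partners.setdefault(a, set()).add(b)
        self._partners.setdefault(b, set()).add(a)

    def r2(self, a: str, b: str) -> float:
        return self._r2.get(self._key(a, b), 0.0)

    def partners(self, a: str) -> set[str]:
        return self._partners.get(a, set())

    def items(self):
        """Iterate (id_a, id_b, r2) with id_a <= id_b, sorted."""
        for (a, b), r2 in sorted(self._r2.items()):
            yield a, b, r2

    def __len__(self) -> int:
        return len(self._r2)


class ExpressionMatrix:
    """Region (or sample) x gene expression values with optional stages."""

    def __init__(self, values: pd.DataFrame, stages: pd.Series | None = None):
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise IntegrityError("expression matrix has duplicate region or gene ids")
        if values.isna().any().any():
            raise IntegrityError("expression matrix contains missing values")
        self.values = values.astype(float)
        if stages is not None:
            stages = stages.reindex(values.index)
            if stages.isna().any():
                raise IntegrityError("stage labels missing for some rows")
            bad = set(stages.unique()) - {"prenatal", "postnatal"}
            if bad:
                raise IntegrityError(f"unknown stage labels: {sorted(bad)}")
        self.stages = stages

    @property
    def regions(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GenerationScale:
    """Conversion between years and generations (default 25 y/generation)."""

    years_per_generation: float = 25.0

    def __post_init__(self):
        if self.years_per_generation <= 0:
            raise ContractError("years_per_generation must be positive")

    def to_generations(self, years):
        return np.asarray(years, dtype=float) / self.years_per_generation

    def to_years(self, generations):
        return np.asarray(generations, dtype=float) * self.years_per_generation


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_atlas(
    path, min_quality: float | None = None, permissive: bool = False
) -> VariantAtlas:
    """Read a dated-variant atlas table.

    ``min_quality`` keeps rows with quality strictly greater than the
    threshold (the dating-confidence filter is "above", not "at least").
    """
    frame = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    missing = [c for c in ATLAS_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing atlas columns {missing}")
    bad_rows = []
    for i, row in enumerate(frame[ATLAS_COLUMNS].to_dict("records")):
        msg = _check_variant_row(row, context=f"row {i + 2}")  # header is line 1
        if msg is not None:
            bad_rows.append((i, f"row {i + 2} ({row['variant_id']}): {msg}"))
    if bad_rows:
        if not permissive:
            raise IntegrityError(f"{path}: " + "; ".join(m for _, m in bad_rows[:10]))
        logger.warning("%s: skipping %d malformed rows", path, len(bad_rows))
        frame = frame.drop(index=[i for i, _ in bad_rows]).reset_index(drop=True)
    if min_quality is not None:
        n0 = len(frame)
        frame = frame[frame["quality"] > min_quality].reset_index(drop=True)
        logger.info(
            "read_atlas quality > %g: %d -> %d rows", min_quality, n0, len(frame)
        )
    return VariantAtlas(frame, provenance=str(path))


def read_associations(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gwas_id": str})
    missing = [c for c in ASSOCIATION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing association columns {missing}")
    for level in HIERARCHY_LEVELS:
        empty = frame[level].isna() | (frame[level].astype(str).str.len() == 0)
        if empty.any():
            raise IntegrityError(f"{path}: empty {level} labels at rows {list(frame.index[empty][:5])}")
    if (frame["sample_size"] < 1).any():
        raise IntegrityError(f"{path}: sample_size must be >= 1")
    return frame.reset_index(drop=True)


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open -> 1-based inclusive)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise SchemaError(f"{path}:{lineno}: BED needs chrom,start,end,name")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise IntegrityError(
                    f"{path}:{lineno}: degenerate interval start={start} end={end}"
                )
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "unknown"
            genes.append(
                GeneModel(gene_id=name, chrom=chrom, tx_start=start + 1, tx_end=end, strand=strand)
            )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as BED (inverse of :func:`read_gene_models`)."""
    with open(path, "w") as fh:
        for g in genes:
            strand = g.strand if g.strand in {"+", "-"} else "."
            fh.write(f"{g.chrom}\t{g.tx_start - 1}\t{g.tx_end}\t{g.gene_id}\t0\t{strand}\n")


def read_ld_pairs(path) -> LdTable:
    frame = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
    missing = [c for c in LD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing LD columns {missing}")
    return LdTable(frame[LD_COLUMNS].itertuples(index=False, name=None))


def read_expression(path, stage_column: str = "stage") -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    if "region_id" not in frame.columns:
        raise SchemaError(f"{path}: expression table needs a region_id column")
    frame = frame.set_index("region_id")
    stages = None
    if stage_column in frame.columns:
        stages = frame.pop(stage_column)
    return ExpressionMatrix(frame, stages=stages)


def write_results(table: pd.DataFrame, path) -> None:
    """Write any result table as TSV, 12 significant digits."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
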