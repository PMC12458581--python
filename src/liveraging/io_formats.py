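"""Readers and writers for the flat formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) everywhere in
the package; any 1-based dialect must be converted at this boundary.  Tables
are TSV with a header row; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ParseError, SchemaError

logger = logging.getLogger(__name__)

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (BED semantics)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(_VALID_STRANDS)}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def interval_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneAnnotation:
    """Minimal gene model: a TSS position with a strand.

    Promoter windows are derived from this (TSS +/- flank), so no exon
    structure is carried.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")


@dataclass
class ExpressionMatrix:
    """Genes x samples values plus per-sample metadata.

    ``values`` is indexed by gene id with one column per sample;
    ``samples`` is indexed by sample id (same order as the columns) and
    carries whatever metadata the study design needs (age, sex, exposure,
    disease state, ...).
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.values.columns)
        if list(self.samples.index) != list(self.values.columns):
            raise ValueError("sample metadata index must match value columns")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def sample_ids(self, **criteria) -> list[str]:
        """Sample ids whose metadata matches all keyword criteria."""
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        return list(self.samples.index[mask])

    def to_tsv(self, values_path: str | Path, samples_path: str | Path) -> None:
        self.values.rename_axis("gene_id").to_csv(values_path, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, values_path: str | Path, samples_path: str | Path | None = None
    ) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
        samples = None
        if samples_path is not None:
            samples = pd.read_csv(samples_path, sep="\t", index_col=0, comment="#")
            samples = samples.loc[values.columns]
        return cls(values=values, samples=samples)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse a BED3/BED6 file into a list of intervals (order preserved).

    Raises :class:`ParseError` naming the offending line for non-integer
    coordinates, degenerate intervals (end <= start) or too few columns.
    """
    intervals: list[GenomicInterval] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >=3 tab-separated columns, got {len(fields)}",
                    path=str(path), line=lineno,
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"non-integer coordinates {fields[1]!r}/{fields[2]!r}",
                    path=str(path), line=lineno,
                ) from exc
            name = fields[3] if len(fields) > 3 else ""
            score = 0.0
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(
                        f"non-numeric score {fields[4]!r}", path=str(path), line=lineno
                    ) from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
                )
            except ValueError as exc:
                raise ParseError(str(exc), path=str(path), line=lineno) from exc
    logger.info("read %d intervals from %s", len(intervals), path)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 such that ``read_bed`` round-trips them."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file into {set name -> set of gene ids}.

    Duplicate genes within one set collapse (set semantics); duplicate set
    names across lines are an error.
    """
    collection: dict[str, set[str]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT line needs name, description and >=1 gene",
                    path=str(path), line=lineno,
                )
            name, genes = fields[0], {g for g in fields[2:] if g}
            if name in collection:
                raise ParseError(f"duplicate gene-set name {name!r}", path=str(path), line=lineno)
            if not genes:
                raise ParseError(f"gene set {name!r} is empty", path=str(path), line=lineno)
            collection[name] = genes
    return collection


def write_gmt(collection: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description, *sorted(set(genes))]) + "\n")


# ---------------------------------------------------------------------------
# Generic TSV tables
# ---------------------------------------------------------------------------

def read_table(
    path: str | Path,
    schema: Mapping[str, type] | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a header-bearing TSV, validating that schema columns exist.

    ``schema`` may be a sequence of required column names or a mapping
    column -> dtype (the column is cast).  Missing columns raise
    :class:`SchemaError` naming the column.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if schema is not None:
        names = list(schema.keys()) if isinstance(schema, Mapping) else list(schema)
        for col in names:
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} missing from {path}")
        if isinstance(schema, Mapping):
            for col, dtype in schema.items():
                try:
                    df[col] = df[col].astype(dtype)
                except (TypeError, ValueError) as exc:
                    raise SchemaError(
                        f"column {col!r} in {path} cannot be cast to {dtype}"
                    ) from exc
    logger.info("read %d rows from %s", len(df), path)
    return df


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read the TSS annotation table (gene_id, chrom, tss, strand)."""
    df = read_table(path, schema={"gene_id": str, "chrom": str, "tss": int, "strand": str})
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise SchemaError(f"duplicate gene_id entries in annotation: {dupes[:5]}")
    return [
        GeneAnnotation(r.gene_id, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_gene_annotation(annotation: Iterable[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.gene_id, a.chrom, a.tss, a.strand) for a in annotation],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)
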