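"""Readers and writers for the formats the occupancy pipeline consumes.

All in-memory coordinates are 0-based half-open, matching the BED and
narrowPeak dialects.  Tab-separated tables (gene annotation, expression,
qPCR Ct) use fixed headers documented in the README; the annotation TSS
column is 0-based to match the interval convention.

Reading is tolerant of extra columns where the format allows them (BED
beyond column 6); writing is strict so that write∘read is the identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised on malformed input files; message names the offending line."""


_DNA_ALPHABET = frozenset("ACGTN")
_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open (one aligned read, typically)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of +, -, . — got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """An ENCODE narrowPeak record.

    ``summit_offset`` is the point-source offset from ``start`` (narrowPeak
    column 10), or -1 when no summit was called.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    signal: float = 0.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.signal < 0:
            raise ValueError(f"signalValue must be >= 0, got {self.signal}")
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{self.end - self.start}"
            )

    @property
    def summit(self) -> int:
        """Absolute summit coordinate; midpoint when no summit was called."""
        if self.summit_offset >= 0:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's TSS and the class flags the analysis stratifies on."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    is_rp: bool = False
    is_dba: bool = False

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter sequence anchored on the A of the translation start codon.

    ``atg_index`` is the 0-based index of that A within ``sequence``.  It may
    equal or exceed ``len(sequence)`` for sequences lying entirely upstream of
    the start codon; it then merely fixes the coordinate frame.
    """

    sequence: str
    atg_index: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)}")
        if self.atg_index < 0:
            raise ValueError("atg_index must be >= 0")


class ExpressionMatrix:
    """Genes × ordered differentiation stages of RPKM values for one species."""

    def __init__(
        self,
        genes: list[str],
        stages: list[str],
        values: np.ndarray,
        species: str = "unknown",
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(genes), len(stages)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(genes)} genes x {len(stages)} stages"
            )
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("RPKM values must be finite and >= 0")
        if len(set(genes)) != len(genes):
            raise ValueError("gene ids must be unique")
        self.genes = list(genes)
        self.stages = list(stages)
        self.values = values
        self.species = species

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.stages == other.stages
            and self.species == other.species
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix({len(self.genes)} genes x {len(self.stages)} "
            f"stages, species={self.species!r})"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.stages)


@dataclass(frozen=True)
class CtMeasurement:
    """Technical-replicate Ct values for one (sample, amplicon) pair."""

    sample: str
    amplicon: str
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_values:
            raise ValueError("ct_values must be non-empty")
        for ct in self.ct_values:
            if not (0 < ct < 50):
                raise ValueError(f"Ct value {ct} outside (0, 50)")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_values))


# ---------------------------------------------------------------------------
# BED intervals


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"line {lineno}: non-integer {what}: {token!r}") from None


def read_intervals(path: str | Path) -> list[Interval]:
    """Read a BED file (>= 3 columns) into 0-based half-open intervals.

    Strand is taken from column 6 when present, else ``"."``.  Columns beyond
    6 are ignored.
    """
    intervals: list[Interval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: expected >= 3 tab-separated fields")
        start = _parse_int(fields[1], "start", lineno)
        end = _parse_int(fields[2], "end", lineno)
        strand = fields[5] if len(fields) >= 6 else "."
        try:
            intervals.append(Interval(fields[0], start, end, strand))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
    return intervals


def write_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write 6-column BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# narrowPeak


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read ENCODE narrowPeak (exactly 10 columns per data line)."""
    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 10:
            raise FormatError(
                f"line {lineno}: narrowPeak requires 10 columns, found {len(fields)}"
            )
        start = _parse_int(fields[1], "start", lineno)
        end = _parse_int(fields[2], "end", lineno)
        try:
            signal = float(fields[6])
        except ValueError:
            raise FormatError(
                f"line {lineno}: non-numeric signalValue: {fields[6]!r}"
            ) from None
        summit = _parse_int(fields[9], "summit offset", lineno)
        try:
            peaks.append(Peak(fields[0], start, end, fields[3], signal, summit))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                f"{p.signal!r}\t-1\t-1\t{p.summit_offset}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{record id: uppercased sequence}``.

    Duplicate record ids are an error.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA record id: {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    """Write FASTA wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tab-separated tables

ANNOTATION_COLUMNS = ["gene_id", "gene_name", "chrom", "strand", "tss", "is_rp", "is_dba"]
QPCR_COLUMNS = ["sample", "amplicon", "ct"]


def _read_tsv(path: str | Path, required: list[str], schema: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{schema} table is missing required column(s): {', '.join(missing)}"
        )
    return df


def read_table(path: str | Path, schema: str, species: str = "unknown"):
    """Read a typed TSV: ``annotation``, ``expression`` or ``qpcr``.

    - annotation → list of :class:`GeneAnnotation`
    - expression → :class:`ExpressionMatrix` (column 1 = gene_id, the
      remaining columns are the ordered stages)
    - qpcr → list of :class:`CtMeasurement`, replicate rows grouped by
      (sample, amplicon)
    """
    if schema == "annotation":
        df = _read_tsv(path, ANNOTATION_COLUMNS, schema)
        genes = []
        for row in df.itertuples(index=False):
            genes.append(
                GeneAnnotation(
                    gene_id=row.gene_id,
                    gene_name=row.gene_name,
                    chrom=row.chrom,
                    strand=row.strand,
                    tss=int(row.tss),
                    is_rp=bool(int(row.is_rp)),
                    is_dba=bool(int(row.is_dba)),
                )
            )
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate gene_id in annotation table")
        return genes
    if schema == "expression":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if df.columns[0] != "gene_id":
            raise FormatError("expression table must start with a gene_id column")
        if df.shape[1] < 2:
            raise FormatError("expression table needs at least one stage column")
        stages = list(df.columns[1:])
        values = df[stages].to_numpy(dtype=float)
        if np.any(values < 0):
            raise FormatError("expression table contains negative RPKM values")
        return ExpressionMatrix(list(df["gene_id"].astype(str)), stages, values, species)
    if schema == "qpcr":
        df = _read_tsv(path, QPCR_COLUMNS, schema)
        measurements: list[CtMeasurement] = []
        for (sample, amplicon), grp in df.groupby(["sample", "amplicon"], sort=False):
            cts = tuple(float(x) for x in grp["ct"])
            measurements.append(CtMeasurement(sample, amplicon, cts))
        return measurements
    raise ValueError(f"unknown table schema: {schema!r}")


def write_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    rows = [
        (g.gene_id, g.gene_name, g.chrom, g.strand, g.tss, int(g.is_rp), int(g.is_dba))
        for g in genes
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.insert(0, "gene_id", matrix.genes)
    df.to_csv(path, sep="\t", index=False)


def write_qpcr(measurements: Iterable[CtMeasurement], path: str | Path) -> None:
    rows = list(
        itertools.chain.from_iterable(
            ((m.sample, m.amplicon, ct) for ct in m.ct_values) for m in measurements
        )
    )
    pd.DataFrame(rows, columns=QPCR_COLUMNS).to_csv(path, sep="\t", index=False)
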