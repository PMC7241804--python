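"""Tabular and sequence I/O for junction-count analysis.

All tabular formats are TSV with a header row:

* junction counts — columns ``junction_id``, ``gene``, then one column per
  sample, holding non-negative integer read counts;
* gene expression — columns ``gene``, then one column per sample, holding
  non-negative reals (RSEM-style normalized values);
* sample metadata — columns ``sample``, ``condition``.

Sequences are plain FASTA; an optional ``offset=<int>`` token in the
description line records the 1-based genomic coordinate of the first base.

Junction coordinates are 1-based and inclusive throughout; the printed form
is ``chrom:start-end``.  On input the separators between chrom, start and
end may be ``:``, ``-`` or the typographic en-dash ``–``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "JunctionID",
    "JunctionCountMatrix",
    "GeneExpressionMatrix",
    "SequenceRecord",
    "parse_junction_id",
    "read_junction_counts",
    "write_junction_counts",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_fasta",
    "write_fasta",
]

_STRANDS = {"+", "-", "unknown"}

_JID_RE = re.compile(r"^(?P<chrom>.+?)[:\-–](?P<start>\d+)[:\-–](?P<end>\d+)$")


@dataclass(frozen=True)
class JunctionID:
    """A splice junction: donor/acceptor coordinate pair on a chromosome.

    Coordinates are 1-based, inclusive.  ``strand`` is ``"+"``, ``"-"`` or
    ``"unknown"`` (the default when the input format carries no strand).
    """

    chrom: str
    start: int
    end: int
    gene: str
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (isinstance(self.start, (int, np.integer)) and isinstance(self.end, (int, np.integer))):
            raise ValueError("start and end must be integers")
        if self.start >= self.end:
            raise ValueError(
                f"junction start must be < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_junction_id(text: str, gene: str, strand: str = "unknown") -> JunctionID:
    """Parse ``"chrom:start-end"`` into a :class:`JunctionID`.

    Hyphen, colon and en-dash are accepted interchangeably as separators
    (published junction IDs are often typeset with en-dashes), so
    ``"chr20:44443109–44444493"`` and ``"chr20:44443109-44444493"`` parse
    identically.
    """
    m = _JID_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed junction ID: {text!r}")
    return JunctionID(
        chrom=m.group("chrom"),
        start=int(m.group("start")),
        end=int(m.group("end")),
        gene=gene,
        strand=strand,
    )


@dataclass
class JunctionCountMatrix:
    """Junction x sample matrix of non-negative integer read counts.

    ``condition_of`` maps each sample to its condition label; it may be
    empty when no metadata accompanies the counts, but downstream two-group
    testing requires exactly two distinct labels.
    """

    junctions: list[JunctionID]
    samples: list[str]
    counts: np.ndarray
    condition_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.junctions), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.junctions)} junctions x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        ids = [str(j) for j in self.junctions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate junction IDs")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")
        unknown = set(self.condition_of) - set(self.samples)
        if unknown:
            raise ValueError(f"metadata names unknown samples: {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for j in self.junctions:
            seen.setdefault(j.gene, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "gene", [j.gene for j in self.junctions])
        df.insert(0, "junction_id", [str(j) for j in self.junctions])
        return df


@dataclass
class GeneExpressionMatrix:
    """Gene x sample matrix of non-negative normalized expression values."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite and non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.samples)
        df.insert(0, "gene", self.genes)
        return df


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence with the genomic coordinate of its first base."""

    name: str
    sequence: str
    offset: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.name!r}")
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"record {self.name!r} contains non-DNA characters {bad}")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval covered, 1-based inclusive."""
        return self.offset, self.offset + len(self.sequence) - 1


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_metadata(path) -> dict[str, str]:
    """Read a sample -> condition mapping from a two-column TSV."""
    df = _read_tsv(path)
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ValueError(f"metadata file {path} lacks required column {col!r}")
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate samples in metadata: {dupes}")
    return dict(zip(df["sample"], df["condition"]))


def write_metadata(condition_of: dict[str, str], path) -> None:
    df = pd.DataFrame({"sample": list(condition_of), "condition": list(condition_of.values())})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_junction_counts(path, metadata_path=None) -> JunctionCountMatrix:
    """Read a junction-count TSV (and optional sample metadata TSV).

    Raises a format error naming the offending cell when a count is
    negative or non-integer, and an error when metadata names a sample
    absent from the count matrix.
    """
    df = _read_tsv(path)
    if df.columns[0] != "junction_id" or df.columns[1] != "gene":
        raise ValueError(
            f"{path}: first two columns must be 'junction_id' and 'gene', "
            f"got {list(df.columns[:2])}"
        )
    samples = list(df.columns[2:])
    junctions = [
        parse_junction_id(jid, gene) for jid, gene in zip(df["junction_id"], df["gene"])
    ]
    counts = np.empty((len(junctions), len(samples)), dtype=np.int64)
    for ci, sample in enumerate(samples):
        for ri, raw in enumerate(df[sample]):
            try:
                value = int(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer count {raw!r} at row {ri + 2}, column {sample!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"{path}: negative count {value} at row {ri + 2}, column {sample!r}"
                )
            counts[ri, ci] = value
    condition_of: dict[str, str] = {}
    if metadata_path is not None:
        condition_of = read_metadata(metadata_path)
        unknown = set(condition_of) - set(samples)
        if unknown:
            raise ValueError(f"metadata names samples absent from counts: {sorted(unknown)}")
    return JunctionCountMatrix(junctions, samples, counts, condition_of)


def write_junction_counts(matrix: JunctionCountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_expression(path) -> GeneExpressionMatrix:
    """Read a gene-expression TSV (gene column + one column per sample)."""
    df = _read_tsv(path)
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    samples = list(df.columns[1:])
    values = np.empty((len(df), len(samples)), dtype=float)
    for ci, sample in enumerate(samples):
        for ri, raw in enumerate(df[sample]):
            try:
                value = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {raw!r} at row {ri + 2}, column {sample!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"{path}: negative value {value} at row {ri + 2}, column {sample!r}"
                )
            values[ri, ci] = value
    return GeneExpressionMatrix(list(df["gene"]), samples, values)


def write_expression(matrix: GeneExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


_OFFSET_RE = re.compile(r"\boffset=(-?\d+)\b")


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA records; sequences are uppercased, names must be unique.

    An ``offset=<int>`` token in the description line sets the genomic
    coordinate of the first base (default 1).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        m = _OFFSET_RE.search(rec.description)
        offset = int(m.group(1)) if m else 1
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), offset))
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.name, description=f"offset={r.offset}")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")
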