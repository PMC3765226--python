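"""Readers/writers for the standard formats touched by the pipeline and
the contig naming grammar ``<locus>v<version>rpkm<rpkm>[_PRE]``.

Record dataclasses mirror their source formats: variant and TE interval
coordinates are 1-based inclusive exactly as in VCF/GFF3. Sequence
slicing elsewhere in the package is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when a record is inconsistent with supplied reference data."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class TranscriptContig:
    """An assembled contig with locus assignment, isoform version,
    abundance and precursor flag."""

    contig_id: str
    sequence: str
    locus_id: str
    version: int
    rpkm: float
    precursor: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")
        if self.version < 1:
            raise ValueError("version must be >= 1")
        if self.rpkm < 0:
            raise ValueError("rpkm must be non-negative")

    @property
    def name(self) -> str:
        return format_contig_name(
            self.locus_id, self.version, self.rpkm, self.precursor
        )


@dataclass(frozen=True)
class VariantRecord:
    """One SNP or indel call; ``position`` is 1-based as in VCF."""

    contig_id: str
    position: int
    ref_allele: str
    alt_allele: str
    quality: int
    variant_class: str = field(init=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        is_snp = len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        object.__setattr__(self, "variant_class", "snp" if is_snp else "indel")


@dataclass(frozen=True)
class TEAnnotation:
    """A transposable-element interval on a contig, 1-based inclusive."""

    contig_id: str
    start: int
    end: int
    repeat_class: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("require 1 <= start <= end")


@dataclass
class ExpressionMatrix:
    """A loci x samples matrix of RPKM values with labelled axes."""

    locus_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match label lists")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.values < 0):
            raise ValueError("RPKM values must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.locus_ids, columns=self.sample_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            locus_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


# ---------------------------------------------------------------------------
# Contig naming grammar

_NAME_RE = re.compile(
    r"^(?P<locus>.+?)v(?P<version>\d+)rpkm(?P<rpkm>\d+\.\d+)(?P<pre>_PRE)?$"
)


def render_rpkm(rpkm: float) -> str:
    """Shortest positional decimal with at least one fractional digit."""
    if rpkm < 0:
        raise ValueError("rpkm must be non-negative")
    return np.format_float_positional(float(rpkm), unique=True, trim="0")


def format_contig_name(
    locus_id: str, version: int, rpkm: float, precursor: bool
) -> str:
    """Render e.g. ``Locus1v2rpkm3.45_PRE`` — the 2nd most abundant isoform
    of Locus1 at RPKM 3.45, flagged as a potential precursor."""
    if version < 1:
        raise ValueError("version must be >= 1")
    name = f"{locus_id}v{version}rpkm{render_rpkm(rpkm)}"
    return name + "_PRE" if precursor else name


def parse_contig_name(name: str) -> tuple[str, int, float, bool]:
    """Invert :func:`format_contig_name`; raises ``FormatError`` otherwise."""
    m = _NAME_RE.match(name)
    if m is None:
        raise FormatError(f"not a valid contig name: {name!r}")
    return (
        m.group("locus"),
        int(m.group("version")),
        float(m.group("rpkm")),
        m.group("pre") is not None,
    )


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, uppercase sequence)`` pairs, order kept."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"zero-length sequence for record {rec.id!r}")
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path,
             contig_lengths: dict[str, int] | None = None
             ) -> list[VariantRecord]:
    """Read VCF 4.x into variant records; QUAL parsed as integer where
    integral. If contig lengths are supplied, out-of-bounds positions raise
    a :class:`ValidationError`."""
    from cyvcf2 import VCF

    out: list[VariantRecord] = []
    for v in VCF(str(path)):
        qual = v.QUAL if v.QUAL is not None else 0
        qual = int(qual) if float(qual).is_integer() else qual
        alt = v.ALT[0] if v.ALT else "."
        rec = VariantRecord(v.CHROM, v.POS, v.REF, alt, qual)
        if contig_lengths is not None:
            length = contig_lengths.get(rec.contig_id)
            if length is not None and rec.position > length:
                raise ValidationError(
                    f"{rec.contig_id}:{rec.position} beyond contig length "
                    f"{length}"
                )
        out.append(rec)
    return out


def write_vcf(path: str | Path, records: Sequence[VariantRecord],
              contig_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for cid, length in contig_lengths.items():
                fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(
                f"{r.contig_id}\t{r.position}\t.\t{r.ref_allele}\t"
                f"{r.alt_allele}\t{r.quality}\t.\t.\n"
            )


# ---------------------------------------------------------------------------
# GFF3 intervals


def read_gff_intervals(path: str | Path,
                       contig_lengths: dict[str, int] | None = None
                       ) -> list[TEAnnotation]:
    """Read a GFF3 file of repeat intervals. The repeat class is taken from
    a ``repeat_class=`` attribute when present, else the type column."""
    out: list[TEAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"GFF3 line has {len(cols)} columns: {line!r}")
            seqid, _source, ftype, start, end, _score, _strand, _phase, attrs = cols
            repeat_class = ftype
            for item in attrs.split(";"):
                if item.startswith("repeat_class="):
                    repeat_class = item.split("=", 1)[1]
            ann = TEAnnotation(seqid, int(start), int(end), repeat_class)
            if contig_lengths is not None:
                length = contig_lengths.get(seqid)
                if length is not None and ann.end > length:
                    raise ValidationError(
                        f"interval {seqid}:{ann.start}-{ann.end} beyond "
                        f"contig length {length}"
                    )
            out.append(ann)
    return out


def write_gff_intervals(path: str | Path,
                        annotations: Sequence[TEAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                f"{a.contig_id}\trepeat\ttransposable_element\t{a.start}\t"
                f"{a.end}\t.\t+\t.\trepeat_class={a.repeat_class}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices (TSV with header row and index column)


def read_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"empty matrix in {path}")
    return ExpressionMatrix.from_dataframe(df)


def write_matrix(path: str | Path, matrix: ExpressionMatrix) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t")
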