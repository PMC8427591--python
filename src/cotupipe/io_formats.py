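"""Readers and writers for the pipeline's file formats.

FASTA, FASTQ (Sanger Phred+33) and aligned FASTA go through Bio.SeqIO; the
sample-sheet and primer-table TSV dialects (tab-separated, ``#`` comments,
UTF-8) go through pandas.  Every downstream module consumes only the types
defined here.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import AlignmentShapeError, AlphabetError, ParseError, ValidationError
from .oligo import _check_alphabet

Format = Literal["fasta", "fastq", "aligned_fasta"]


@dataclass
class SeqRecord:
    """One sequence with optional per-base Phred qualities.

    The sequence is stored uppercased with U normalised to T; the gap
    character ``-`` is permitted only in alignment context.
    """

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        self.seq = _check_alphabet(self.seq).replace("U", "T")
        if self.qual is not None:
            self.qual = list(self.qual)
            if len(self.qual) != len(self.seq):
                raise ValidationError(
                    f"record {self.id!r}: {len(self.qual)} qualities for "
                    f"{len(self.seq)} bases"
                )
            if any(q < 0 for q in self.qual):
                raise ValidationError(f"record {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> "SeqRecord":
        return SeqRecord(self.id, self.seq.replace("-", ""), None)


@dataclass
class SampleSheet:
    """Map from sample id to its unique DNA label (all labels same length, ACGT only)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("sample sheet is empty")
        clean: dict[str, str] = {}
        for sample, label in self.entries.items():
            label = label.upper()
            if set(label) - set("ACGT"):
                raise ValidationError(
                    f"label for sample {sample!r} contains non-ACGT characters: {label}"
                )
            clean[sample] = label
        lengths = {len(v) for v in clean.values()}
        if len(lengths) != 1:
            raise ValidationError(f"labels have mixed lengths: {sorted(lengths)}")
        labels = list(clean.values())
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate labels: {dup}")
        self.entries = clean

    @property
    def label_len(self) -> int:
        return len(next(iter(self.entries.values())))

    @property
    def by_label(self) -> dict[str, str]:
        return {label: sample for sample, label in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PrimerSpec:
    fwd: str
    rev: str
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not self.fwd or not self.rev:
            raise ValidationError("primers must be non-empty")
        _check_alphabet(self.fwd)
        _check_alphabet(self.rev)
        if self.min_len > self.max_len:
            raise ValidationError(
                f"min_len {self.min_len} > max_len {self.max_len}"
            )


@dataclass
class PrimerTable:
    """Map from gene (fragment) name to its primer pair and expected length range."""

    genes: dict[str, PrimerSpec]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("primer table is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.items())


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path: str | Path, format: Format) -> list[SeqRecord]:
    """Read FASTA / FASTQ / aligned FASTA into a list of :class:`SeqRecord`.

    Records keep their input order and are uppercased (U -> T).  For
    ``aligned_fasta`` all rows must have equal length, else
    :class:`AlignmentShapeError` is raised.
    """
    if format not in ("fasta", "fastq", "aligned_fasta"):
        raise ValueError(f"unknown format {format!r}")
    bio_fmt = "fastq" if format == "fastq" else "fasta"
    records: list[SeqRecord] = []
    with _open_text(path) as handle:
        try:
            for i, rec in enumerate(SeqIO.parse(handle, bio_fmt)):
                qual = rec.letter_annotations.get("phred_quality")
                records.append(SeqRecord(rec.id, str(rec.seq), qual))
        except (ValueError, AlphabetError) as exc:
            # FASTA records span 2+ lines, FASTQ exactly 4; report the line
            # at which the failing record starts.
            lines_per = 4 if bio_fmt == "fastq" else 2
            raise ParseError(
                f"{path}: malformed {format} record near line "
                f"{len(records) * lines_per + 1}: {exc}"
            ) from exc
    if format == "aligned_fasta" and records:
        widths = {len(r.seq) for r in records}
        if len(widths) != 1:
            raise AlignmentShapeError(
                f"{path}: aligned FASTA rows have mixed lengths {sorted(widths)}"
            )
    return records


def write_sequences(path: str | Path, records: Iterable[SeqRecord],
                    format: Format) -> None:
    """Write records as FASTA / FASTQ / aligned FASTA (FASTQ requires qualities)."""
    if format not in ("fasta", "fastq", "aligned_fasta"):
        raise ValueError(f"unknown format {format!r}")
    bio_fmt = "fastq" if format == "fastq" else "fasta"
    bio_records = []
    for rec in records:
        bio = BioSeqRecord(Seq(rec.seq), id=rec.id, description="")
        if format == "fastq":
            if rec.qual is None:
                raise ValidationError(f"record {rec.id!r} has no qualities")
            bio.letter_annotations["phred_quality"] = rec.qual
        bio_records.append(bio)
    with _open_text(path, "wt") as handle:
        SeqIO.write(bio_records, handle, bio_fmt)


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return df


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a ``sample_id <tab> label`` TSV into a validated :class:`SampleSheet`."""
    df = _read_tsv(path, ["sample_id", "label"])
    entries: dict[str, str] = {}
    for _, row in df.iterrows():
        sample = str(row["sample_id"])
        if sample in entries:
            raise ValidationError(f"{path}: duplicate sample_id {sample!r}")
        entries[sample] = str(row["label"])
    return SampleSheet(entries)


def read_primer_table(path: str | Path) -> PrimerTable:
    """Read a ``gene, fwd_primer, rev_primer, min_len, max_len`` TSV."""
    df = _read_tsv(path, ["gene", "fwd_primer", "rev_primer", "min_len", "max_len"])
    genes: dict[str, PrimerSpec] = {}
    for _, row in df.iterrows():
        gene = str(row["gene"])
        if gene in genes:
            raise ValidationError(f"{path}: duplicate gene {gene!r}")
        try:
            lo, hi = int(row["min_len"]), int(row["max_len"])
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer length for {gene!r}") from exc
        genes[gene] = PrimerSpec(str(row["fwd_primer"]).upper(),
                                 str(row["rev_primer"]).upper(), lo, hi)
    return PrimerTable(genes)


def write_sample_sheet(path: str | Path, sheet: SampleSheet) -> None:
    pd.DataFrame(
        {"sample_id": list(sheet.entries), "label": list(sheet.entries.values())}
    ).to_csv(path, sep="\t", index=False)


def write_primer_table(path: str | Path, table: PrimerTable) -> None:
    rows = [
        {"gene": g, "fwd_primer": s.fwd, "rev_primer": s.rev,
         "min_len": s.min_len, "max_len": s.max_len}
        for g, s in table
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
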