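"""Demultiplex merged amplicon reads by sample label + introducer + gene primer.

Every read carries the construct ``label + introducer + forward primer +
insert + revcomp(reverse primer) + revcomp(introducer) + revcomp(label)``
(the 3' copy may be truncated by the read end).  Assignment tries the forward
orientation first and the reverse complement second; the artificial regions
are trimmed off and the insert is length-filtered.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .io_formats import PrimerTable, SampleSheet, SeqRecord
from .oligo import INTRODUCER, IUPAC_SETS, iupac_mismatches, revcomp

UnassignedReason = Literal[
    "no_label", "no_primer", "ambiguous_label", "ambiguous_gene", "too_short"
]


@dataclass(frozen=True)
class DemuxParams:
    """Tolerances for label / introducer / primer matching and the length filter.

    Labels are matched exactly by default: the label set carries no stated
    error-correction distance, so mismatch tolerance is opt-in.  ``min_len``
    applies to the trimmed insert.
    """

    label_len: int = 10
    introducer: str = INTRODUCER
    label_max_mismatch: int = 0
    introducer_max_mismatch: int = 1
    primer_max_mismatch: int = 2
    min_len: int = 200
    require_both_ends: bool = False

    def __post_init__(self) -> None:
        if min(self.label_max_mismatch, self.introducer_max_mismatch,
               self.primer_max_mismatch) < 0:
            raise ValueError("mismatch allowances must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass
class DemuxedRead:
    """A read assigned to (sample, gene), artificial regions trimmed off."""

    sample_id: str
    gene: str
    insert: SeqRecord
    orientation: Literal["forward", "reverse"]
    label_mismatches: int
    primer_mismatches: int


@dataclass(frozen=True)
class Unassigned:
    read_id: str
    reason: UnassignedReason


def _match_label(prefix: str, sheet: SampleSheet, max_mm: int):
    """Best label for a read prefix: (sample, mismatches) or reason string."""
    by_label = sheet.by_label
    if prefix in by_label:  # exact match has priority
        return by_label[prefix], 0
    if max_mm == 0:
        return "no_label", None
    scored = []
    for label, sample in by_label.items():
        mm = sum(a != b for a, b in zip(label, prefix))
        if mm <= max_mm:
            scored.append((mm, sample))
    if not scored:
        return "no_label", None
    scored.sort(key=lambda t: t[0])
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        return "ambiguous_label", None
    return scored[0][1], scored[0][0]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_tail_anchor(seq: str, anchor: str, start: int, max_mm: int) -> int:
    """Rightmost position of ``anchor`` in ``seq[start:]`` within ``max_mm``; -1 if absent."""
    pos = seq.rfind(anchor, start)
    if pos >= 0:
        return pos
    if max_mm == 0 or len(seq) - start < len(anchor):
        return -1
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pat = np.frombuffer(anchor.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, len(pat))
    mism = np.count_nonzero(windows != pat, axis=1)
    hits = np.nonzero(mism[start:] <= max_mm)[0]
    return int(hits[-1]) + start if hits.size else -1


# how far an attempt progressed before failing; ties between orientations go
# to the more advanced attempt (forward wins exact ties)
_STAGE = {"no_label": 0, "ambiguous_label": 0,
          "no_primer": 1, "ambiguous_gene": 1, "too_short": 2}


def _attempt(read: SeqRecord, seq: str,
             orientation: Literal["forward", "reverse"],
             sheet: SampleSheet, primers: PrimerTable,
             params: DemuxParams) -> DemuxedRead | str:
    """One full assignment attempt on ``seq``; a reason string on failure."""
    L, ilen = params.label_len, len(params.introducer)
    if len(seq) <= L + ilen:
        return "no_label"
    outcome = _match_label(seq[:L], sheet, params.label_max_mismatch)
    if outcome[1] is None:
        return outcome[0]
    sample, label_mm = outcome
    if _hamming(seq[L:L + ilen], params.introducer) > params.introducer_max_mismatch:
        return "no_label"

    pos = L + ilen
    best: list[tuple[int, str]] = []
    for gene, spec in primers:
        if pos + len(spec.fwd) > len(seq):
            continue
        mm = iupac_mismatches(spec.fwd, seq[pos:pos + len(spec.fwd)])
        if mm <= params.primer_max_mismatch:
            best.append((mm, gene))
    if not best:
        return "no_primer"
    best.sort(key=lambda t: t[0])
    if len(best) > 1 and best[0][0] == best[1][0]:
        return "ambiguous_gene"
    primer_mm, gene = best[0]
    spec = primers.genes[gene]
    insert_start = pos + len(spec.fwd)

    anchor_pos = _find_tail_anchor(seq, revcomp(params.introducer), insert_start,
                                   params.introducer_max_mismatch)
    if anchor_pos >= 0:
        insert_end = max(insert_start, anchor_pos - len(spec.rev))
    elif params.require_both_ends:
        return "no_label"
    else:
        insert_end = len(seq)  # read-through truncation: keep to the read end

    insert_seq = seq[insert_start:insert_end]
    if len(insert_seq) < params.min_len:
        return "too_short"
    if read.qual is not None:
        qual = read.qual if orientation == "forward" else read.qual[::-1]
        qual = qual[insert_start:insert_end]
    else:
        qual = None
    insert = SeqRecord(read.id, insert_seq, qual)
    return DemuxedRead(sample, gene, insert, orientation, label_mm, primer_mm)


def assign_read(read: SeqRecord, sheet: SampleSheet, primers: PrimerTable,
                params: DemuxParams = DemuxParams()) -> DemuxedRead | Unassigned:
    """Assign one merged read to (sample, gene) and trim the artificial regions.

    The forward orientation is tried first, then the reverse complement: an
    orientation assigns when its 5' prefix matches some label (exact match has
    priority) followed by the introducer, and a forward primer follows within
    the mismatch tolerance; the 3' construct, when locatable by its
    reverse-complemented introducer, is trimmed together with the reverse
    primer, otherwise the read is kept to its end.  Failures return an
    :class:`Unassigned` with one of the reasons
    ``no_label / no_primer / ambiguous_label / ambiguous_gene / too_short``,
    from whichever orientation progressed further.
    """
    fwd = _attempt(read, read.seq, "forward", sheet, primers, params)
    if isinstance(fwd, DemuxedRead):
        return fwd
    rev = _attempt(read, revcomp(read.seq), "reverse", sheet, primers, params)
    if isinstance(rev, DemuxedRead):
        return rev
    reason = fwd if _STAGE[fwd] >= _STAGE[rev] else rev
    return Unassigned(read.id, reason)  # type: ignore[arg-type]


@dataclass
class DemuxResult:
    """Per-(sample, gene) read bins plus unassigned reads and a summary table."""

    bins: dict[tuple[str, str], list[DemuxedRead]]
    unassigned: dict[str, list[Unassigned]]
    summary: pd.DataFrame  # columns: sample, gene, reads, percent (of total input)

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.bins.values())

    @property
    def n_unassigned(self) -> int:
        return sum(len(v) for v in self.unassigned.values())


def demultiplex_run(reads: Iterable[SeqRecord], sheet: SampleSheet,
                    primers: PrimerTable,
                    params: DemuxParams = DemuxParams()) -> DemuxResult:
    """Demultiplex a whole run; every read lands in exactly one bin or one
    unassigned category.  The summary has one row per (sample, gene) with the
    read count and its percentage of the total input."""
    bins: dict[tuple[str, str], list[DemuxedRead]] = defaultdict(list)
    unassigned: dict[str, list[Unassigned]] = defaultdict(list)
    total = 0
    for read in reads:
        total += 1
        outcome = assign_read(read, sheet, primers, params)
        if isinstance(outcome, DemuxedRead):
            bins[(outcome.sample_id, outcome.gene)].append(outcome)
        else:
            unassigned[outcome.reason].append(outcome)
    rows = []
    for sample in sheet.entries:
        for gene, _ in primers:
            n = len(bins.get((sample, gene), []))
            rows.append({"sample": sample, "gene": gene, "reads": n,
                         "percent": 100.0 * n / total if total else 0.0})
    summary = pd.DataFrame(rows, columns=["sample", "gene", "reads", "percent"])
    return DemuxResult(dict(bins), dict(unassigned), summary)
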