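"""Merge paired-end reads into single amplicon sequences by 3'-overlap.

Candidate overlaps are ungapped alignments of read 1's suffix against the
reverse complement of read 2's prefix; the overlap minimising the mismatch
ratio (ties broken toward the longest overlap) is accepted when its ratio is
at or below ``max_mismatch_ratio`` and its length at least ``min_overlap``.
Within the overlap, disagreeing bases take the higher-quality call (and its
quality); agreeing bases keep the higher of the two qualities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io_formats import SeqRecord
from .oligo import revcomp

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_RATIO = 0.25


@dataclass(frozen=True)
class MergeFailure:
    """A read pair with no acceptable overlap (reported, not raised)."""

    r1_id: str
    reason: str = "no_overlap"

    def __bool__(self) -> bool:
        return False


def merge_pair(r1: SeqRecord, r2: SeqRecord,
               min_overlap: int = DEFAULT_MIN_OVERLAP,
               max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
               ) -> SeqRecord | MergeFailure:
    """Merge one read pair, or return a :class:`MergeFailure`.

    Both reads must carry quality scores.  The merged record has length
    ``len(r1) + len(r2) - overlap_len``.
    """
    if r1.qual is None or r2.qual is None:
        raise ValueError("merge_pair requires quality scores on both reads")
    rc_seq = revcomp(r2.seq)
    rc_qual = r2.qual[::-1]

    a = np.frombuffer(r1.seq.encode(), dtype=np.uint8)
    b = np.frombuffer(rc_seq.encode(), dtype=np.uint8)
    qa = np.asarray(r1.qual, dtype=np.int32)
    qb = np.asarray(rc_qual, dtype=np.int32)

    max_len = min(len(a), len(b))
    best_mm = -1
    best_len = 0
    for length in range(min_overlap, max_len + 1):
        mm = int(np.count_nonzero(a[len(a) - length:] != b[:length]))
        if best_len == 0 or mm * best_len < best_mm * length:
            best_mm, best_len = mm, length
        elif mm * best_len == best_mm * length and length > best_len:
            best_mm, best_len = mm, length
    if best_len == 0 or best_mm > max_mismatch_ratio * best_len:
        return MergeFailure(r1.id)

    off = len(a) - best_len
    ov_a, ov_b = a[off:], b[:best_len]
    ov_qa, ov_qb = qa[off:], qb[:best_len]
    take_b = (ov_a != ov_b) & (ov_qb > ov_qa)  # disagreements: higher quality wins, tie -> r1
    ov_seq = np.where(take_b, ov_b, ov_a)
    ov_qual = np.where(ov_a == ov_b, np.maximum(ov_qa, ov_qb),
                       np.where(take_b, ov_qb, ov_qa))

    seq = r1.seq[:off] + ov_seq.tobytes().decode() + rc_seq[best_len:]
    qual = list(r1.qual[:off]) + ov_qual.tolist() + rc_qual[best_len:]
    merged_id = r1.id.rsplit("/", 1)[0]
    return SeqRecord(merged_id, seq, qual)


def merge_pairs(pairs: Iterable[tuple[SeqRecord, SeqRecord]],
                min_overlap: int = DEFAULT_MIN_OVERLAP,
                max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
                ) -> tuple[list[SeqRecord], list[tuple[SeqRecord, SeqRecord]]]:
    """Merge many pairs; returns (merged records, unmerged pairs)."""
    merged: list[SeqRecord] = []
    unmerged: list[tuple[SeqRecord, SeqRecord]] = []
    for r1, r2 in pairs:
        result = merge_pair(r1, r2, min_overlap, max_mismatch_ratio)
        if isinstance(result, MergeFailure):
            unmerged.append((r1, r2))
        else:
            merged.append(result)
    return merged, unmerged
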