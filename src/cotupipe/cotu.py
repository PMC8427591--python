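"""Majority-rule consensus with noise removal, core-range detection and
thresholded end extension (the Cotu consensus method).

A plain majority-rule consensus of an amplicon alignment suffers at the
alignment ends, where quality trimming leaves only a fraction of the reads:
requiring a strict majority of *all* reads truncates the sequence.  The Cotu
rule instead detects a well-covered core by a sliding coverage window and
treats the two flanks differently:

* inside the core, a column whose gaps outnumber its bases is an insertion
  introduced by occasional reads and is dropped;
* outside the core, a column is kept (and called by majority) as long as its
  base count reaches a small end threshold (20% of the reads by default),
  which extends the consensus into the sparsely covered ends;
* everywhere, bases making up less than a noise fraction (10%) of the bases
  observed at a column are removed before the majority rule is applied.

Ties between bases are emitted as IUPAC ambiguity codes; a gap-vs-base tie
inside the core keeps the base (favouring sequence length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import InsufficientDepthError, NoCoreError
from .io_formats import SeqRecord
from .oligo import ambiguity_code
from .readgroup import Alignment, Cluster, ClusterParams, center_star_align, greedy_cluster

_BASES = "ACGT"


@dataclass(frozen=True)
class CotuParams:
    """Consensus-calling parameters.

    noise_fraction
        Bases below this fraction of a column's observed bases are removed
        before the majority rule.
    end_threshold
        Minimum coverage (fraction of reads) for a column outside the core to
        be called instead of dropped; this is what extends the sequence ends.
    core_window, core_fraction
        The core starts/ends at the first window of ``core_window`` consecutive
        columns, from either end, each covered by more than ``core_fraction``
        of the reads.
    min_depth
        Alignments with fewer reads produce no consensus.
    max_reads
        Depth cap: only the first ``max_reads`` alignment rows are used.
    ambiguity_fraction
        Optional: when set, a runner-up base reaching this fraction of the
        column's bases turns the call into a two-base ambiguity code.
    """

    noise_fraction: float = 0.10
    end_threshold: float = 0.20
    core_window: int = 3
    core_fraction: float = 0.50
    min_depth: int = 10
    max_reads: int = 500
    ambiguity_fraction: float | None = None

    def __post_init__(self) -> None:
        for name in ("noise_fraction", "end_threshold", "core_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.core_window < 1 or self.min_depth < 1:
            raise ValueError("core_window and min_depth must be >= 1")
        if self.max_reads < self.min_depth:
            raise ValueError("max_reads must be >= min_depth")
        if self.ambiguity_fraction is not None and not 0.0 < self.ambiguity_fraction < 1.0:
            raise ValueError("ambiguity_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ColumnProfile:
    """Symbol counts of one alignment column."""

    position: int
    counts: dict[str, int]  # keys: A, C, G, T, other, gap
    n_reads: int

    @property
    def coverage(self) -> int:
        """Number of non-gap symbols (the "bases" of the column)."""
        return self.n_reads - self.counts["gap"]


@dataclass(frozen=True)
class CoreRange:
    start: int  # inclusive, 0-based
    end: int    # inclusive


@dataclass(frozen=True)
class Call:
    kind: Literal["base", "drop_insertion", "drop_end"]
    base: str | None = None
    support: float | None = None


@dataclass
class ConsensusResult:
    seq: SeqRecord
    support: list[float]
    depth_used: int
    core: CoreRange
    dropped_insertion_columns: int
    dropped_end_columns: int


def column_profiles(alignment: Alignment) -> list[ColumnProfile]:
    """Per-column symbol counts, computed vectorised over the whole alignment."""
    if alignment.n_reads == 0:
        raise ValueError("empty alignment")
    arr = np.frombuffer("".join(alignment.rows).encode(), dtype=np.uint8)
    arr = arr.reshape(alignment.n_reads, alignment.width)
    profiles = []
    base_counts = {b: np.count_nonzero(arr == ord(b), axis=0) for b in _BASES}
    gap_counts = np.count_nonzero(arr == ord("-"), axis=0)
    for j in range(alignment.width):
        counts = {b: int(base_counts[b][j]) for b in _BASES}
        counts["gap"] = int(gap_counts[j])
        counts["other"] = alignment.n_reads - sum(counts.values())
        profiles.append(ColumnProfile(j, counts, alignment.n_reads))
    return profiles


def find_core_range(alignment: Alignment,
                    params: CotuParams = CotuParams(),
                    profiles: Sequence[ColumnProfile] | None = None) -> CoreRange:
    """First window of ``core_window`` consecutive columns, from each end, with
    coverage strictly above ``core_fraction`` of the reads.

    The core starts at the leftmost such window and ends at the rightmost
    column of the rightmost such window; raises :class:`NoCoreError` when no
    window qualifies.
    """
    if profiles is None:
        profiles = column_profiles(alignment)
    n = alignment.n_reads
    w = params.core_window
    ok = np.array([p.coverage > params.core_fraction * n for p in profiles])
    if len(ok) < w:
        raise NoCoreError(f"alignment width {len(ok)} shorter than core window {w}")
    runs = np.convolve(ok.astype(int), np.ones(w, dtype=int), mode="valid") == w
    hits = np.nonzero(runs)[0]
    if not hits.size:
        raise NoCoreError("no run of well-covered columns; consensus impossible")
    return CoreRange(int(hits[0]), int(hits[-1]) + w - 1)


def call_column(profile: ColumnProfile, in_core: bool,
                params: CotuParams = CotuParams()) -> Call:
    """Call one column by the majority rule with noise removal.

    Outside the core, columns with coverage below ``end_threshold x n_reads``
    are dropped as incorrect insertions; at or above it the column is normal
    and the majority rule applies.  Inside the core, a column whose gaps
    strictly outnumber its bases is dropped (a gap-vs-base tie keeps the
    base).  Bases below ``noise_fraction`` of the column's bases are removed
    before majority; ties between surviving bases yield the IUPAC code of the
    tied set.
    """
    if profile.n_reads <= 0:
        raise ValueError("empty column profile")
    cov = profile.coverage
    if not in_core:
        if cov < params.end_threshold * profile.n_reads:
            return Call("drop_end")
    else:
        if profile.counts["gap"] > cov:
            return Call("drop_insertion")
    kept = {b: c for b, c in ((b, profile.counts[b]) for b in _BASES)
            if c > 0 and c >= params.noise_fraction * cov}
    if not kept:
        return Call("drop_insertion" if in_core else "drop_end")
    top = max(kept.values())
    winners = frozenset(b for b, c in kept.items() if c == top)
    if len(winners) == 1 and params.ambiguity_fraction is not None:
        cutoff = params.ambiguity_fraction * cov
        winners = frozenset(b for b, c in kept.items()
                            if c == top or c >= cutoff)
    called = ambiguity_code(winners)
    support = sum(kept[b] for b in winners) / cov
    return Call("base", called, support)


def cotu_consensus(alignment: Alignment,
                   params: CotuParams = CotuParams(),
                   seq_id: str = "consensus") -> ConsensusResult:
    """Consensus of one alignment under the Cotu rules.

    Rows beyond ``max_reads`` are discarded first (depth cap, first rows in
    input order); fewer than ``min_depth`` remaining rows raise
    :class:`InsufficientDepthError`; an alignment without a well-covered core
    raises :class:`NoCoreError`.  The emitted sequence contains no gaps and
    carries one support value (fraction of the column's bases agreeing with
    the call) per emitted position.
    """
    rows = alignment.rows[:params.max_reads]
    ids = alignment.ids[:params.max_reads]
    capped = Alignment(ids, rows)
    if capped.n_reads < params.min_depth:
        raise InsufficientDepthError(
            f"{capped.n_reads} reads < min_depth {params.min_depth}"
        )
    profiles = column_profiles(capped)
    core = find_core_range(capped, params, profiles)
    seq_chars: list[str] = []
    support: list[float] = []
    dropped_ins = dropped_end = 0
    for profile in profiles:
        in_core = core.start <= profile.position <= core.end
        call = call_column(profile, in_core, params)
        if call.kind == "base":
            seq_chars.append(call.base)  # type: ignore[arg-type]
            support.append(call.support)  # type: ignore[arg-type]
        elif call.kind == "drop_insertion":
            dropped_ins += 1
        else:
            dropped_end += 1
    return ConsensusResult(
        seq=SeqRecord(seq_id, "".join(seq_chars)),
        support=support,
        depth_used=capped.n_reads,
        core=core,
        dropped_insertion_columns=dropped_ins,
        dropped_end_columns=dropped_end,
    )


@dataclass
class PipelineOutput:
    """Per-cluster consensus results of one (sample, gene) bin, largest first,
    plus the sizes of clusters skipped for insufficient depth."""

    results: list[ConsensusResult]
    skipped: list[int]


def cotu_pipeline(reads: Sequence[SeqRecord],
                  cluster_params: ClusterParams = ClusterParams(),
                  cotu_params: CotuParams = CotuParams(),
                  seq_id: str = "consensus") -> PipelineOutput:
    """Cluster one (sample, gene) bin, align each cluster, call its consensus.

    Clusters below ``min_depth`` are reported skipped; an empty result simply
    means no cluster was deep enough.
    """
    if not reads:
        raise ValueError("cotu_pipeline needs at least one read")
    clusters = greedy_cluster(reads, cluster_params)
    results: list[ConsensusResult] = []
    skipped: list[int] = []
    for k, cluster in enumerate(clusters):
        if cluster.size < cotu_params.min_depth:
            skipped.append(cluster.size)
            continue
        members = cluster.members[:cotu_params.max_reads]
        alignment = center_star_align(members)
        name = seq_id if len(clusters) == 1 else f"{seq_id}_c{k + 1}"
        results.append(cotu_consensus(alignment, cotu_params, seq_id=name))
    return PipelineOutput(results, skipped)
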