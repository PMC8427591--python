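"""Group reads into putative gene copies / species and align each group.

Clustering is greedy centroid clustering at an identity threshold (0.97 for
ITS-class markers, 0.99 for the less variable plastid markers); the multiple
alignment of a group is a center-star alignment, adequate for near-identical
amplicon reads.  Pairwise identity and the star alignment both use global
end-to-end alignment with affine gap penalties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
from Bio import Align

from .errors import AlignmentShapeError
from .io_formats import SeqRecord

#: Identity thresholds for greedy clustering by marker class.
ITS_IDENTITY = 0.97
PLASTID_IDENTITY = 0.99

# Alignment scoring used throughout (documented constants; end-to-end, affine).
MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1


@dataclass(frozen=True)
class ClusterParams:
    """Greedy-clustering parameters; ``identity_threshold`` in (0, 1]."""

    identity_threshold: float = ITS_IDENTITY

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass
class Cluster:
    centroid: SeqRecord
    members: list[SeqRecord]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Alignment:
    """Equal-length gapped rows; ungapping row i reproduces member i exactly."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise AlignmentShapeError(
                f"rows have mixed lengths {sorted({len(r) for r in self.rows})}"
            )

    @property
    def n_reads(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = make_aligner()


def global_align(a: str, b: str) -> tuple[str, str]:
    """Deterministic global affine alignment; returns the two gapped rows."""
    aln = _ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(a: SeqRecord | str, b: SeqRecord | str) -> float:
    """Matches / alignment columns of the global alignment (gap columns count
    as mismatch); symmetric for practical purposes and 1.0 for identical input."""
    sa = a.seq if isinstance(a, SeqRecord) else a
    sb = b.seq if isinstance(b, SeqRecord) else b
    if not sa or not sb:
        raise ValueError("pairwise_identity of an empty sequence is undefined")
    if sa == sb:
        return 1.0
    ra, rb = global_align(sa, sb)
    matches = sum(x == y and x != "-" for x, y in zip(ra, rb))
    return matches / len(ra)


def greedy_cluster(reads: Sequence[SeqRecord],
                   params: ClusterParams = ClusterParams()) -> list[Cluster]:
    """Greedy centroid clustering.

    Reads are processed in decreasing length (ties: input order); each read
    joins the first existing centroid at or above the identity threshold, else
    founds a new cluster.  Clusters are returned by decreasing size (ties:
    founding order), so the result is fully deterministic.
    """
    order = sorted(range(len(reads)), key=lambda i: (-len(reads[i].seq), i))
    clusters: list[Cluster] = []
    for i in order:
        read = reads[i]
        for cluster in clusters:
            if pairwise_identity(read, cluster.centroid) >= params.identity_threshold:
                cluster.members.append(read)
                break
        else:
            clusters.append(Cluster(read, [read]))
    order = sorted(range(len(clusters)), key=lambda k: (-clusters[k].size, k))
    return [clusters[k] for k in order]


def _edit_identity(a: str, b: str) -> float:
    """Fast identity proxy (1 - edit distance / longer length) for center scoring."""
    if a == b:
        return 1.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _pairwise_pieces(center: str, member: str) -> tuple[list[str], list[str]]:
    """Decompose a center-vs-member alignment into per-center-position pieces.

    Returns (inserts, aligned): ``inserts[k]`` holds member characters falling
    between center positions k-1 and k (k = 0..len(center)), ``aligned[k]``
    the member character (or '-') opposite center position k.
    """
    c_row, m_row = global_align(center, member)
    inserts = [""] * (len(center) + 1)
    aligned = [""] * len(center)
    k = 0
    for c, m in zip(c_row, m_row):
        if c == "-":
            inserts[k] += m
        else:
            aligned[k] = m
            k += 1
    return inserts, aligned


def center_star_align(members: Sequence[SeqRecord]) -> Alignment:
    """Star multiple alignment around the most central read.

    The center is the member with maximal summed identity to all others (ties
    go to the first in input order; the O(n^2) scoring uses a fast edit-distance
    identity, equivalent for the near-identical reads this is applied to).
    Each member is aligned to the center by global affine alignment and the
    pairwise alignments are merged by the once-a-gap-always-a-gap rule.
    """
    if not members:
        raise ValueError("center_star_align needs at least one member")
    if len(members) == 1:
        return Alignment([members[0].id], [members[0].seq])

    n = len(members)
    scores = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            s = _edit_identity(members[i].seq, members[j].seq)
            scores[i] += s
            scores[j] += s
    center_idx = max(range(n), key=lambda i: (scores[i], -i))
    center = members[center_idx].seq

    all_inserts: list[list[str]] = []
    all_aligned: list[list[str]] = []
    for member in members:
        if member is members[center_idx]:
            all_inserts.append([""] * (len(center) + 1))
            all_aligned.append(list(center))
        else:
            ins, aln = _pairwise_pieces(center, member.seq)
            all_inserts.append(ins)
            all_aligned.append(aln)

    ins_width = [max(len(ins[k]) for ins in all_inserts)
                 for k in range(len(center) + 1)]
    rows = []
    for ins, aln in zip(all_inserts, all_aligned):
        parts = []
        for k in range(len(center)):
            parts.append(ins[k].ljust(ins_width[k], "-"))
            parts.append(aln[k])
        parts.append(ins[len(center)].ljust(ins_width[len(center)], "-"))
        rows.append("".join(parts))
    return Alignment([m.id for m in members], rows)
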