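"""Evaluation computations: K2P distance, per-site error profiling, run summaries.

The Kimura two-parameter model separates transition and transversion rates;
its distance is ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` where P and Q are
the transition and transversion proportions over the compared sites.  Sites
where either sequence carries anything but a literal A/C/G/T (ambiguity codes,
gaps) are ignored pairwise, the convention of the standard distance software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cotu import ConsensusResult
from .errors import SaturatedDistanceError
from .io_formats import SeqRecord
from .readgroup import Alignment, global_align

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass(frozen=True)
class K2PResult:
    P: float      # transition proportion
    Q: float      # transversion proportion
    d: float      # K2P distance
    sites: int    # compared (unambiguous, ungapped) sites


def k2p_distance(a: SeqRecord | str, b: SeqRecord | str,
                 aligned: bool = False) -> K2PResult:
    """Kimura two-parameter distance between two sequences.

    With ``aligned=True`` the inputs must be equal-length gapped rows; else a
    global alignment is computed first.  Raises on zero comparable sites and
    on saturated distances (non-positive log arguments).
    """
    sa = a.seq if isinstance(a, SeqRecord) else a
    sb = b.seq if isinstance(b, SeqRecord) else b
    if aligned:
        if len(sa) != len(sb):
            raise ValueError("aligned sequences must have equal length")
        ra, rb = sa.upper(), sb.upper()
    else:
        ra, rb = global_align(sa.upper().replace("-", ""),
                              sb.upper().replace("-", ""))
    sites = transitions = transversions = 0
    for x, y in zip(ra, rb):
        if x not in "ACGT" or y not in "ACGT":
            continue  # ambiguous or gapped site: ignored pairwise
        sites += 1
        if x != y:
            if frozenset((x, y)) in _TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    if sites == 0:
        raise ValueError("no comparable sites (all ambiguous or gapped)")
    P = transitions / sites
    Q = transversions / sites
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        raise SaturatedDistanceError(
            f"saturated distance: P={P:.4f}, Q={Q:.4f}"
        )
    d = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    return K2PResult(P, Q, d, sites)


@dataclass
class SiteErrorProfile:
    """Base-frequency spectrum of mapped reads at every reference position.

    ``frequencies`` has one row per reference (non-gap) position with columns
    A, C, G, T, other, gap summing to 1 over the reads; ``match_rank`` is 1
    when the most frequent base equals the reference base, 2 when the second
    does, and so on — site-by-site comparison continues down the frequency
    ranking until an exact match is found, and ranks above 1 estimate
    sequencing error.
    """

    positions: list[int]          # 0-based reference coordinates
    frequencies: pd.DataFrame     # columns A, C, G, T, other, gap
    match_rank: list[int]
    reference: str

    @property
    def accuracy(self) -> float:
        """Fraction of reference positions whose top-ranked base matches."""
        return float(np.mean([r == 1 for r in self.match_rank]))


def site_error_profile(alignment: Alignment, reference_id: str) -> SiteErrorProfile:
    """Profile read-base frequencies against the reference row of an alignment."""
    if reference_id not in alignment.ids:
        raise ValueError(f"reference {reference_id!r} not present in alignment")
    ref_idx = alignment.ids.index(reference_id)
    ref_row = alignment.rows[ref_idx]
    read_rows = [r for i, r in enumerate(alignment.rows) if i != ref_idx]
    if not read_rows:
        raise ValueError("no reads to profile against the reference")
    n = len(read_rows)
    positions: list[int] = []
    freq_rows: list[dict[str, float]] = []
    ranks: list[int] = []
    ref_pos = -1
    for j, ref_char in enumerate(ref_row):
        if ref_char == "-":
            continue
        ref_pos += 1
        counts = {"A": 0, "C": 0, "G": 0, "T": 0, "other": 0, "gap": 0}
        for row in read_rows:
            c = row[j]
            if c in "ACGT":
                counts[c] += 1
            elif c == "-":
                counts["gap"] += 1
            else:
                counts["other"] += 1
        positions.append(ref_pos)
        freq_rows.append({k: v / n for k, v in counts.items()})
        ref_count = counts.get(ref_char, 0)
        rank = 1 + sum(counts[b] > ref_count for b in "ACGT")
        ranks.append(rank)
    ref_seq = ref_row.replace("-", "")
    return SiteErrorProfile(positions, pd.DataFrame(freq_rows), ranks, ref_seq)


@dataclass
class RunSummary:
    """Recovery / length / depth summaries of one pipeline run."""

    recovery: pd.DataFrame       # gene, created, samples, recovery_percent
    lengths: pd.DataFrame        # gene, n, mean_len, sd_len
    depth_percent: pd.DataFrame  # sample, gene, reads, percent (of the gene total)


def recovery_percent(created: int, samples: int) -> float:
    """Sequences created as a percentage of samples with data, one decimal."""
    if samples <= 0:
        raise ValueError("sample count must be positive")
    return round(100.0 * created / samples, 1)


def summarize_run(consensus_sets: Mapping[tuple[str, str], Sequence[ConsensusResult]],
                  n_samples: int,
                  demux_summary: pd.DataFrame | None = None) -> RunSummary:
    """Summarise consensus output per gene: recovery, sequence length, depth share.

    ``consensus_sets`` maps (sample, gene) to that bin's consensus sequences;
    ``demux_summary`` is the per-(sample, gene) read-count table from
    demultiplexing, used for the relative-depth percentages (which sum to 100
    within each gene).
    """
    if n_samples <= 0:
        raise ValueError("sample count must be positive")
    genes = sorted({gene for (_, gene) in consensus_sets})
    rec_rows, len_rows = [], []
    for gene in genes:
        with_seq = [s for (s, g), res in consensus_sets.items()
                    if g == gene and len(res) > 0]
        lengths = [len(r.seq.seq) for (s, g), res in consensus_sets.items()
                   if g == gene for r in res]
        rec_rows.append({
            "gene": gene, "created": len(with_seq), "samples": n_samples,
            "recovery_percent": recovery_percent(len(with_seq), n_samples),
        })
        len_rows.append({
            "gene": gene, "n": len(lengths),
            "mean_len": float(np.mean(lengths)) if lengths else float("nan"),
            "sd_len": float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0,
        })
    if demux_summary is not None and len(demux_summary):
        dp = demux_summary[["sample", "gene", "reads"]].copy()
        totals = dp.groupby("gene")["reads"].transform("sum")
        dp["percent"] = np.where(totals > 0, 100.0 * dp["reads"] / totals, 0.0)
    else:
        dp = pd.DataFrame(columns=["sample", "gene", "reads", "percent"])
    return RunSummary(pd.DataFrame(rec_rows), pd.DataFrame(len_rows), dp)
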