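"""Synthetic multiplexed amplicon runs with ground truth.

Emulates a two-round labelling-PCR sequencing run: every amplicon carries the
construct ``label + introducer + forward primer + insert + revcomp(reverse
primer) + revcomp(introducer) + revcomp(label)`` and is sequenced as a
paired-end read pair with substitution errors, homopolymer-enriched indel
errors and linearly decaying base qualities.  Per-bin depths are drawn from a
lognormal to emulate the depth bias observed between samples on real runs.
A :class:`TruthManifest` records every true insert and every injected error so
downstream modules can be tested for exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .barcodes import PANEL
from .io_formats import (PrimerSpec, PrimerTable, SampleSheet, SeqRecord,
                         write_primer_table, write_sample_sheet, write_sequences)
from .oligo import INTRODUCER, IUPAC_SETS, revcomp
from .readgroup import Alignment, pairwise_identity

#: Default per-gene insert length ranges (between the primers).  Real runs see
#: mean read lengths around 62-93% of the nominal fragment length, so the
#: defaults sit at ~75-85% of the panel's expected lengths minus the primers;
#: this also guarantees that 250-nt read pairs overlap by >= ~30 nt.
DEFAULT_INSERT_RANGES: dict[str, tuple[int, int]] = {
    "ITS1": (280, 330),
    "ITS2": (330, 380),
    "matK1": (290, 340),
    "matK2": (320, 370),
    "rbcL1": (320, 370),
    "rbcL2": (330, 380),
}


@dataclass(frozen=True)
class GeneModel:
    name: str
    fwd: str
    rev: str
    insert_range: tuple[int, int]


def default_genes() -> list[GeneModel]:
    return [GeneModel(f.gene, f.fwd, f.rev, DEFAULT_INSERT_RANGES[f.gene])
            for f in PANEL]


@dataclass
class SimParams:
    """Study conditions of a simulated run.

    Rates are per base: 0.005 substitutions and 0.0005 indels, with indels
    10x more likely inside homopolymer runs of four or more (the
    semiconductor-platform error profile).  Qualities decay linearly from 38
    at the read start to 28 at the read end; per-bin depth is lognormal with
    median ``depth_mean`` and log-scale sigma ``depth_sigma``.
    """

    n_samples: int = 10
    genes: list[GeneModel] = field(default_factory=default_genes)
    depth_mean: float = 100.0
    depth_sigma: float = 0.5
    sub_rate: float = 0.005
    indel_rate: float = 0.0005
    homopolymer_indel_multiplier: float = 10.0
    homopolymer_min_run: int = 4
    qual_start: int = 38
    qual_end: int = 28
    read_len: int = 250
    label_len: int = 10
    label_min_dist: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sub_rate < 1.0 and 0.0 <= self.indel_rate < 1.0):
            raise ValueError("error rates must be in [0, 1)")
        if self.read_len < 50:
            raise ValueError("read_len must be >= 50")
        if self.n_samples < 1 or not self.genes:
            raise ValueError("need at least one sample and one gene")


@dataclass
class ManifestEntry:
    sample: str
    gene: str
    label: str
    insert: str
    depth: int
    read_errors: dict[str, list[tuple[int, str, str]]]  # read id -> (pos, kind, base)


@dataclass
class TruthManifest:
    """Ground truth of a simulated run: one entry per (sample, gene) bin."""

    entries: dict[tuple[str, str], ManifestEntry]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample": e.sample, "gene": e.gene, "label": e.label,
                 "depth": e.depth, "insert": e.insert,
                 "n_read_errors": sum(len(v) for v in e.read_errors.values())}
                for e in self.entries.values()]
        return pd.DataFrame(rows)


@dataclass
class SimRun:
    r1: list[SeqRecord]
    r2: list[SeqRecord]
    sheet: SampleSheet
    primers: PrimerTable
    manifest: TruthManifest

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sequences(outdir / "reads_R1.fastq", self.r1, "fastq")
        write_sequences(outdir / "reads_R2.fastq", self.r2, "fastq")
        write_sample_sheet(outdir / "samples.tsv", self.sheet)
        write_primer_table(outdir / "primers.tsv", self.primers)
        self.manifest.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def make_label_set(n: int, length: int = 10, min_dist: int = 3,
                   rng: np.random.Generator | None = None,
                   max_tries: int = 10_000) -> list[str]:
    """Random ACGT labels with minimum pairwise Hamming distance ``min_dist``."""
    if rng is None:
        rng = np.random.default_rng(0)
    labels: list[str] = []
    arrs: list[np.ndarray] = []
    tries = 0
    while len(labels) < n:
        cand = rng.integers(0, 4, length)
        if all(int(np.count_nonzero(cand != a)) >= min_dist for a in arrs):
            arrs.append(cand)
            labels.append("".join("ACGT"[c] for c in cand))
        tries += 1
        if tries > max_tries:
            raise ValueError(f"cannot place {n} labels at distance {min_dist}")
    return labels


def realize_primer(pattern: str, rng: np.random.Generator) -> str:
    """Resolve each degenerate position by uniform choice in its degeneracy set."""
    out = []
    for c in pattern:
        choices = sorted(IUPAC_SETS[c])
        out.append(choices[0] if len(choices) == 1
                   else choices[rng.integers(0, len(choices))])
    return "".join(out)


def _run_lengths(seq: str) -> np.ndarray:
    """Length of the homopolymer run containing each position."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if arr.size == 0:
        return np.zeros(0, dtype=np.int64)
    change = np.nonzero(np.diff(arr))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    out = np.empty(arr.size, dtype=np.int64)
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def inject_errors(seq: str, rng: np.random.Generator, sub_rate: float,
                  indel_rate: float, homopolymer_multiplier: float = 10.0,
                  homopolymer_min_run: int = 4,
                  ) -> tuple[str, list[tuple[int, str, str]]]:
    """Apply substitution / indel errors to one read template.

    Indels inside homopolymer runs of at least ``homopolymer_min_run`` bases
    are ``homopolymer_multiplier`` times more likely; insertions duplicate the
    local base (slippage).  Returns the mutated sequence and the error list as
    (template position, kind, base) with kind in {sub, ins, del}.
    """
    if sub_rate == 0.0 and indel_rate == 0.0:
        return seq, []
    L = len(seq)
    runs = _run_lengths(seq)
    p_ind = indel_rate * np.where(runs >= homopolymer_min_run,
                                  homopolymer_multiplier, 1.0)
    u = rng.random(L)
    hits = np.nonzero(u < sub_rate + p_ind)[0]
    parts: list[str] = []
    errors: list[tuple[int, str, str]] = []
    prev = 0
    for pos in hits:
        pos = int(pos)
        parts.append(seq[prev:pos])
        base = seq[pos]
        if u[pos] < sub_rate:
            new = "ACGT".replace(base, "")[rng.integers(0, 3)]
            parts.append(new)
            errors.append((pos, "sub", new))
        elif rng.random() < 0.5:
            parts.append(base + base)
            errors.append((pos, "ins", base))
        else:
            errors.append((pos, "del", base))
        prev = pos + 1
    parts.append(seq[prev:])
    return "".join(parts), errors


def _qualities(length: int, start: int, end: int) -> list[int]:
    if length == 0:
        return []
    if length == 1:
        return [start]
    return [round(start + (end - start) * i / (length - 1)) for i in range(length)]


def simulate_references(n: int, length_range: tuple[int, int],
                        pairwise_divergence: float = 0.0,
                        seed: int = 0, max_tries: int = 200) -> list[SeqRecord]:
    """Random insert sequences with at least the requested pairwise divergence."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    refs: list[SeqRecord] = []
    tries = 0
    while len(refs) < n:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        cand = SeqRecord(f"ref{len(refs) + 1}", _random_seq(rng, length))
        if all(pairwise_identity(cand, r) <= 1.0 - pairwise_divergence
               for r in refs):
            refs.append(cand)
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot reach pairwise divergence {pairwise_divergence}"
            )
    return refs


def simulate_run(params: SimParams = SimParams(),
                 sheet: SampleSheet | None = None,
                 primers: PrimerTable | None = None,
                 depth_override: dict[tuple[str, str], int] | None = None,
                 ) -> SimRun:
    """Simulate one multiplexed paired-end run (byte-identical under a fixed seed).

    ``depth_override`` pins the depth of selected (sample, gene) bins, e.g. to
    create a deliberately under-covered bin.
    """
    rng = np.random.default_rng(params.seed)
    if sheet is None:
        labels = make_label_set(params.n_samples, params.label_len,
                                params.label_min_dist, rng)
        sheet = SampleSheet({f"S{i + 1:03d}": lab for i, lab in enumerate(labels)})
    if len(sheet) < params.n_samples:
        raise ValueError("sample sheet smaller than n_samples")
    if primers is None:
        primers = PrimerTable({
            g.name: PrimerSpec(g.fwd, g.rev, g.insert_range[0], g.insert_range[1])
            for g in params.genes
        })
    min_construct = 2 * (params.label_len + len(INTRODUCER))
    for g in params.genes:
        if g.insert_range[0] + min_construct < 20:
            raise ValueError(f"gene {g.name}: construct too short to sequence")

    r1_out: list[SeqRecord] = []
    r2_out: list[SeqRecord] = []
    entries: dict[tuple[str, str], ManifestEntry] = {}
    samples = list(sheet.entries)[:params.n_samples]
    for sample in samples:
        label = sheet.entries[sample]
        for gene in params.genes:
            lo, hi = gene.insert_range
            insert = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            if depth_override and (sample, gene.name) in depth_override:
                depth = depth_override[(sample, gene.name)]
            else:
                depth = max(1, round(float(rng.lognormal(
                    np.log(params.depth_mean), params.depth_sigma))))
            read_errors: dict[str, list[tuple[int, str, str]]] = {}
            for i in range(depth):
                fwd = realize_primer(gene.fwd, rng)
                rev = realize_primer(gene.rev, rng)
                amplicon = (label + INTRODUCER + fwd + insert
                            + revcomp(rev) + revcomp(INTRODUCER) + revcomp(label))
                rid = f"{sample}|{gene.name}|{i}"
                t1 = amplicon[:params.read_len]
                t2 = revcomp(amplicon)[:params.read_len]
                s1, e1 = inject_errors(t1, rng, params.sub_rate, params.indel_rate,
                                       params.homopolymer_indel_multiplier,
                                       params.homopolymer_min_run)
                s2, e2 = inject_errors(t2, rng, params.sub_rate, params.indel_rate,
                                       params.homopolymer_indel_multiplier,
                                       params.homopolymer_min_run)
                r1_out.append(SeqRecord(rid, s1, _qualities(
                    len(s1), params.qual_start, params.qual_end)))
                r2_out.append(SeqRecord(rid, s2, _qualities(
                    len(s2), params.qual_start, params.qual_end)))
                errs = [(p, k, b) for p, k, b in e1] + \
                       [(p, k, b) for p, k, b in e2]
                if errs:
                    read_errors[rid] = errs
            entries[(sample, gene.name)] = ManifestEntry(
                sample, gene.name, label, insert, depth, read_errors)
    return SimRun(r1_out, r2_out, sheet, primers, TruthManifest(entries))


def simulate_ragged_alignment(rng: np.random.Generator, n_reads: int = 10,
                              core_len: int = 40, left_ext: int = 5,
                              right_ext: int = 5, left_cov: float = 0.3,
                              right_cov: float = 0.3,
                              ) -> tuple[Alignment, str]:
    """A ragged-end alignment: all reads cover the core, only a fraction extend
    into each flank (emulating quality-trimmed read ends).  Returns the
    alignment and the full truth sequence (flanks + core)."""
    truth = _random_seq(rng, left_ext + core_len + right_ext)
    n_left = round(left_cov * n_reads)
    n_right = round(right_cov * n_reads)
    rows = []
    for i in range(n_reads):
        left = truth[:left_ext] if i < n_left else "-" * left_ext
        right = truth[left_ext + core_len:] if i < n_right else "-" * right_ext
        rows.append(left + truth[left_ext:left_ext + core_len] + right)
    return Alignment([f"r{i}" for i in range(n_reads)], rows), truth
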