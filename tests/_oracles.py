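"""Independent brute-force re-implementations used as test oracles.

These recompute consensus calls directly from the rule definitions with plain
Python (collections.Counter, explicit loops), sharing no code with the
package's vectorised implementation.
"""

from collections import Counter

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W", frozenset("GT"): "K",
    frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


class NoCore(Exception):
    pass


def oracle_core_range(rows, core_window=3, core_fraction=0.5):
    """First window of consecutive well-covered columns from each end."""
    n, width = len(rows), len(rows[0])
    cov = [sum(r[j] != "-" for r in rows) for j in range(width)]
    ok = [c > core_fraction * n for c in cov]
    start = end = None
    for i in range(width - core_window + 1):
        if all(ok[i:i + core_window]):
            start = i
            break
    for j in range(width - 1, core_window - 2, -1):
        if all(ok[j - core_window + 1:j + 1]):
            end = j
            break
    if start is None or end is None:
        raise NoCore
    return start, end


def oracle_call(column, in_core, n_reads, noise_fraction=0.10,
                end_threshold=0.20):
    """One column call: a base/ambiguity character, or 'drop_insertion' /
    'drop_end'.  Columns contain only A/C/G/T/-."""
    gaps = column.count("-")
    cov = n_reads - gaps
    if not in_core and cov < end_threshold * n_reads:
        return "drop_end"
    if in_core and gaps > cov:
        return "drop_insertion"
    counts = Counter(c for c in column if c in "ACGT")
    kept = {b: c for b, c in counts.items() if c >= noise_fraction * cov}
    if not kept:
        return "drop_insertion" if in_core else "drop_end"
    top = max(kept.values())
    return _IUPAC[frozenset(b for b, c in kept.items() if c == top)]


def oracle_consensus(rows, core_window=3, core_fraction=0.5,
                     noise_fraction=0.10, end_threshold=0.20):
    """Full consensus: (sequence, core, dropped_insertion, dropped_end)."""
    n = len(rows)
    start, end = oracle_core_range(rows, core_window, core_fraction)
    seq = []
    dropped_ins = dropped_end = 0
    for j in range(len(rows[0])):
        column = [r[j] for r in rows]
        outcome = oracle_call(column, start <= j <= end, n,
                              noise_fraction, end_threshold)
        if outcome == "drop_insertion":
            dropped_ins += 1
        elif outcome == "drop_end":
            dropped_end += 1
        else:
            seq.append(outcome)
    return "".join(seq), (start, end), dropped_ins, dropped_end


def naive_consensus(rows):
    """Majority-rule consensus dropping every column covered by <= 50% of reads
    (the length baseline the thresholded end extension is compared against)."""
    n = len(rows)
    seq = []
    for j in range(len(rows[0])):
        column = [r[j] for r in rows]
        cov = sum(c != "-" for c in column)
        if cov <= 0.5 * n:
            continue
        counts = Counter(c for c in column if c in "ACGT")
        if counts:
            seq.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(seq)


def random_alignment(rng, max_rows=20, max_cols=50):
    """A random gapped alignment with ragged ends and scattered internal gaps."""
    n = int(rng.integers(1, max_rows + 1))
    width = int(rng.integers(3, max_cols + 1))
    rows = []
    for _ in range(n):
        lead = int(rng.integers(0, max(1, width // 3)))
        trail = int(rng.integers(0, max(1, width // 3)))
        chars = []
        for j in range(width):
            if j < lead or j >= width - trail or rng.random() < 0.08:
                chars.append("-")
            else:
                chars.append("ACGT"[rng.integers(0, 4)])
        rows.append("".join(chars))
    return rows
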