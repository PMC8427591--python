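"""IUPAC-aware oligo utilities.

Reverse complement, degenerate-code matching, GC content, and assembly of the
two-round labelling-PCR construct (sample label + introducer + gene primer)
used to multiplex many samples in one amplicon sequencing run.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AlphabetError

#: The fixed 14-nt oligo bridging the sample label and the gene primer in the
#: two-round labelling PCR.  It is appended to every first-round primer and
#: serves as the priming site for the labelled second-round primer.
INTRODUCER = "GTAGACTGCGTACC"

#: Degeneracy sets of the IUPAC nucleotide codes (T and U collapse to T).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse of :data:`IUPAC_SETS`: maps a set of literal bases to its code.
IUPAC_CODES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN-", "TGCAAYRSWMKVHDBN-")
_VALID = frozenset("ACGTURYSWKMBDHVN-")


def _check_alphabet(seq: str) -> str:
    up = seq.upper()
    bad = set(up) - _VALID
    if bad:
        raise AlphabetError(f"invalid nucleotide character(s): {sorted(bad)!r}")
    return up


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Degenerate codes map to the code of the complemented set (R<->Y, K<->M,
    S and W are self-complementary, B<->V, D<->H, N<->N); gaps are preserved.
    """
    return _check_alphabet(seq).translate(_COMPLEMENT)[::-1]


def iupac_mismatches(pattern: str, window: str) -> int:
    """Count positions of ``window`` not covered by ``pattern``'s degeneracy sets.

    ``pattern`` may contain degenerate IUPAC codes; ``window`` is an observed
    read region.  A window base mismatches unless it belongs to the degeneracy
    set of the corresponding pattern symbol, so N in the pattern matches
    everything while N in the window matches only an N/degenerate superset.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    p = _check_alphabet(pattern)
    w = _check_alphabet(window)
    return sum(b not in IUPAC_SETS.get(a, frozenset()) for a, b in zip(p, w))


def gc_percent(seq: str) -> float:
    """Percent of literal G and C in ``seq``, rounded to two decimals.

    Degenerate symbols (R, Y, W, S, K, M, N, ...) count as non-GC.  Applied to
    a full first-round oligo (introducer + primer) this is the GC convention
    used for the standard barcoding primer panel shipped with the package.
    """
    up = _check_alphabet(seq)
    if not up:
        raise ValueError("gc_percent of an empty sequence is undefined")
    gc = sum(c in "GC" for c in up)
    return round(100.0 * gc / len(up), 2)


def ambiguity_code(bases: frozenset[str] | set[str]) -> str:
    """IUPAC code for a set of literal A/C/G/T bases (single bases map to themselves)."""
    code = IUPAC_CODES.get(frozenset(bases))
    if code is None:
        raise ValueError(f"not a valid base set: {sorted(bases)!r}")
    return code


@dataclass(frozen=True)
class OligoConstruct:
    """A first- or second-round PCR oligo: ``label + introducer + primer``.

    The first-round oligo has an empty label (introducer + gene primer); the
    second-round labelling primer prepends the 10-nt sample label.
    """

    primer: str
    label: str = ""
    introducer: str = INTRODUCER

    def __post_init__(self) -> None:
        for part in (self.label, self.introducer, self.primer):
            _check_alphabet(part)

    @property
    def full(self) -> str:
        return (self.label + self.introducer + self.primer).upper()

    @property
    def gc_percent(self) -> float:
        return gc_percent(self.full)
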