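"""The standard six-fragment plant barcoding primer panel.

Conventional plant DNA barcodes (ITS, matK, rbcL) run 600-800 bp, longer than
one paired-end 250 read pair can span, so each barcode is amplified as two
overlapping ~400 bp fragments with universal middle primers.  The panel below
lists the six fragments with their first-round primer pairs and nominal
amplified fragment lengths (primers included).
"""

from __future__ import annotations

from dataclasses import dataclass

from .oligo import INTRODUCER, OligoConstruct


@dataclass(frozen=True)
class BarcodeFragment:
    gene: str
    fwd_name: str
    fwd: str
    rev_name: str
    rev: str
    expected_len: tuple[int, int]  # nominal amplified fragment length, primers included

    @property
    def fwd_oligo(self) -> OligoConstruct:
        """First-round forward oligo: introducer + forward primer."""
        return OligoConstruct(primer=self.fwd, introducer=INTRODUCER)

    @property
    def rev_oligo(self) -> OligoConstruct:
        return OligoConstruct(primer=self.rev, introducer=INTRODUCER)


#: Universal first-round primer panel for the six conventional barcode fragments.
PANEL: tuple[BarcodeFragment, ...] = (
    BarcodeFragment("ITS1", "ITS-P5", "CCTTATCAYTTAGAGGAAGGAG",
                    "ITS-U2", "GCGTTCAAAGAYTCGATGRTTC", (370, 380)),
    BarcodeFragment("ITS2", "ITS-P3", "YGACTCTCGGCAACGGATA",
                    "ITS-U4", "RGTTTCTTTTCCTCCGCTTA", (440, 450)),
    BarcodeFragment("matK1", "matK-472F", "CCCRTYCATCTGGAAATCTTGGTTC",
                    "matK-821R", "TTTCCTTGATATCTAACATAATG", (380, 390)),
    BarcodeFragment("matK2", "matK-821F", "CATTATGTTAGATATCAAGGAAA",
                    "matK-1248R", "GCTRTRATAATGAGAAAGATTTCTGC", (420, 430)),
    BarcodeFragment("rbcL1", "rbcLbF", "AGACCTWTTTGAAGAAGGTTCWGT",
                    "rbcL717R", "CATGTACCTGCAGTAGCATTCAAGT", (420, 430)),
    BarcodeFragment("rbcL2", "rbcL717F", "ACTTGAATGCTACTGCAGGTACATG",
                    "rbcLbR", "TCGGTYAGAGCRGGCATRTGCCA", (430, 440)),
)

PANEL_BY_GENE: dict[str, BarcodeFragment] = {f.gene: f for f in PANEL}
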