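"""Small nucleotide-string helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

#: IUPAC nucleotide code -> set of matching unambiguous bases
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_mismatches(pattern: str, text: str) -> int:
    """Number of positions of ``text`` not matched by the IUPAC ``pattern``.

    Both strings must have equal length; pattern characters may be
    degenerate codes, text characters are compared literally (a non-ACGT
    text character only matches when listed in the pattern's expansion).
    """
    if len(pattern) != len(text):
        raise ValueError("pattern/text length mismatch")
    mism = 0
    for p, t in zip(pattern, text):
        if t not in IUPAC.get(p, ()):
            mism += 1
    return mism


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def is_acgt(seq: str) -> bool:
    return not set(seq) - {"A", "C", "G", "T"}
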