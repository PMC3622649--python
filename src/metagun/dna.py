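"""Small DNA primitives shared across the package.

Sequences are plain upper-case Python strings over the alphabet {A,C,G,T,N}.
Coordinates are 0-based half-open on the strand under consideration; file
formats convert at the boundary (see :mod:`metagun.io`).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

#: the three canonical prokaryotic stop codons (translation table 11)
STOP_CODONS = ("TAA", "TAG", "TGA")
#: the canonical prokaryotic start codons; CTG is deliberately excluded
START_CODONS = ("ATG", "GTG", "TTG")

#: all 64 codons in lexicographic order
CODONS64 = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
#: the 61 sense codons (stops removed), lexicographic — this fixed order
#: indexes every codon-count vector and EDP in the package
SENSE_CODONS = tuple(c for c in CODONS64 if c not in STOP_CODONS)
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize(seq: str) -> str:
    """Upper-case and map every character outside {A,C,G,T,N} to N."""
    seq = seq.upper()
    if set(seq) <= set("ACGTN"):
        return seq
    return "".join(c if c in "ACGTN" else "N" for c in seq)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes A=0 C=1 G=2 T=3, anything else -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out
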