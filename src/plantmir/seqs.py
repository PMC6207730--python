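"""Small nucleotide-sequence helpers shared across the package.

Sequences are plain Python strings. Genomic sequences use the DNA alphabet
{A,C,G,T,N}; folded/mature sequences use RNA {A,C,G,U}. Encoded arrays map
A=0, C=1, G=2, T/U=3, N=4.
"""

from __future__ import annotations

import numpy as np

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_CODE[ord("U")] = 3
_CODE[ord("u")] = 3

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as int8 codes (A=0, C=1, G=2, T/U=3, other=4)."""
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def check_alphabet(seq: str, alphabet: frozenset, what: str = "sequence") -> None:
    bad = set(seq.upper()) - alphabet
    if bad:
        raise ValueError(
            f"{what} contains characters outside {''.join(sorted(alphabet))}: "
            f"{''.join(sorted(bad))}"
        )


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    acgu = sum(s.count(c) for c in "ACGTU")
    if acgu == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgu


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
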