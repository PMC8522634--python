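"""Small DNA-sequence helpers shared across pipeline stages.

Sequences are plain Python strings over A/C/G/T (plus N where noted).
For vectorised inner loops they are viewed as uint8 arrays of ASCII
codes; the lookup tables below complement or encode in that space.
"""

from __future__ import annotations

import numpy as np

DNA_BASES = "ACGT"
_BASE_SET = frozenset(DNA_BASES)
_READ_SET = frozenset(DNA_BASES + "N")

# ASCII-level complement table: A<->T, C<->G, N->N; everything else maps
# to itself (never consulted for validated sequences).
_COMPLEMENT_ASCII = np.arange(256, dtype=np.uint8)
for _a, _b in [("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")]:
    _COMPLEMENT_ASCII[ord(_a)] = ord(_b)

_COMPLEMENT_STR = str.maketrans("ACGTN", "TGCAN")

# ASCII -> base index (A=0, C=1, G=2, T=3, N=4); 255 marks invalid.
ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES + "N"):
    ASCII_TO_CODE[ord(_b)] = _i
CODE_TO_ASCII = np.frombuffer((DNA_BASES + "N").encode(), dtype=np.uint8)


def is_dna(seq: str, allow_n: bool = False) -> bool:
    """True if *seq* is over the A/C/G/T alphabet (N allowed when asked)."""
    alphabet = _READ_SET if allow_n else _BASE_SET
    return all(c in alphabet for c in seq)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT_STR)[::-1]


def seq_to_ascii(seq: str) -> np.ndarray:
    """View a sequence as a 1-D uint8 array of ASCII codes (no copy of semantics)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def ascii_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def complement_ascii(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT_ASCII[arr]
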