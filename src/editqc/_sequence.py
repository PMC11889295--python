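"""Low-level DNA sequence helpers shared across the package.

Sequences are plain Python strings over the IUPAC DNA alphabet; the hot
numerical paths (k-mer counting, off-target scanning, read simulation) work on
2-bit numpy encodings produced here.
"""

from __future__ import annotations

import numpy as np

#: IUPAC nucleotide codes and the concrete bases each one stands for.
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

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

_COMPLEMENT_MAP = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(
    "".join(_COMPLEMENT_MAP) + "".join(_COMPLEMENT_MAP).lower(),
    "".join(_COMPLEMENT_MAP.values()) + "".join(_COMPLEMENT_MAP.values()).lower(),
)


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (case preserved)."""
    return seq.translate(_COMP_TABLE)[::-1]


# 2-bit encoding: A=0 C=1 G=2 T=3; anything else maps to the sentinel 255.
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A/C/G/T -> 0..3, other -> 255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for arrays containing only codes 0..3."""
    return _DEC[codes].tobytes().decode("ascii")


def window_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every length-``k`` window of a 2-bit encoded sequence into uint64.

    Returns ``(codes, valid)`` where ``codes[i]`` is the packed code of the
    window starting at 0-based ``i`` and ``valid[i]`` is False when the window
    contains a non-ACGT base (its packed code is then meaningless).

    Requires ``k <= 32`` (two bits per base in a 64-bit word).
    """
    if k > 32:
        raise ValueError("k must be <= 32 for packed 2-bit codes")
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = (enc >= 4).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    safe = np.where(enc < 4, enc, 0).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        codes = (codes << two) | safe[j : j + n]
    return codes, valid


def validate_dna(seq: str, *, name: str = "sequence") -> str:
    """Uppercase ``seq`` and reject characters outside the IUPAC DNA alphabet."""
    up = seq.upper()
    if not up:
        raise ValueError(f"{name}: empty sequence")
    bad = set(up) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"{name}: non-IUPAC DNA characters {sorted(bad)!r}")
    return up


def shannon_entropy(seq: str) -> float:
    """Base-composition Shannon entropy of a DNA string, in bits (0..2)."""
    n = len(seq)
    h = 0.0
    for b in set(seq):
        f = seq.count(b) / n
        h -= f * np.log2(f)
    return h
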