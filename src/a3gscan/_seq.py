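"""Byte-level DNA sequence helpers.

Sequences are held as ``numpy.uint8`` arrays of ASCII codes (A/C/G/T plus
anything else treated as missing), which keeps whole-genome operations
vectorised.  IUPAC degenerate codes are supported where motifs need them
(W, R, Y, N).
"""

from __future__ import annotations

import numpy as np

from .errors import ArgumentError

A, C, G, T = (ord(b) for b in "ACGT")
N = ord("N")
GAP = ord("-")

#: IUPAC code -> set of concrete bases it matches.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "R": "AG", "Y": "CT", "N": "ACGT",
}

_COMPLEMENT_STR = {"A": "T", "C": "G", "G": "C", "T": "A",
                   "W": "W", "R": "Y", "Y": "R", "N": "N"}

COMP = np.full(256, N, dtype=np.uint8)
for _b, _c in zip("ACGTN", "TGCAN"):
    COMP[ord(_b)] = ord(_c)
COMP[GAP] = GAP

# membership lookup tables: _IUPAC_LUT[code][byte] -> bool
_IUPAC_LUT: dict[str, np.ndarray] = {}
for _code, _bases in IUPAC.items():
    _lut = np.zeros(256, dtype=bool)
    for _b in _bases:
        _lut[ord(_b)] = True
    _IUPAC_LUT[_code] = _lut

_IS_BASE = np.zeros(256, dtype=bool)
for _b in "ACGT":
    _IS_BASE[ord(_b)] = True


def seq_to_array(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    arr = np.frombuffer(seq, dtype=np.uint8).copy()
    # uppercase soft-masked bases in place (a-z -> A-Z)
    lower = (arr >= ord("a")) & (arr <= ord("z"))
    arr[lower] -= 32
    return arr


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def is_base(arr: np.ndarray) -> np.ndarray:
    """True where the byte is a concrete A/C/G/T."""
    return _IS_BASE[arr]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT_STR.get(b, "N") for b in reversed(seq.upper()))


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return COMP[arr][::-1]


def iupac_match(arr: np.ndarray, code: str) -> np.ndarray:
    """Boolean mask of positions in *arr* matching one IUPAC *code*."""
    try:
        return _IUPAC_LUT[code][arr]
    except KeyError:
        raise ArgumentError(f"unsupported IUPAC code {code!r}") from None


def pattern_positions(arr: np.ndarray, pattern: str, anchor_index: int) -> np.ndarray:
    """Boolean mask over *arr*: True at position ``p`` when *pattern*
    occurs on the plus strand with its ``anchor_index``-th symbol at ``p``.

    Positions where the pattern would run off either end are False.
    """
    m = len(pattern)
    if not 0 <= anchor_index < m:
        raise ArgumentError(f"anchor_index {anchor_index} outside pattern of length {m}")
    L = arr.size
    out = np.ones(L, dtype=bool)
    for j, code in enumerate(pattern):
        off = j - anchor_index  # genome offset of pattern symbol j relative to anchor
        hit = np.zeros(L, dtype=bool)
        lo, hi = max(0, -off), min(L, L - off)
        if lo < hi:
            hit[lo:hi] = iupac_match(arr[lo + off:hi + off], code)
        out &= hit
    return out


def pattern_positions_minus(arr: np.ndarray, pattern: str, anchor_index: int) -> np.ndarray:
    """Like :func:`pattern_positions` but for occurrences on the minus
    strand; position ``p`` refers to plus-strand coordinates of the anchored
    (mutated) base."""
    rc = revcomp(pattern)
    return pattern_positions(arr, rc, len(pattern) - 1 - anchor_index)
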