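"""Shared nucleotide-sequence helpers (alphabet order A, C, G, T throughout)."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A<->T, C<->G in index space: complement(i) = 3 - i
NON_ACGT = 4


def revcomp(seq: str) -> str:
    """Reverse complement; N (and lowercase) are preserved as N."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8: A=0, C=1, G=2, T=3, anything else 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, NON_ACGT, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def gc_fraction_acgt(seq: str) -> float:
    """G+C over A+C+G+T (non-ACGT letters excluded). Raises if no ACGT letters."""
    enc = encode(seq)
    counted = enc != NON_ACGT
    n = int(counted.sum())
    if n == 0:
        raise ValueError("sequence has no A/C/G/T letters; GC content undefined")
    gc = int(((enc == 1) | (enc == 2)).sum())
    return gc / n
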