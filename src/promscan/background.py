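"""0-order nucleotide background models estimated from promoter FASTA sets.

Scanning is two-stranded, so backgrounds are strand-averaged by construction:
letters are counted on the forward strand and its reverse complement, which
forces q[A]=q[T] and q[C]=q[G] and removes any strand bias.  An add-one floor
keeps every frequency strictly positive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from ._seq import BASES, encode, NON_ACGT


@dataclass(frozen=True)
class BackgroundModel:
    """Per-species 0-order nucleotide frequencies q[b], b in (A, C, G, T)."""

    background_id: str
    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        q = np.asarray(self.freqs, dtype=float)
        if q.shape != (4,):
            raise ValueError("freqs must have exactly four entries (A, C, G, T)")
        if np.any(q <= 0):
            raise ValueError("background frequencies must be strictly positive")
        if abs(q.sum() - 1.0) > 1e-12:
            raise ValueError("background frequencies must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    @classmethod
    def uniform(cls, background_id: str = "uniform") -> "BackgroundModel":
        return cls(background_id, (0.25, 0.25, 0.25, 0.25))


def estimate_background(
    sequences: Iterable[str] | str | Path, background_id: str
) -> BackgroundModel:
    """Estimate strand-averaged base frequencies from sequences or a FASTA path.

    Non-ACGT letters (N, IUPAC codes) are ignored.  q[b] = (c[b] + 1) /
    (total + 4), where counts include each sequence and its reverse
    complement.
    """
    if isinstance(sequences, (str, Path)):
        seqs = (str(rec.seq) for rec in SeqIO.parse(str(sequences), "fasta"))
    else:
        seqs = iter(sequences)

    counts = np.zeros(4, dtype=np.int64)
    for seq in seqs:
        enc = encode(seq)
        enc = enc[enc != NON_ACGT]
        fwd = np.bincount(enc, minlength=4)
        counts += fwd + fwd[::-1]  # reverse complement: index i -> 3 - i
    total = counts.sum()
    if total == 0:
        raise ValueError("no A/C/G/T letters in input; cannot estimate background")
    q = (counts + 1) / (total + 4)
    return BackgroundModel(background_id, tuple(float(x) for x in q))


def write_background(bg: BackgroundModel, path: str | Path) -> None:
    """Write as a 2-column text file (base, frequency), MEME-background style."""
    with open(path, "w") as fh:
        for base, freq in zip(BASES, bg.freqs):
            fh.write(f"{base} {freq:.10g}\n")


def read_background(path: str | Path, background_id: str | None = None) -> BackgroundModel:
    freqs = dict.fromkeys(BASES, None)
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        base, value = line.split()[:2]
        if base.upper() in freqs:
            freqs[base.upper()] = float(value)
    if any(v is None for v in freqs.values()):
        raise ValueError(f"background file {path} is missing one of A/C/G/T")
    return BackgroundModel(
        background_id or Path(path).stem, tuple(freqs[b] for b in BASES)
    )
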