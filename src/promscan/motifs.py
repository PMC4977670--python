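"""Position matrices: parsing, log-odds conversion, similarity, deduplication, DKL.

A :class:`PositionMatrix` is the probability form of a transcription-factor
binding profile (a PFM column-normalized to probabilities), carrying TF
metadata used downstream (family for overlap resolution, evidence level for
redundancy removal).  Matrices collected from multiple databases and species
are redundant; :func:`deduplicate` collapses profiles whose best ungapped
alignment (either orientation) exceeds a similarity threshold, preferring
experimentally derived matrices.

The DKL conservation index summarizes how far a motif's column distributions
sit from the scanning background: values near zero mean near-background
(uninformative) columns, strongly negative values mean an information-rich,
conserved motif.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from ._seq import BASES
from .background import BackgroundModel

EVIDENCE_LEVELS = ("experimental", "inferred", "unknown")
_EVIDENCE_RANK = {lvl: i for i, lvl in enumerate(EVIDENCE_LEVELS)}


class MotifParseError(ValueError):
    """Raised when a motif document or one of its records is malformed."""


@dataclass
class PositionMatrix:
    """A probability-form position matrix with TF metadata.

    ``probs`` is an L×4 array over (A, C, G, T); every column sums to 1.
    ``counts`` optionally retains the raw PFM the probabilities came from.
    """

    motif_id: str
    probs: np.ndarray
    tf_name: str = ""
    tf_family: str = "unknown"
    species: str = ""
    evidence: str = "unknown"
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise MotifParseError(
                f"motif {self.motif_id!r}: probs must be L x 4 with L >= 1"
            )
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise MotifParseError(f"motif {self.motif_id!r}: probabilities outside [0,1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise MotifParseError(f"motif {self.motif_id!r}: columns must sum to 1")
        if self.evidence not in EVIDENCE_LEVELS:
            raise MotifParseError(
                f"motif {self.motif_id!r}: evidence must be one of {EVIDENCE_LEVELS}"
            )
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != self.probs.shape:
                raise MotifParseError(f"motif {self.motif_id!r}: counts shape mismatch")
            if np.any(self.counts < 0):
                raise MotifParseError(f"motif {self.motif_id!r}: negative counts")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        """Most probable base per column (ties broken by alphabet order)."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        """Total information content in bits: Σ_j (2 − H_j)."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return float(2.0 * self.length + plogp.sum())


@dataclass
class LogOddsMatrix:
    """Log-odds scoring form of a motif against a 0-order background.

    s[j][b] = log2( ((p[j][b] + ε) / (1 + 4ε)) / q[b] ), in bits.
    """

    motif_id: str
    scores: np.ndarray
    pseudo: float
    background_id: str

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def to_probabilities(self, bg: BackgroundModel) -> np.ndarray:
        """Invert back to column probabilities given the same background and ε."""
        q = bg.as_array()
        return np.exp2(self.scores) * q[None, :] * (1.0 + 4.0 * self.pseudo) - self.pseudo


@dataclass
class SimilarityReport:
    motif_a: str
    motif_b: str
    similarity: float
    offset: int
    orientation: str  # "forward" | "revcomp"
    overlap_cols: int


def reverse_complement(m: PositionMatrix) -> PositionMatrix:
    """Reverse column order and swap A<->T, C<->G rows (an involution)."""
    return replace(
        m,
        probs=m.probs[::-1, ::-1].copy(),
        counts=None if m.counts is None else m.counts[::-1, ::-1].copy(),
    )


def to_log_odds(
    m: PositionMatrix, bg: BackgroundModel, pseudo: float = 1e-8
) -> LogOddsMatrix:
    """Convert to log-odds bits against ``bg`` with pseudo-probability ε."""
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0 (zero probabilities give -inf scores)")
    q = bg.as_array()
    p = (m.probs + pseudo) / (1.0 + 4.0 * pseudo)
    return LogOddsMatrix(
        motif_id=m.motif_id,
        scores=np.log2(p / q[None, :]),
        pseudo=pseudo,
        background_id=bg.background_id,
    )


# ---------------------------------------------------------------------------
# Parsing


def _from_biopython(motif: "bio_motifs.Motif", motif_id: str) -> PositionMatrix:
    counts = None
    if motif.counts is not None:
        counts = np.column_stack([np.asarray(motif.counts[b], float) for b in BASES])
        totals = counts.sum(axis=1)
        if np.any(totals <= 0):
            raise MotifParseError(f"motif {motif_id!r}: zero-total column in counts")
        probs = counts / totals[:, None]
    else:
        probs = np.column_stack([np.asarray(motif.pwm[b], float) for b in BASES])
        # normalize away rounding in the source document
        probs = probs / probs.sum(axis=1)[:, None]
    return PositionMatrix(motif_id=motif_id, probs=probs, counts=counts)


def parse_motifs(
    text: str,
    metadata: pd.DataFrame | str | None = None,
    fmt: str = "jaspar",
) -> list[PositionMatrix]:
    """Parse a JASPAR-PFM (``fmt="jaspar"``) or MEME (``fmt="meme"``) document.

    ``metadata`` is a TF-association table (TSV path or DataFrame) with columns
    motif_id, tf_name, tf_family and optionally species, evidence.  Motifs
    missing from the table get tf_family="unknown".
    """
    if fmt not in ("jaspar", "meme"):
        raise ValueError(f"unsupported motif format {fmt!r}")
    biopy_fmt = "jaspar" if fmt == "jaspar" else "minimal"
    try:
        records = bio_motifs.parse(io.StringIO(text), biopy_fmt)
    except Exception as exc:  # Bio raises bare Exceptions on malformed input
        raise MotifParseError(f"could not parse {fmt} document: {exc}") from exc

    # the JASPAR reader silently drops records without 4 base rows
    if fmt == "jaspar":
        declared = [ln[1:].split()[0] for ln in text.splitlines() if ln.startswith(">")]
    else:
        declared = [ln.split()[1] for ln in text.splitlines() if ln.startswith("MOTIF")]
    if len(records) != len(declared):
        parsed_ids = {getattr(r, "matrix_id", None) or r.name for r in records}
        missing = [d for d in declared if d not in parsed_ids]
        raise MotifParseError(
            f"malformed motif record(s) (expected 4 base rows): {', '.join(missing) or declared}"
        )

    out: list[PositionMatrix] = []
    for i, rec in enumerate(records):
        motif_id = getattr(rec, "matrix_id", None) or rec.name or f"motif_{i + 1}"
        pm = _from_biopython(rec, motif_id)
        if rec.name and rec.name != motif_id:
            pm.tf_name = rec.name
        out.append(pm)

    if metadata is not None:
        meta = (
            pd.read_csv(metadata, sep="\t", dtype=str)
            if isinstance(metadata, str)
            else metadata
        )
        meta = meta.set_index("motif_id")
        for pm in out:
            if pm.motif_id in meta.index:
                row = meta.loc[pm.motif_id]
                pm.tf_name = str(row.get("tf_name", pm.tf_name) or pm.tf_name)
                pm.tf_family = str(row.get("tf_family", "unknown") or "unknown")
                pm.species = str(row.get("species", pm.species) or pm.species)
                ev = str(row.get("evidence", "unknown") or "unknown")
                pm.evidence = ev if ev in EVIDENCE_LEVELS else "unknown"
    return out


# ---------------------------------------------------------------------------
# Similarity and deduplication


def _column_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two probability columns (length-4 vectors).

    Constant columns carry no preference: two equal constant columns score 1,
    a constant vs a non-constant column scores 0.
    """
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        if sx == 0.0 and sy == 0.0 and np.allclose(x, y):
            return 1.0
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def motif_similarity(a: PositionMatrix, b: PositionMatrix) -> SimilarityReport:
    """Best mean column-wise Pearson correlation over ungapped offsets.

    Both orientations of ``b`` are tried; admissible offsets must overlap by at
    least ceil(0.7 · min(La, Lb)) columns.  The report records the argmax
    offset (position of b's first column relative to a's first column) and
    orientation.
    """
    la, lb = a.length, b.length
    if min(la, lb) < 4:
        raise ValueError("motif_similarity requires both motifs to have length >= 4")
    min_overlap = math.ceil(0.7 * min(la, lb))

    best: SimilarityReport | None = None
    for orientation, bm in (("forward", b), ("revcomp", reverse_complement(b))):
        for offset in range(-(lb - 1), la):
            lo = max(0, offset)
            hi = min(la, offset + lb)
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            cols_a = a.probs[lo:hi]
            cols_b = bm.probs[lo - offset : hi - offset]
            sim = float(
                np.mean([_column_pearson(ca, cb) for ca, cb in zip(cols_a, cols_b)])
            )
            if best is None or sim > best.similarity:
                best = SimilarityReport(a.motif_id, b.motif_id, sim, offset, orientation, overlap)
    if best is None:
        raise ValueError(
            f"no admissible offset for {a.motif_id!r} vs {b.motif_id!r} "
            f"(minimum overlap {min_overlap})"
        )
    return best


def deduplicate(
    motifs: Sequence[PositionMatrix], threshold: float = 0.8
) -> tuple[list[PositionMatrix], list[tuple[str, str, float]]]:
    """Greedy redundancy removal at similarity > ``threshold``.

    Motifs are processed in a canonical order — experimental evidence first,
    then descending information content, then motif_id — so the retained
    representative of each redundant group is the best-supported matrix.
    Returns (kept, dropped) where each dropped entry records
    (dropped_id, kept_id, similarity).
    """
    if not motifs:
        raise ValueError("deduplicate requires a nonempty motif list")
    ordered = sorted(
        motifs,
        key=lambda m: (
            _EVIDENCE_RANK.get(m.evidence, len(EVIDENCE_LEVELS)),
            -m.information_content(),
            m.motif_id,
        ),
    )
    kept: list[PositionMatrix] = []
    dropped: list[tuple[str, str, float]] = []
    for m in ordered:
        match = None
        for k in kept:
            try:
                rep = motif_similarity(k, m)
            except ValueError:
                continue  # overlap constraint unsatisfiable for this pair
            if rep.similarity > threshold:
                match = (m.motif_id, k.motif_id, rep.similarity)
                break
        if match is None:
            kept.append(m)
        else:
            dropped.append(match)
    return kept, dropped


def dedup_report_frame(dropped: Iterable[tuple[str, str, float]]) -> pd.DataFrame:
    """Deduplication report as a DataFrame (written as TSV by callers)."""
    return pd.DataFrame(dropped, columns=["dropped_id", "kept_id", "similarity"])


# ---------------------------------------------------------------------------
# Conservation index


def dkl_index(m: PositionMatrix, bg: BackgroundModel) -> float:
    """Negated Kullback–Leibler divergence of motif columns from background.

    DKL = − Σ_j Σ_b p[j][b] log2(p[j][b] / q[b]), with 0·log 0 = 0.  Against a
    uniform background the index is ≤ 0, and more negative means a more
    information-rich (conserved) motif.
    """
    q = bg.as_array()
    p = m.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q[None, :]), 0.0)
    return float(-terms.sum())
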