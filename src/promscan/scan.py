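"""Two-stranded log-odds scanning with exact p-values and Storey q-values.

The null distribution of a motif's window score under the 0-order background
is computed exactly by dynamic programming: per-column scores are discretized
to bins of width δ (bits) and the distribution of the binned sum is built by
positional convolution over the columns.  A window's p-value is the tail
probability at its own binned score, so p-values are exact at δ resolution
and agree with brute-force enumeration of all 4^L windows.

Reported site scores are the δ-quantized scores (δ · Σ per-column integer
bins).  Integer bin sums are order-independent, which makes strand/reverse-
complement symmetry exact in floating point: scanning the reverse complement
of a sequence yields the coordinate-mirrored site list with bit-identical
scores and p-values.

False-discovery control follows Storey: q-values are computed within each
(motif, species) stratum, ranking candidate p-values against the p-values of
*all* scored windows in the stratum, with the π0 plug-in at λ = 0.5 (floored
at 1/m, capped at 1); sites with q above the threshold (default 0.2) are
discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import NON_ACGT, encode, revcomp
from .background import BackgroundModel
from .motifs import LogOddsMatrix
from .promoters import PromoterRecord

DEFAULT_DELTA = 1e-3  # score bin width, bits
SCORE_FLOOR = -100.0  # per-column clamp, bits


@dataclass
class ScoreDistribution:
    """Exact null distribution of the binned window score for one motif.

    ``tail[k]`` = P(binned score ≥ kmin + k bins) under the background.
    ``column_bins`` (L×4 int) are the per-column discretized scores shared
    with the scanner, so p-value lookups are exactly consistent with the DP.
    """

    motif_id: str
    delta: float
    column_bins: np.ndarray  # L x 4 int64
    kmin: int
    tail: np.ndarray

    @property
    def min_score(self) -> float:
        return self.kmin * self.delta

    @property
    def max_score(self) -> float:
        return (self.kmin + len(self.tail) - 1) * self.delta

    def pvalue_of_binsum(self, binsum: int | np.ndarray) -> np.ndarray:
        idx = np.clip(np.asarray(binsum) - self.kmin, 0, len(self.tail) - 1)
        return self.tail[idx]


@dataclass
class PredictedSite:
    """One motif occurrence on a promoter (1-based inclusive coordinates)."""

    motif_id: str
    tf_name: str
    tf_family: str
    gene_id: str
    start: int
    stop: int
    strand: str
    score: float
    p_value: float
    q_value: float = math.nan
    matched_seq: str = ""
    species: str = ""

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


def window_score(lo: LogOddsMatrix, window: str) -> float | None:
    """Exact log-odds score of one window; None when the window has non-ACGT."""
    if len(window) != lo.length:
        raise ValueError("window length must equal motif length")
    enc = encode(window)
    if np.any(enc == NON_ACGT):
        return None
    return float(lo.scores[np.arange(lo.length), enc].sum())


def build_score_distribution(
    lo: LogOddsMatrix, bg: BackgroundModel, delta: float = DEFAULT_DELTA
) -> ScoreDistribution:
    """Exact null score distribution by positional convolution at δ resolution."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    scores = np.maximum(lo.scores, SCORE_FLOOR)
    k = np.rint(scores / delta).astype(np.int64)  # L x 4
    q = bg.as_array()

    # Convolve per-column kernels in a canonical (sorted) order so the result
    # is bit-identical under column permutation — and hence for a motif and
    # its reverse complement when the background is strand-symmetric.
    kernels = sorted(
        tuple(sorted((int(k[j, b]), float(q[b])) for b in range(4)))
        for j in range(lo.length)
    )
    pmf = np.ones(1)
    kmin = 0
    for kernel in kernels:
        lo_k, hi_k = kernel[0][0], kernel[-1][0]
        new = np.zeros(len(pmf) + hi_k - lo_k)
        for kb, qb in kernel:
            off = kb - lo_k
            new[off : off + len(pmf)] += qb * pmf
        pmf = new
        kmin += lo_k
    tail = np.cumsum(pmf[::-1])[::-1]
    return ScoreDistribution(
        motif_id=lo.motif_id, delta=delta, column_bins=k, kmin=kmin, tail=tail.copy()
    )


def _binsums(enc: np.ndarray, bins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binned window scores along an encoded sequence.

    Returns (binsum, scorable) arrays of length len(enc) − L + 1; unscorable
    windows (containing non-ACGT) get binsum 0 with scorable False.
    """
    L = bins.shape[0]
    n = len(enc) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(enc, L)  # n x L
    scorable = ~(win == NON_ACGT).any(axis=1)
    safe = np.where(win == NON_ACGT, 0, win)
    sums = bins[np.arange(L)[None, :], safe].sum(axis=1)
    return sums.astype(np.int64), scorable


def _rc_bins(bins: np.ndarray) -> np.ndarray:
    """Column bins of the reverse-complement motif (reverse cols, swap rows)."""
    return bins[::-1, ::-1].copy()


def _scan_arrays(
    dist: ScoreDistribution, sequence: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Binned scores and p-values for both strands over one sequence.

    Returns (binsum_fwd, p_fwd, binsum_rev, p_rev); unscorable windows carry
    p = NaN.  A minus-strand hit at forward window i means the motif matches
    the reverse complement of that window, scored via the reverse-complement
    column bins — exactly equal, bin for bin, to scoring the reverse strand.
    """
    enc = encode(sequence)
    out = []
    for bins in (dist.column_bins, _rc_bins(dist.column_bins)):
        sums, scorable = _binsums(enc, bins)
        p = np.full(len(sums), np.nan)
        if len(sums):
            p[scorable] = dist.pvalue_of_binsum(sums[scorable])
        out.extend((sums, p))
    return tuple(out)  # type: ignore[return-value]


def scan_promoter(
    lo: LogOddsMatrix,
    promoter: PromoterRecord,
    dist: ScoreDistribution,
    p_max: float = 1e-3,
    tf_name: str = "",
    tf_family: str = "unknown",
) -> list[PredictedSite]:
    """Scan both strands of one promoter; candidates with p ≤ p_max, q unset."""
    sites, _ = scan_promoter_with_null(
        lo, promoter, dist, p_max=p_max, tf_name=tf_name, tf_family=tf_family
    )
    return sites


def scan_promoter_with_null(
    lo: LogOddsMatrix,
    promoter: PromoterRecord,
    dist: ScoreDistribution,
    p_max: float = 1e-3,
    tf_name: str = "",
    tf_family: str = "unknown",
) -> tuple[list[PredictedSite], np.ndarray]:
    """Like :func:`scan_promoter` but also returns all scored-window p-values
    (both strands), the null set that q-value estimation ranks against."""
    L = lo.length
    seq = promoter.sequence.upper()
    sum_f, p_f, sum_r, p_r = _scan_arrays(dist, seq)
    sites: list[PredictedSite] = []
    for strand, sums, pvals in (("+", sum_f, p_f), ("-", sum_r, p_r)):
        hit_idx = np.flatnonzero(~np.isnan(pvals) & (pvals <= p_max))
        for i in hit_idx:
            start, stop = int(i) + 1, int(i) + L
            matched = seq[i : i + L]
            if strand == "-":
                matched = revcomp(matched)
            sites.append(
                PredictedSite(
                    motif_id=lo.motif_id,
                    tf_name=tf_name,
                    tf_family=tf_family,
                    gene_id=promoter.gene_id,
                    start=start,
                    stop=stop,
                    strand=strand,
                    score=float(sums[i]) * dist.delta,
                    p_value=float(pvals[i]),
                    matched_seq=matched,
                    species=promoter.species,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand, s.stop))
    null_p = np.concatenate([p_f[~np.isnan(p_f)], p_r[~np.isnan(p_r)]])
    return sites, null_p


def scan_promoters(
    lo: LogOddsMatrix,
    promoters: Sequence[PromoterRecord],
    dist: ScoreDistribution,
    p_max: float = 1e-3,
    tf_name: str = "",
    tf_family: str = "unknown",
) -> tuple[list[PredictedSite], dict[tuple[str, str], np.ndarray]]:
    """Scan a promoter set; returns (candidates, null p-values per stratum).

    Strata are (motif_id, species), matching the grouping used by
    :func:`assign_qvalues`.
    """
    candidates: list[PredictedSite] = []
    null_parts: dict[tuple[str, str], list[np.ndarray]] = {}
    for prom in promoters:
        sites, null_p = scan_promoter_with_null(
            lo, prom, dist, p_max=p_max, tf_name=tf_name, tf_family=tf_family
        )
        candidates.extend(sites)
        null_parts.setdefault((lo.motif_id, prom.species), []).append(null_p)
    nulls = {k: np.concatenate(v) if v else np.zeros(0) for k, v in null_parts.items()}
    return candidates, nulls


# ---------------------------------------------------------------------------
# q-values


def storey_qvalues(
    p: np.ndarray, null_p: np.ndarray | None = None, pi0: float | str = "storey",
    lam: float = 0.5,
) -> np.ndarray:
    """Storey q-values for ``p``, ranked against ``null_p`` (default: p itself).

    q(p_i) = min over null p_j ≥ p_i of π0 · m · p_j / rank(p_j), where m and
    ranks refer to the full null set.  ``pi0`` may be an explicit value (1.0
    gives Benjamini–Hochberg) or "storey" for the λ plug-in
    (1 + #{p_j > λ}) / ((1 − λ) m), floored at 1/m and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    null = p if null_p is None else np.asarray(null_p, dtype=float)
    m = len(null)
    if pi0 == "storey":
        pi0_val = (1.0 + float((null > lam).sum())) / ((1.0 - lam) * m)
        pi0_val = min(1.0, max(pi0_val, 1.0 / m))
    else:
        pi0_val = float(pi0)
    order = np.sort(null)
    q_sorted = pi0_val * m * order / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    idx = np.searchsorted(order, p, side="left")
    idx = np.clip(idx, 0, m - 1)
    return np.minimum(q_sorted[idx], 1.0)


def assign_qvalues(
    candidates: Iterable[PredictedSite],
    null_pvalues: Mapping[tuple[str, str], np.ndarray] | None = None,
    q_max: float = 0.2,
    pi0: float | str = "storey",
    lam: float = 0.5,
) -> list[PredictedSite]:
    """Set q-values per (motif, species) stratum and keep sites with q ≤ q_max."""
    by_stratum: dict[tuple[str, str], list[PredictedSite]] = {}
    for s in candidates:
        by_stratum.setdefault((s.motif_id, s.species), []).append(s)
    kept: list[PredictedSite] = []
    for stratum, sites in by_stratum.items():
        null = None if null_pvalues is None else null_pvalues.get(stratum)
        q = storey_qvalues(
            np.array([s.p_value for s in sites]), null_p=null, pi0=pi0, lam=lam
        )
        for site, qv in zip(sites, q):
            site.q_value = float(qv)
            if site.q_value <= q_max:
                kept.append(site)
    kept.sort(key=lambda s: (s.species, s.gene_id, s.start, s.strand, s.motif_id))
    return kept
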