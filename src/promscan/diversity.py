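"""Tajima's D on aligned sequence sets, with complete-deletion gap handling.

The statistic contrasts two estimators of the population mutation parameter:
mean pairwise differences π and the segregating-sites estimator S/a1.  An
excess of rare variants (constrained, specific binding sites) drives D
negative.  Used here both intraspecifically (per TF family binding-site
alignments) and interspecifically (per ortholog group, per region class:
binding sites vs coding sequence vs introns); in the latter use it simply
summarizes divergence, not demography.

Columns containing any gap or N are removed before counting (complete
deletion, the VariScan convention); π is the raw mean pairwise difference
count per block, not per site, as in Tajima's original formulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import encode, NON_ACGT


@dataclass
class AlignmentBlock:
    """An aligned set of n ≥ 2 equal-length rows over {A,C,G,T,N,-}."""

    block_id: str
    rows: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"block {self.block_id!r}: need at least 2 sequences")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError(f"block {self.block_id!r}: rows differ in length")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])


@dataclass
class DiversityResult:
    """Tajima's D and all intermediate quantities for one alignment block."""

    block_id: str
    label: str
    n_used: int
    sites_used: int
    S: int
    pi: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float  # NaN when undefined (S = 0)

    @property
    def d_defined(self) -> bool:
        return not math.isnan(self.D)


def tajima_coefficients(n: int) -> dict[str, float]:
    """The standard a1…e2 coefficients for sample size n."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


class InsufficientSequences(ValueError):
    """Raised when fewer than min_n usable sequences remain in a block."""


def tajima_d(block: AlignmentBlock, min_n: int = 4) -> DiversityResult:
    """Tajima's D with complete deletion of gap/N columns.

    Rows that are entirely gap/N are dropped first; the analysis then uses
    only columns free of gaps and Ns in every remaining row.  D is NaN (not
    an error) when no segregating sites remain.
    """
    mat = np.vstack([encode(r.replace("-", "N")) for r in block.rows])
    usable_rows = (mat != NON_ACGT).any(axis=1)
    mat = mat[usable_rows]
    n = mat.shape[0]
    if n < min_n:
        raise InsufficientSequences(
            f"block {block.block_id!r}: {n} usable sequences < min_n={min_n}"
        )
    clean = ~(mat == NON_ACGT).any(axis=0)
    mat = mat[:, clean]
    sites_used = mat.shape[1]

    # segregating sites: columns with >= 2 distinct bases
    seg = np.zeros(sites_used, dtype=bool)
    if sites_used:
        seg = (mat != mat[0]).any(axis=0)
    S = int(seg.sum())

    # mean pairwise differences over all n(n-1)/2 pairs (raw counts per block)
    npairs = n * (n - 1) // 2
    diff_total = 0
    sub = mat[:, seg]
    for i in range(n - 1):
        diff_total += int((sub[i + 1 :] != sub[i]).sum())
    pi = diff_total / npairs

    coef = tajima_coefficients(n)
    var = coef["e1"] * S + coef["e2"] * S * (S - 1)
    # var = 0 also when n <= 3, where the normalizing constants vanish
    D = math.nan if S == 0 or var <= 0 else (pi - S / coef["a1"]) / math.sqrt(var)
    return DiversityResult(
        block_id=block.block_id,
        label=block.label,
        n_used=n,
        sites_used=sites_used,
        S=S,
        pi=pi,
        D=D,
        **coef,
    )


def group_d_summary(
    results: Iterable[DiversityResult],
    bins: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-label summary of defined D values: n, mean, min, max, histogram.

    ``bins`` are histogram edges (default 12 bins over [-3, 3]); undefined-D
    blocks are counted but excluded from the statistics.
    """
    if bins is None:
        bins = np.linspace(-3.0, 3.0, 13)
    rows = []
    by_label: dict[str, list[DiversityResult]] = {}
    for r in results:
        by_label.setdefault(r.label, []).append(r)
    for label in sorted(by_label):
        group = by_label[label]
        d = np.array([r.D for r in group if r.d_defined])
        n_undef = sum(1 for r in group if not r.d_defined)
        if d.size:
            hist, _ = np.histogram(d, bins=bins)
            rows.append(
                (label, len(group), d.size, n_undef, d.mean(), d.min(), d.max(), hist.tolist())
            )
        else:
            rows.append((label, len(group), 0, n_undef, np.nan, np.nan, np.nan, []))
    return pd.DataFrame(
        rows,
        columns=["label", "n_blocks", "n_defined", "n_undefined", "mean_d", "min_d", "max_d", "histogram"],
    )


def region_divergence_compare(
    og_blocks: Mapping[tuple[str, str], AlignmentBlock], min_n: int = 4
) -> tuple[pd.DataFrame, list[str]]:
    """Per-region-class D distributions across ortholog groups, plus ordering.

    ``og_blocks`` is keyed by (OG id, region_class).  Returns a summary frame
    (one row per region class) and the region classes sorted by descending
    mean D — a descriptive ordering report, no test statistic.
    """
    results: list[DiversityResult] = []
    for (og, region), block in sorted(og_blocks.items()):
        try:
            r = tajima_d(block, min_n=min_n)
        except InsufficientSequences:
            continue
        r.label = region
        results.append(r)
    summary = group_d_summary(results)
    defined = summary[summary["n_defined"] > 0]
    ordering = list(defined.sort_values("mean_d", ascending=False)["label"])
    return summary, ordering


def results_frame(results: Iterable[DiversityResult]) -> pd.DataFrame:
    """All coefficient columns, for auditability of each block's computation."""
    cols = [
        "block_id", "label", "n_used", "sites_used", "S", "pi",
        "a1", "a2", "b1", "b2", "c1", "c2", "e1", "e2", "D",
    ]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in results], columns=cols)


def read_alignment_fasta(path: str | Path, block_id: str | None = None, label: str = "") -> AlignmentBlock:
    from Bio import SeqIO

    rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    return AlignmentBlock(block_id or Path(path).stem, rows, label=label)
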