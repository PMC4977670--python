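"""Post-scan site cleaning: same-family overlap resolution and overlap summaries.

Within each gene's promoter, predicted sites of the same TF family that share
at least one base (on either strand — occupancy is on the DNA duplex) form
connected overlap clusters.  Each cluster is resolved to a single site:
the longest one, then the smallest p-value, with a deterministic positional
tiebreak.  Sites of different families never compete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .scan import PredictedSite


@dataclass
class OverlapSummary:
    species: str
    tf_family: str
    n_overlapping_sites: int
    n_total_sites: int

    @property
    def fraction(self) -> float:
        return (
            self.n_overlapping_sites / self.n_total_sites if self.n_total_sites else 0.0
        )


def _clusters(sites: list[PredictedSite]) -> list[list[PredictedSite]]:
    """Connected components under transitive ≥1-base interval overlap."""
    ordered = sorted(sites, key=lambda s: (s.start, s.stop))
    out: list[list[PredictedSite]] = []
    cur: list[PredictedSite] = []
    cur_end = -1
    for s in ordered:
        if cur and s.start <= cur_end:
            cur.append(s)
            cur_end = max(cur_end, s.stop)
        else:
            if cur:
                out.append(cur)
            cur = [s]
            cur_end = s.stop
    if cur:
        out.append(cur)
    return out


def _winner(cluster: Sequence[PredictedSite]) -> PredictedSite:
    return min(
        cluster,
        key=lambda s: (
            -s.length,
            s.p_value,
            s.start,
            0 if s.strand == "+" else 1,
            s.motif_id,
        ),
    )


def resolve_same_family_overlaps(
    sites: Iterable[PredictedSite],
) -> tuple[list[PredictedSite], list[tuple[PredictedSite, PredictedSite]]]:
    """Keep one site per same-family overlap cluster within each gene.

    Returns (kept, dropped) where each dropped entry is (site, winning site).
    The result is independent of input order and idempotent.
    """
    groups: dict[tuple[str, str, str], list[PredictedSite]] = {}
    for s in sites:
        groups.setdefault((s.species, s.gene_id, s.tf_family), []).append(s)
    kept: list[PredictedSite] = []
    dropped: list[tuple[PredictedSite, PredictedSite]] = []
    for group in groups.values():
        for cluster in _clusters(group):
            win = _winner(cluster)
            kept.append(win)
            dropped.extend((s, win) for s in cluster if s is not win)
    kept.sort(key=lambda s: (s.species, s.gene_id, s.start, s.strand, s.motif_id))
    return kept, dropped


def overlap_summary(kept: Iterable[PredictedSite]) -> list[OverlapSummary]:
    """Per (species, family): how many kept sites overlap a kept site of a
    *different* family on the same gene's promoter."""
    kept = list(kept)
    by_gene: dict[tuple[str, str], list[PredictedSite]] = {}
    for s in kept:
        by_gene.setdefault((s.species, s.gene_id), []).append(s)

    overlapping: set[id] = set()
    for sites in by_gene.values():
        for i, a in enumerate(sites):
            for b in sites[i + 1 :]:
                if a.tf_family != b.tf_family and a.start <= b.stop and b.start <= a.stop:
                    overlapping.add(id(a))
                    overlapping.add(id(b))

    keys = sorted({(s.species, s.tf_family) for s in kept})
    out = []
    for species, family in keys:
        members = [s for s in kept if s.species == species and s.tf_family == family]
        n_over = sum(1 for s in members if id(s) in overlapping)
        out.append(OverlapSummary(species, family, n_over, len(members)))
    return out


def overlap_summary_frame(summaries: Iterable[OverlapSummary]) -> pd.DataFrame:
    rows = [
        (s.species, s.tf_family, s.n_overlapping_sites, s.n_total_sites, s.fraction)
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=["species", "tf_family", "n_overlapping_sites", "n_total_sites", "fraction"],
    )
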