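"""Tabular writers for predicted sites and related reports.

The site TSV mirrors FIMO's column order; BED output converts to 0-based
half-open coordinates at the writer (the in-memory convention is 1-based
inclusive throughout).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .scan import PredictedSite

FIMO_COLUMNS = [
    "motif_id",
    "motif_alt_id",
    "sequence_name",
    "start",
    "stop",
    "strand",
    "score",
    "p-value",
    "q-value",
    "matched_sequence",
]


def sites_frame(sites: Iterable[PredictedSite]) -> pd.DataFrame:
    rows = [
        (
            s.motif_id,
            s.tf_name,
            s.gene_id,
            s.start,
            s.stop,
            s.strand,
            s.score,
            s.p_value,
            s.q_value,
            s.matched_seq,
        )
        for s in sites
    ]
    return pd.DataFrame(rows, columns=FIMO_COLUMNS)


def write_sites_tsv(sites: Iterable[PredictedSite], path: str | Path) -> None:
    sites_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sites_to_bed(sites: Iterable[PredictedSite]) -> list[str]:
    """BED6 lines; start converted to 0-based half-open here."""
    return [
        f"{s.gene_id}\t{s.start - 1}\t{s.stop}\t{s.motif_id}\t{s.score:.3f}\t{s.strand}"
        for s in sites
    ]


def sites_to_gff3(sites: Iterable[PredictedSite]) -> list[str]:
    lines = ["##gff-version 3"]
    for s in sites:
        attrs = f"ID={s.motif_id}:{s.gene_id}:{s.start};Name={s.tf_name};family={s.tf_family};pvalue={s.p_value:.3g};qvalue={s.q_value:.3g}"
        lines.append(
            f"{s.gene_id}\tpromscan\tTF_binding_site\t{s.start}\t{s.stop}\t{s.score:.3f}\t{s.strand}\t.\t{attrs}"
        )
    return lines


def write_dropped_tsv(
    dropped: Iterable[tuple[PredictedSite, PredictedSite]], path: str | Path
) -> None:
    rows = [
        (
            s.motif_id,
            s.gene_id,
            s.start,
            s.stop,
            s.strand,
            s.p_value,
            "overlapped_by_same_family",
            f"{w.motif_id}:{w.gene_id}:{w.start}",
        )
        for s, w in dropped
    ]
    pd.DataFrame(
        rows,
        columns=[
            "motif_id",
            "sequence_name",
            "start",
            "stop",
            "strand",
            "p-value",
            "reason",
            "winner_id",
        ],
    ).to_csv(path, sep="\t", index=False)
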