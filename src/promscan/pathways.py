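"""Projection of kept binding sites onto flowering-pathway gene lists.

Produces the per-gene, per-TF-family count tables for the photoperiod (PH),
vernalization (VE) and pathway-integration (PI) gene sets, and the
family-level totals.  Pathway topology is carried as opaque annotation
(node_group); this module computes counts, not graph layouts.  Wheat
homoeologs (A/B/D subgenomes) are handled as separate species-like pathway
definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .scan import PredictedSite

UNASSIGNED = "unassigned"


@dataclass
class PathwayDefinition:
    """Gene membership of the PH/VE/PI pathways for one species (or subgenome)."""

    species: str
    entries: list[tuple[str, str, str, str]]  # (gene_id, gene_symbol, pathway, node_group)

    def __post_init__(self) -> None:
        seen = set()
        for gene_id, _, pathway, _ in self.entries:
            if pathway not in ("PH", "VE", "PI"):
                raise ValueError(f"gene {gene_id}: pathway must be PH, VE or PI")
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id!r} in pathway definition")
            seen.add(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def pathway_of(self) -> dict[str, str]:
        return {e[0]: e[2] for e in self.entries}


def read_pathway_tsv(path: str | Path, species: str | None = None) -> PathwayDefinition:
    """Read a pathway definition TSV: gene_id, gene_symbol, pathway, node_group."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    sp = species or (df["species"].iloc[0] if "species" in df.columns else "")
    entries = [
        (r["gene_id"], r.get("gene_symbol", ""), r["pathway"], r.get("node_group", ""))
        for _, r in df.iterrows()
    ]
    return PathwayDefinition(sp, entries)


def map_sites(
    sites: Iterable[PredictedSite],
    pathway: PathwayDefinition,
    promoter_gene_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate kept sites by pathway gene × TF family.

    Rows are indexed by (gene_id, pathway) with one column per family plus
    ``total`` and a ``no_promoter`` flag — pathway genes absent from the
    promoter set are flagged, mirroring the "(0)" annotation convention for
    genes with no retrievable promoter.  Sites on genes outside the pathway
    definition are routed to an "unassigned" row.
    """
    pathway_of = pathway.pathway_of()
    promoter_set = None if promoter_gene_ids is None else set(promoter_gene_ids)

    counts: dict[tuple[str, str], dict[str, int]] = {}
    families: set[str] = set()
    for s in sites:
        key = (
            (s.gene_id, pathway_of[s.gene_id])
            if s.gene_id in pathway_of
            else (s.gene_id, UNASSIGNED)
        )
        counts.setdefault(key, {})
        counts[key][s.tf_family] = counts[key].get(s.tf_family, 0) + 1
        families.add(s.tf_family)

    fam_cols = sorted(families)
    rows = []
    index = []
    for gene_id, _, pw, _ in pathway.entries:
        key = (gene_id, pw)
        fam_counts = counts.pop(key, {})
        row = [fam_counts.get(f, 0) for f in fam_cols]
        no_promoter = promoter_set is not None and gene_id not in promoter_set
        rows.append(row + [sum(row), no_promoter])
        index.append(key)
    # anything left over is off-pathway
    for key in sorted(counts):
        fam_counts = counts[key]
        row = [fam_counts.get(f, 0) for f in fam_cols]
        rows.append(row + [sum(row), False])
        index.append((key[0], UNASSIGNED))

    table = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["gene_id", "pathway"]),
        columns=fam_cols + ["total", "no_promoter"],
    )
    return table


def family_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Per family: total sites and number of distinct genes with ≥1 site.

    The ``formatted`` column renders the conventional "sites (genes)" cell.
    """
    fam_cols = [c for c in table.columns if c not in ("total", "no_promoter")]
    rows = []
    for fam in fam_cols:
        col = table[fam]
        n_sites = int(col.sum())
        n_genes = int((col > 0).sum())
        rows.append((fam, n_sites, n_genes, f"{n_sites} ({n_genes})"))
    return pd.DataFrame(rows, columns=["tf_family", "n_sites", "n_genes", "formatted"])


def write_gmt(pathway: PathwayDefinition, path: str | Path) -> None:
    """Optional GMT-style export of the PH/VE/PI gene sets."""
    by_pw: dict[str, list[str]] = {}
    for gene_id, _, pw, _ in pathway.entries:
        by_pw.setdefault(pw, []).append(gene_id)
    with open(path, "w") as fh:
        for pw in ("PH", "VE", "PI"):
            if pw in by_pw:
                genes = "\t".join(by_pw[pw])
                fh.write(f"{pathway.species}_{pw}\t{pw} pathway genes\t{genes}\n")
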