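"""GC-content profiling by genomic region class and TFBS density.

GC content is compositional — N bases are excluded from both numerator and
denominator — while TFBS density is per retrieved sequence length, so Ns
count toward the denominator there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._seq import gc_fraction_acgt
from .promoters import PromoterRecord
from .scan import PredictedSite

REGION_CLASSES = ("promoter", "TFBS", "UTR5", "CDS", "intron", "UTR3")
PATHWAYS = ("PH", "VE", "PI")


@dataclass
class RegionSequence:
    """One sequence labelled with its genomic region class and pathway."""

    gene_id: str
    species: str
    pathway: str
    region_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")
        if not self.sequence:
            raise ValueError("sequence must be nonempty")


def gc_percent(sequence: str) -> float:
    """GC percentage over A/C/G/T letters only; raises when none are present."""
    return 100.0 * gc_fraction_acgt(sequence)


def region_gc_table(regions: Iterable[RegionSequence]) -> pd.DataFrame:
    """Mean ± sample sd of per-sequence GC%, per (species, pathway, region_class).

    Cells with a single sequence report sd as NaN ("not applicable").
    """
    rows = [
        (r.species, r.pathway, r.region_class, gc_percent(r.sequence)) for r in regions
    ]
    df = pd.DataFrame(rows, columns=["species", "pathway", "region_class", "gc"])
    out = (
        df.groupby(["species", "pathway", "region_class"])["gc"]
        .agg(n="count", mean_gc="mean", sd_gc=lambda x: x.std(ddof=1))
        .reset_index()
    )
    return out


def sites_as_regions(sites: Iterable[PredictedSite], pathway_of_gene: Mapping[str, str]) -> list[RegionSequence]:
    """Kept sites' matched sequences as TFBS region records for the GC table."""
    return [
        RegionSequence(
            gene_id=s.gene_id,
            species=s.species,
            pathway=pathway_of_gene.get(s.gene_id, "PH"),
            region_class="TFBS",
            sequence=s.matched_seq,
        )
        for s in sites
        if s.matched_seq
    ]


def tfbs_density(
    sites: Iterable[PredictedSite], promoters: Iterable[PromoterRecord]
) -> dict[str, float]:
    """Sites per kilobase of promoter sequence, per species (Ns included)."""
    length_by_species: dict[str, int] = {}
    for p in promoters:
        length_by_species[p.species] = length_by_species.get(p.species, 0) + p.length
    if not length_by_species or all(v == 0 for v in length_by_species.values()):
        raise ValueError("tfbs_density requires promoters with nonzero total length")
    counts: dict[str, int] = {sp: 0 for sp in length_by_species}
    for s in sites:
        if s.species in counts:
            counts[s.species] += 1
    return {
        sp: 1000.0 * counts[sp] / length_by_species[sp] for sp in length_by_species
    }


def read_region_fasta(path: str) -> list[RegionSequence]:
    """Read regions from FASTA with headers gene|species|pathway|region_class."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(path, "fasta"):
        gene, species, pathway, region_class = rec.id.split("|")
        out.append(RegionSequence(gene, species, pathway, region_class, str(rec.seq).upper()))
    return out
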