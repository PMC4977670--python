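"""Promoter extraction and quality filtering.

A promoter is the stretch of up to ``max_len`` (default 1000) bases
immediately 5' of a gene's transcription start site, truncated so that it
never overlaps any other annotated gene body (either strand) and clipped at
the chromosome edge.  Genes whose upstream neighbour is adjacent or
overlapping yield no promoter at all and are reported absent.

Draft-genome promoters can be dominated by assembly-gap N runs; the filter
removes promoters that are mostly gap (N-fraction above a threshold) or that
retain too few informative bases to host a single scan window.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

from ._seq import revcomp

logger = logging.getLogger(__name__)


@dataclass
class PromoterRecord:
    """An extracted upstream sequence with provenance coordinates.

    Coordinates are 1-based inclusive on the genome; ``sequence`` is reported
    5'→3' relative to the gene (minus-strand promoters are reverse
    complemented), so the last base of ``sequence`` is the base immediately
    5' of the TSS.
    """

    gene_id: str
    species: str
    chrom: str
    genomic_start: int
    genomic_end: int
    strand: str
    sequence: str
    truncated_by_upstream_gene: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if len(self.sequence) != self.genomic_end - self.genomic_start + 1:
            raise ValueError(f"{self.gene_id}: sequence length does not match coordinates")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_fraction(self) -> float:
        if not self.sequence:
            return 0.0
        return self.sequence.upper().count("N") / len(self.sequence)

    @property
    def informative_bases(self) -> int:
        s = self.sequence.upper()
        return sum(s.count(b) for b in "ACGT")

    def fasta_header(self) -> str:
        return f"{self.gene_id}|{self.chrom}:{self.genomic_start}-{self.genomic_end}({self.strand})"


def _load_genome(genome: str | Path | Mapping[str, str]) -> Mapping[str, str]:
    if isinstance(genome, (str, Path)):
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}
    return {k: v.upper() for k, v in genome.items()}


def _gff_db(annotation: str | Path | gffutils.FeatureDB) -> gffutils.FeatureDB:
    if isinstance(annotation, gffutils.FeatureDB):
        return annotation
    path = Path(annotation)
    return gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def _transcript_tss(db: gffutils.FeatureDB, gene: gffutils.Feature) -> int:
    """TSS from mRNA children when present (5'-most transcript end), else gene."""
    starts: list[int] = []
    ends: list[int] = []
    for mrna in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
        starts.append(mrna.start)
        ends.append(mrna.end)
    if gene.strand == "+":
        return min(starts) if starts else gene.start
    return max(ends) if ends else gene.end


def extract_promoters(
    genome: str | Path | Mapping[str, str],
    annotation: str | Path | gffutils.FeatureDB,
    gene_ids: Sequence[str],
    max_len: int = 1000,
    species: str = "",
) -> list[PromoterRecord]:
    """Extract up-to-``max_len``-bp upstream windows for ``gene_ids``.

    The window is truncated at the nearest boundary of any other annotated
    gene (either strand) and at the chromosome edge; genes with zero
    available upstream bases are omitted.  Unknown gene ids are warned about
    and skipped rather than failing the whole extraction.
    """
    seqs = _load_genome(genome)
    db = _gff_db(annotation)

    # all gene bodies per chromosome, for truncation against any neighbour
    bodies: dict[str, list[tuple[int, int, str]]] = {}
    for g in db.features_of_type("gene"):
        bodies.setdefault(g.seqid, []).append((g.start, g.end, g.id))

    out: list[PromoterRecord] = []
    for gid in gene_ids:
        try:
            gene = db[gid]
        except gffutils.exceptions.FeatureNotFoundError:
            logger.warning("gene %s not found in annotation; skipped", gid)
            continue
        if gene.seqid not in seqs:
            logger.warning("gene %s: chromosome %s missing from genome; skipped", gid, gene.seqid)
            continue
        chrom_seq = seqs[gene.seqid]
        chrom_len = len(chrom_seq)
        tss = _transcript_tss(db, gene)
        truncated = False

        if gene.strand == "+":
            win_start, win_end = max(1, tss - max_len), tss - 1
            if win_end < win_start:
                logger.warning("gene %s: no upstream bases (chromosome edge); absent", gid)
                continue
            for start, end, other in bodies.get(gene.seqid, []):
                if other == gene.id:
                    continue
                if start <= win_end and end >= win_start:
                    win_start = max(win_start, end + 1)
                    truncated = True
            if win_start > win_end:
                logger.warning("gene %s: upstream gene adjacent/overlapping; absent", gid)
                continue
            seq = chrom_seq[win_start - 1 : win_end]
        else:
            win_start, win_end = tss + 1, min(chrom_len, tss + max_len)
            if win_end < win_start:
                logger.warning("gene %s: no upstream bases (chromosome edge); absent", gid)
                continue
            for start, end, other in bodies.get(gene.seqid, []):
                if other == gene.id:
                    continue
                if start <= win_end and end >= win_start:
                    win_end = min(win_end, start - 1)
                    truncated = True
            if win_start > win_end:
                logger.warning("gene %s: upstream gene adjacent/overlapping; absent", gid)
                continue
            seq = revcomp(chrom_seq[win_start - 1 : win_end])

        out.append(
            PromoterRecord(
                gene_id=gid,
                species=species,
                chrom=gene.seqid,
                genomic_start=win_start,
                genomic_end=win_end,
                strand=gene.strand,
                sequence=seq,
                truncated_by_upstream_gene=truncated,
            )
        )
    return out


def filter_promoters(
    promoters: Iterable[PromoterRecord],
    max_n_frac: float = 0.9,
    min_informative: int = 20,
) -> tuple[list[PromoterRecord], list[tuple[PromoterRecord, str]]]:
    """Drop gap-dominated promoters; returns (kept, removed_with_reason).

    A promoter is removed when its N-fraction exceeds ``max_n_frac`` or when
    it has fewer than ``min_informative`` non-N bases.
    """
    kept: list[PromoterRecord] = []
    removed: list[tuple[PromoterRecord, str]] = []
    for p in promoters:
        if p.informative_bases < min_informative:
            removed.append(
                (p, f"only {p.informative_bases} informative bases (< {min_informative})")
            )
        elif p.n_fraction > max_n_frac:
            removed.append((p, f"N-fraction {p.n_fraction:.3f} > {max_n_frac}"))
        else:
            kept.append(p)
    return kept, removed


def write_promoters_fasta(promoters: Iterable[PromoterRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.fasta_header()}\n{p.sequence}\n")


def read_promoters_fasta(path: str | Path, species: str = "") -> list[PromoterRecord]:
    """Read promoters written by :func:`write_promoters_fasta` (structured headers)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, loc = rec.id.split("|", 1)
        chrom, rest = loc.split(":", 1)
        coords, strand = rest[:-1].split("("), rest[-2]
        start, end = (int(x) for x in coords[0].split("-"))
        out.append(
            PromoterRecord(
                gene_id=gene_id,
                species=species,
                chrom=chrom,
                genomic_start=start,
                genomic_end=end,
                strand=strand,
                sequence=str(rec.seq).upper(),
            )
        )
    return out
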