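"""Synthetic inputs with planted ground truth for the whole pipeline.

Generates species-like genomes and promoter sets (i.i.d. bases at a chosen
GC fraction — Arabidopsis-like ≈ 0.32, cereal-like ≈ 0.44), motif instances
planted at known coordinates, gap-contaminated promoters to exercise the
N filters, neutral-coalescent alignment blocks for calibrating the diversity
statistics, and ortholog-group alignments whose region classes diverge at
chosen rates.  Everything is deterministic under a fixed seed (default 42).

The coalescent generator emulates the infinite-sites model by assigning each
mutation a unique alignment column, so the Watterson expectation
E[S] = θ·a1 holds exactly and serves as the calibration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from ._seq import BASES, revcomp
from .diversity import AlignmentBlock
from .motifs import PositionMatrix
from .promoters import PromoterRecord

DEFAULT_SEED = 42


@dataclass
class PlantedSite:
    gene_id: str
    motif_id: str
    start: int  # 1-based inclusive, promoter forward axis
    stop: int
    strand: str
    planted_seq: str  # motif-strand sequence (revcomp of the promoter substring on '-')


@dataclass
class SyntheticTruth:
    """Ground-truth record for one generated data set."""

    params: dict
    seed: int
    planted_sites: list[PlantedSite] = field(default_factory=list)
    promoter_intervals: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    # gene_id -> (chrom, genomic_start, genomic_end, strand) of the expected promoter


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=p))


def simulate_genome(
    n_genes: int,
    promoter_len: int = 1000,
    intergenic_len: int = 1500,
    gc: float = 0.44,
    seed: int = DEFAULT_SEED,
    gene_len: int = 300,
    close_every: int = 5,
) -> tuple[dict[str, str], list[str], SyntheticTruth]:
    """One synthetic chromosome with genes at known positions.

    Returns (genome dict {chrom: sequence}, GFF3 lines, truth).  Genes
    alternate strand; every ``close_every``-th gene is placed closer than
    ``promoter_len`` to its upstream neighbour to exercise truncation.  The
    truth records the promoter interval the extraction rule should recover.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    gff = ["##gff-version 3"]
    genes: list[tuple[str, int, int, str]] = []
    cursor = 0
    for i in range(n_genes):
        gap = intergenic_len if (i == 0 or (i + 1) % close_every) else promoter_len // 2
        start = cursor + gap + 1
        end = start + gene_len - 1
        strand = "+" if i % 2 == 0 else "-"
        genes.append((f"gene{i + 1:04d}", start, end, strand))
        cursor = end
    total_len = cursor + intergenic_len
    seq = _random_seq(rng, total_len, gc)
    genome = {chrom: seq}

    truth = SyntheticTruth(
        params={
            "n_genes": n_genes,
            "promoter_len": promoter_len,
            "intergenic_len": intergenic_len,
            "gc": gc,
            "gene_len": gene_len,
        },
        seed=seed,
    )
    for idx, (gid, start, end, strand) in enumerate(genes):
        gff.append(
            f"{chrom}\tpromscan\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
        )
        # expected promoter interval under the truncation rule
        if strand == "+":
            win_start, win_end = max(1, start - promoter_len), start - 1
            for ostart, oend, _, _ in [
                (s, e, g, st) for g, s, e, st in genes if g != gid
            ]:
                if ostart <= win_end and oend >= win_start:
                    win_start = max(win_start, oend + 1)
        else:
            win_start, win_end = end + 1, min(total_len, end + promoter_len)
            for ostart, oend, _, _ in [
                (s, e, g, st) for g, s, e, st in genes if g != gid
            ]:
                if ostart <= win_end and oend >= win_start:
                    win_end = min(win_end, ostart - 1)
        if win_start <= win_end:
            truth.promoter_intervals[gid] = (chrom, win_start, win_end, strand)
    return genome, gff, truth


def simulate_promoters(
    n: int,
    length: int = 1000,
    gc: float = 0.44,
    seed: int = DEFAULT_SEED,
    species: str = "synthetic",
    prefix: str = "gene",
) -> list[PromoterRecord]:
    """Standalone i.i.d. promoter set (no genome context), for scan studies."""
    rng = np.random.default_rng(seed)
    return [
        PromoterRecord(
            gene_id=f"{prefix}{i + 1:04d}",
            species=species,
            chrom="synthetic",
            genomic_start=1,
            genomic_end=length,
            strand="+",
            sequence=_random_seq(rng, length, gc),
        )
        for i in range(n)
    ]


def plant_sites(
    promoters: Sequence[PromoterRecord],
    motifs: Sequence[PositionMatrix],
    sites_per_gene: int | Callable[[np.random.Generator], int] = 1,
    strand_prob: float = 0.5,
    consensus: bool = True,
    seed: int = DEFAULT_SEED,
    max_tries: int = 200,
) -> tuple[list[PromoterRecord], SyntheticTruth]:
    """Plant motif instances at known non-overlapping coordinates.

    Each planted instance is either the motif consensus (``consensus=True``)
    or sampled column-wise from the probability matrix; it replaces the
    background at a random position, on '+' or '-' with ``strand_prob``.
    When a promoter cannot host the requested number of non-overlapping
    instances, fewer are planted (recorded in the truth).
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        params={"sites_per_gene": str(sites_per_gene), "strand_prob": strand_prob,
                "consensus": consensus},
        seed=seed,
    )
    out: list[PromoterRecord] = []
    for prom in promoters:
        seq = list(prom.sequence)
        occupied: list[tuple[int, int]] = []
        n_sites = (
            sites_per_gene(rng) if callable(sites_per_gene) else sites_per_gene
        )
        for _ in range(n_sites):
            motif = motifs[rng.integers(len(motifs))]
            L = motif.length
            if L > prom.length:
                continue
            placed = False
            for _ in range(max_tries):
                pos = int(rng.integers(0, prom.length - L + 1))  # 0-based
                if any(pos <= e and pos + L - 1 >= s for s, e in occupied):
                    continue
                if consensus:
                    inst = motif.consensus()
                else:
                    inst = "".join(
                        BASES[rng.choice(4, p=col)] for col in motif.probs
                    )
                strand = "+" if rng.random() < strand_prob else "-"
                seq[pos : pos + L] = list(inst if strand == "+" else revcomp(inst))
                occupied.append((pos, pos + L - 1))
                truth.planted_sites.append(
                    PlantedSite(
                        gene_id=prom.gene_id,
                        motif_id=motif.motif_id,
                        start=pos + 1,
                        stop=pos + L,
                        strand=strand,
                        planted_seq=inst,
                    )
                )
                placed = True
                break
            if not placed:
                break  # no room left in this promoter
        out.append(replace(prom, sequence="".join(seq)))
    return out, truth


def corrupt_with_gaps(
    promoters: Sequence[PromoterRecord],
    n_frac: float,
    seed: int = DEFAULT_SEED,
) -> list[PromoterRecord]:
    """Replace a contiguous fraction ``n_frac`` of each promoter with N runs."""
    if not 0.0 <= n_frac <= 1.0:
        raise ValueError("n_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for prom in promoters:
        run = round(n_frac * prom.length)
        if run == 0:
            out.append(prom)
            continue
        start = int(rng.integers(0, prom.length - run + 1))
        seq = prom.sequence[:start] + "N" * run + prom.sequence[start + run :]
        out.append(replace(prom, sequence=seq))
    return out


def simulate_coalescent_block(
    n: int,
    theta: float,
    L: int,
    seed: int = DEFAULT_SEED,
    block_id: str = "coalescent",
    label: str = "",
    max_retries: int = 20,
) -> AlignmentBlock:
    """Neutral Kingman coalescent with infinite-sites mutations on L columns.

    While k lineages remain, a waiting time Exp(rate k(k−1)/2) elapses (time
    in units of 2N generations) and a uniformly chosen pair merges; each
    lineage accrues Poisson(θ/2 · branch length) mutations, each assigned a
    unique column carried by the subtended leaves.  If more mutations than
    columns are drawn, the block is resampled (bounded retries).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        # lineages: leaf sets currently uncoalesced
        lineages: list[set[int]] = [{i} for i in range(n)]
        mutations: list[set[int]] = []  # leaf set carrying each mutation
        k = n
        while k > 1:
            dt = rng.exponential(2.0 / (k * (k - 1)))
            if theta > 0:
                for leafset in lineages:
                    for _ in range(rng.poisson(theta / 2.0 * dt)):
                        mutations.append(set(leafset))
            i, j = rng.choice(k, size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            lineages[i] = lineages[i] | lineages[j]
            del lineages[j]
            k -= 1
        if len(mutations) <= L:
            break
    else:
        raise RuntimeError(
            f"could not place {len(mutations)} mutations in {L} columns "
            f"after {max_retries} retries; increase L"
        )

    cols = rng.choice(L, size=len(mutations), replace=False)
    anc = rng.integers(0, 4, size=L)
    rows = np.tile(anc, (n, 1))
    for col, leafset in zip(cols, mutations):
        derived = (anc[col] + 1 + rng.integers(0, 3)) % 4
        for leaf in leafset:
            rows[leaf, col] = derived
    seqs = ["".join(BASES[b] for b in row) for row in rows]
    return AlignmentBlock(block_id, seqs, label=label)


def mutate_ortholog_regions(
    ancestors: Mapping[str, str],
    rates: Mapping[str, float],
    n_species: int,
    seed: int = DEFAULT_SEED,
    og_id: str = "OG",
) -> dict[tuple[str, str], AlignmentBlock]:
    """Diverge one ortholog group's region sequences at per-region rates.

    Each species independently substitutes each base of each region's
    ancestral sequence with that region's rate, choosing uniformly among the
    three alternative bases (Jukes–Cantor-style); the alignment is positional
    (no indels).  Returns blocks keyed by (og_id, region_class).
    """
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], AlignmentBlock] = {}
    for region, anc_seq in ancestors.items():
        r = rates[region]
        if not 0.0 <= r < 0.75:
            raise ValueError(f"rate for {region!r} must be in [0, 0.75)")
        anc = np.array([BASES.index(b) for b in anc_seq.upper()])
        rows = []
        for _ in range(n_species):
            hit = rng.random(len(anc)) < r
            shift = 1 + rng.integers(0, 3, size=len(anc))
            derived = np.where(hit, (anc + shift) % 4, anc)
            rows.append("".join(BASES[b] for b in derived))
        out[(og_id, region)] = AlignmentBlock(
            f"{og_id}_{region}", rows, label=region
        )
    return out


def simulate_ortholog_groups(
    n_og: int,
    rates: Mapping[str, float],
    region_len: int = 300,
    n_species: int = 4,
    gc: float = 0.44,
    seed: int = DEFAULT_SEED,
) -> dict[tuple[str, str], AlignmentBlock]:
    """Batch of ortholog groups with random ancestors and shared region rates."""
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], AlignmentBlock] = {}
    for i in range(n_og):
        og = f"OG{i + 1:04d}"
        ancestors = {
            region: _random_seq(rng, region_len, gc) for region in rates
        }
        out.update(
            mutate_ortholog_regions(
                ancestors, rates, n_species,
                seed=int(rng.integers(2**31)), og_id=og,
            )
        )
    return out


def write_genome_files(
    genome: Mapping[str, str], gff: Sequence[str], outdir: str | Path, stem: str = "synthetic"
) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{stem}.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    gff_path = outdir / f"{stem}.gff3"
    gff_path.write_text("\n".join(gff) + "\n")
    return fasta, gff_path


def truth_to_bed(truth: SyntheticTruth) -> list[str]:
    """Planted sites as BED6 lines (0-based half-open, promoter-relative)."""
    return [
        f"{p.gene_id}\t{p.start - 1}\t{p.stop}\t{p.motif_id}\t0\t{p.strand}"
        for p in truth.planted_sites
    ]
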