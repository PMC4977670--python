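"""End-to-end orchestration: dedup → background → promoters → scan → filter →
region stats → diversity → pathway tables.

Every stage's output is written with a content-describing filename under the
configured output directory, and a JSON manifest records per-stage inputs
(with SHA-256 hashes), parameters and row counts.  Stage outputs are pure
functions of (inputs, config, seed): rerunning an identical configuration
reproduces identical site tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as psio
from .background import BackgroundModel, estimate_background, write_background
from .diversity import read_alignment_fasta, results_frame, tajima_d, InsufficientSequences
from .motifs import dedup_report_frame, deduplicate, parse_motifs, to_log_odds
from .pathways import family_totals, map_sites, read_pathway_tsv
from .promoters import extract_promoters, filter_promoters, write_promoters_fasta
from .region_stats import region_gc_table, RegionSequence, sites_as_regions, tfbs_density
from .scan import assign_qvalues, build_score_distribution, scan_promoters
from .site_filter import overlap_summary, overlap_summary_frame, resolve_same_family_overlaps

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid or out-of-range configuration values."""


@dataclass
class SpeciesConfig:
    name: str
    genome: str
    annotation: str
    gene_list: str  # text file, one gene id per line (optionally TAB pathway)
    background_fasta: str | None = None  # defaults to the species' promoters
    alignments: str | None = None  # manifest TSV: block_id, label, fasta_path
    pathway_tsv: str | None = None


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; YAML round-trips losslessly."""

    species: list[SpeciesConfig]
    motif_file: str
    motif_format: str = "jaspar"
    motif_metadata: str | None = None
    q_max: float = 0.2
    pseudo: float = 1e-8
    similarity_threshold: float = 0.8
    max_n_frac: float = 0.9
    min_informative: int = 20
    promoter_max_len: int = 1000
    p_max: float = 1e-3
    delta: float = 1e-3
    outdir: str = "promscan_out"
    seed: int = 42

    def validate(self) -> None:
        if not self.species:
            raise ConfigError("at least one species is required")
        if not 0.0 <= self.q_max <= 1.0:
            raise ConfigError("q_max must be in [0, 1]")
        if self.pseudo <= 0:
            raise ConfigError("pseudo must be > 0")
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise ConfigError("similarity_threshold must be in (0, 1]")
        if not 0.0 <= self.max_n_frac <= 1.0:
            raise ConfigError("max_n_frac must be in [0, 1]")
        if self.promoter_max_len < 1:
            raise ConfigError("promoter_max_len must be >= 1")
        if self.motif_format not in ("jaspar", "meme"):
            raise ConfigError("motif_format must be 'jaspar' or 'meme'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["species"] = [SpeciesConfig(**sp) for sp in data.get("species", [])]
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(manifest: list[dict], name: str, inputs: list[str], params: dict, counts: dict) -> None:
    manifest.append(
        {
            "stage": name,
            "inputs": {p: _sha256(p) for p in inputs if Path(p).exists()},
            "params": params,
            "row_counts": counts,
        }
    )
    logger.info("stage %s: %s", name, counts)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    # 1. motif parsing + deduplication
    motif_text = Path(config.motif_file).read_text()
    motifs = parse_motifs(motif_text, metadata=config.motif_metadata, fmt=config.motif_format)
    kept_motifs, dropped_motifs = deduplicate(motifs, threshold=config.similarity_threshold)
    dedup_report_frame(dropped_motifs).to_csv(out / "motif_dedup_report.tsv", sep="\t", index=False)
    _stage(
        manifest, "motif_dedup",
        [config.motif_file] + ([config.motif_metadata] if config.motif_metadata else []),
        {"similarity_threshold": config.similarity_threshold},
        {"motifs_in": len(motifs), "motifs_kept": len(kept_motifs), "motifs_dropped": len(dropped_motifs)},
    )

    backgrounds: dict[str, BackgroundModel] = {}
    promoters_by_species: dict[str, list] = {}
    pathway_of_gene: dict[str, str] = {}

    # 2. backgrounds
    for sp in config.species:
        source = sp.background_fasta or sp.genome
        backgrounds[sp.name] = estimate_background(source, sp.name)
        write_background(backgrounds[sp.name], out / f"background_{sp.name}.txt")
    _stage(
        manifest, "background",
        [sp.background_fasta or sp.genome for sp in config.species],
        {},
        {sp.name: 4 for sp in config.species},
    )

    # 3. promoter extraction + filtering
    prom_counts: dict[str, Any] = {}
    for sp in config.species:
        gene_rows = [
            line.split("\t") for line in Path(sp.gene_list).read_text().splitlines() if line.strip()
        ]
        gene_ids = [r[0] for r in gene_rows]
        for r in gene_rows:
            if len(r) > 1:
                pathway_of_gene[r[0]] = r[1]
        extracted = extract_promoters(
            sp.genome, sp.annotation, gene_ids, max_len=config.promoter_max_len, species=sp.name
        )
        kept, removed = filter_promoters(
            extracted, max_n_frac=config.max_n_frac, min_informative=config.min_informative
        )
        promoters_by_species[sp.name] = kept
        write_promoters_fasta(kept, out / f"promoters_{sp.name}.fa")
        pd.DataFrame(
            [(p.gene_id, reason) for p, reason in removed], columns=["gene_id", "reason"]
        ).to_csv(out / f"promoters_removed_{sp.name}.tsv", sep="\t", index=False)
        prom_counts[sp.name] = {
            "requested": len(gene_ids), "extracted": len(extracted),
            "kept": len(kept), "removed": len(removed),
        }
    _stage(
        manifest, "promoters",
        [sp.gene_list for sp in config.species],
        {"max_len": config.promoter_max_len, "max_n_frac": config.max_n_frac,
         "min_informative": config.min_informative},
        prom_counts,
    )

    # 4. scan + q-values
    all_sites = []
    for sp in config.species:
        bg = backgrounds[sp.name]
        proms = promoters_by_species[sp.name]
        candidates = []
        nulls: dict = {}
        for m in kept_motifs:
            lo = to_log_odds(m, bg, pseudo=config.pseudo)
            dist = build_score_distribution(lo, bg, delta=config.delta)
            cand, null = scan_promoters(
                lo, proms, dist, p_max=config.p_max,
                tf_name=m.tf_name, tf_family=m.tf_family,
            )
            candidates.extend(cand)
            nulls.update(null)
        all_sites.extend(assign_qvalues(candidates, nulls, q_max=config.q_max))
    psio.write_sites_tsv(all_sites, out / "sites_raw.tsv")
    _stage(
        manifest, "scan", [],
        {"p_max": config.p_max, "q_max": config.q_max, "pseudo": config.pseudo,
         "delta": config.delta},
        {"candidate_sites_kept": len(all_sites)},
    )

    # 5. same-family overlap resolution
    kept_sites, dropped_sites = resolve_same_family_overlaps(all_sites)
    psio.write_sites_tsv(kept_sites, out / "sites_filtered.tsv")
    psio.write_dropped_tsv(dropped_sites, out / "sites_dropped.tsv")
    overlap_summary_frame(overlap_summary(kept_sites)).to_csv(
        out / "overlap_summary.tsv", sep="\t", index=False
    )
    _stage(
        manifest, "site_filter", [], {},
        {"sites_in": len(all_sites), "sites_kept": len(kept_sites),
         "sites_dropped": len(dropped_sites)},
    )

    # 6. GC / density stats
    regions: list[RegionSequence] = []
    for sp in config.species:
        for p in promoters_by_species[sp.name]:
            if p.informative_bases:
                regions.append(
                    RegionSequence(p.gene_id, sp.name, pathway_of_gene.get(p.gene_id, "PH"),
                                   "promoter", p.sequence)
                )
    regions.extend(sites_as_regions(kept_sites, pathway_of_gene))
    gc_table = region_gc_table(regions) if regions else pd.DataFrame()
    gc_table.to_csv(out / "region_gc_table.tsv", sep="\t", index=False)
    all_proms = [p for ps in promoters_by_species.values() for p in ps]
    density = tfbs_density(kept_sites, all_proms) if all_proms else {}
    pd.DataFrame(sorted(density.items()), columns=["species", "tfbs_per_kb"]).to_csv(
        out / "tfbs_density.tsv", sep="\t", index=False
    )
    _stage(manifest, "region_stats", [], {},
           {"gc_rows": len(gc_table), "density_species": len(density)})

    # 7. diversity (optional: needs alignment manifests)
    div_results = []
    align_inputs = []
    for sp in config.species:
        if not sp.alignments:
            continue
        align_inputs.append(sp.alignments)
        man = pd.read_csv(sp.alignments, sep="\t")
        base = Path(sp.alignments).parent
        for _, row in man.iterrows():
            block = read_alignment_fasta(
                base / row["fasta_path"], block_id=row["block_id"], label=row["label"]
            )
            try:
                div_results.append(tajima_d(block))
            except InsufficientSequences as exc:
                logger.warning("diversity: %s", exc)
    results_frame(div_results).to_csv(out / "tajima_d.tsv", sep="\t", index=False)
    _stage(manifest, "diversity", align_inputs, {"min_n": 4},
           {"blocks": len(div_results)})

    # 8. pathway tables
    n_tables = 0
    for sp in config.species:
        if not sp.pathway_tsv:
            continue
        pdef = read_pathway_tsv(sp.pathway_tsv, species=sp.name)
        sp_sites = [s for s in kept_sites if s.species == sp.name]
        prom_ids = [p.gene_id for p in promoters_by_species[sp.name]]
        table = map_sites(sp_sites, pdef, promoter_gene_ids=prom_ids)
        table.to_csv(out / f"pathway_counts_{sp.name}.tsv", sep="\t")
        family_totals(table).to_csv(out / f"family_totals_{sp.name}.tsv", sep="\t", index=False)
        n_tables += 1
    _stage(manifest, "pathway",
           [sp.pathway_tsv for sp in config.species if sp.pathway_tsv], {},
           {"tables": n_tables})

    manifest_obj = {"config": asdict(config), "stages": manifest}
    (out / "manifest.json").write_text(json.dumps(manifest_obj, indent=2))
    return manifest_obj
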