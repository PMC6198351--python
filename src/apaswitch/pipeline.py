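"""End-to-end orchestration: simulate (optional) -> filter -> cluster ->
annotate -> switch -> DE -> miRNA, with a run manifest.

Every stage writes plain TSV/BED so any stage can be replaced by an
external tool; the manifest records the resolved configuration, input
digests and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import (
    core_io,
    expression_de,
    mirna_sites,
    polya_clustering,
    read_processing,
    site_annotation,
    switching_analysis,
    synthetic_data,
)
from .core_io import GenomeSource, RunConfig

logger = logging.getLogger("apaswitch")


@dataclass
class RunManifest:
    config: dict
    inputs: dict = field(default_factory=dict)  # path -> md5
    counts: dict = field(default_factory=dict)  # stage accounting
    timestamps: dict = field(default_factory=dict)

    def digest_input(self, path: str | Path) -> None:
        h = hashlib.md5()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        self.inputs[str(path)] = h.hexdigest()

    def stamp(self, stage: str) -> None:
        self.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "inputs": self.inputs,
                    "counts": self.counts,
                    "timestamps": self.timestamps,
                },
                fh,
                indent=2,
            )


@dataclass
class PipelineResult:
    manifest: RunManifest
    sites: list
    annotated: list
    profiles: list
    pair_results: list
    calls: list
    de_results: list
    truth: synthetic_data.TruthTable | None = None


def run_all(
    config: RunConfig,
    out_dir: str | Path,
    *,
    sim_config: synthetic_data.SimulationConfig | None = None,
    genome_fasta: str | Path | None = None,
    genes_path: str | Path | None = None,
    sample_beds: dict[str, str | Path] | None = None,
    case_samples: Sequence[str] | None = None,
    control_samples: Sequence[str] | None = None,
    known_ends_bed: str | Path | None = None,
    polyadb_bed: str | Path | None = None,
    mirna_fasta: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline, either on a simulated experiment
    (``sim_config`` given) or on user-supplied files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    truth = None
    known_ends: list[tuple[str, int, str]] = []
    known_polyadb: list[tuple[str, int, str]] = []

    if sim_config is not None:
        manifest.config["simulation"] = sim_config.to_dict()
        genome_map, genes, known_sites, truth, records = (
            synthetic_data.simulate_experiment(sim_config)
        )
        genome = GenomeSource(genome_map)
        synthetic_data.write_genome_fasta(genome_map, out_dir / "genome.fa")
        synthetic_data.write_gtf(genes, out_dir / "genes.gtf")
        synthetic_data.write_known_sites_bed(known_sites, out_dir / "known_polyadb.bed")
        synthetic_data.write_sample_beds(records, out_dir / "cleavage")
        synthetic_data.write_truth_table(truth, out_dir / "truth.tsv")
        known_polyadb = known_sites
        case_samples = sim_config.case_samples
        control_samples = sim_config.control_samples
        manifest.stamp("simulate")
    else:
        if genome_fasta is None or genes_path is None or not sample_beds:
            missing = [
                name
                for name, v in (
                    ("genome FASTA", genome_fasta),
                    ("gene models", genes_path),
                    ("cleavage BEDs", sample_beds),
                )
                if not v
            ]
            raise ValueError(f"missing required input(s): {', '.join(missing)}")
        for p in (genome_fasta, genes_path, *sample_beds.values()):
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input: {p}")
            manifest.digest_input(p)
        genome = GenomeSource(genome_fasta)
        genes = core_io.read_gene_models(genes_path)
        records = {
            sample: core_io.read_cleavage_records(path, sample)
            for sample, path in sample_beds.items()
        }
        if known_ends_bed:
            known_ends = core_io.read_site_bed(known_ends_bed)
        if polyadb_bed:
            known_polyadb = core_io.read_site_bed(polyadb_bed)
        if case_samples is None or control_samples is None:
            raise ValueError("case_samples and control_samples are required")

    samples = list(case_samples) + list(control_samples)

    # --- internal-priming filter ------------------------------------------
    all_records = [r for s in samples for r in records.get(s, [])]
    kept, filtered = read_processing.internal_priming_filter(
        all_records, genome, config.ip_window
    )
    core_io.write_cleavage_records(kept, out_dir / "kept.bed")
    core_io.write_cleavage_records(filtered, out_dir / "filtered.bed")
    manifest.counts["reads_in"] = len(all_records)
    manifest.counts["reads_kept"] = len(kept)
    manifest.counts["reads_filtered"] = len(filtered)
    manifest.stamp("filter")

    # --- clustering --------------------------------------------------------
    sites = polya_clustering.cluster_cleavage_sites(
        kept, max_gap=config.cluster_distance, min_reads=config.min_cluster_reads
    )
    polya_clustering.write_sites_bed(sites, out_dir / "sites.bed")
    matrix = polya_clustering.site_count_matrix(sites, samples)
    core_io.write_tsv(matrix, out_dir / "site_counts.tsv", index=True)
    manifest.counts["sites_called"] = len(sites)
    manifest.stamp("cluster")

    # --- annotation + profiles --------------------------------------------
    annotator = site_annotation.SiteAnnotator(genes, known_ends, known_polyadb)
    annotated = annotator.mark_tandem_sites(annotator.annotate(sites))
    core_io.write_tsv(
        site_annotation.annotated_sites_table(annotated), out_dir / "annotated.tsv"
    )
    profiles = site_annotation.build_profiles(annotated, samples)
    manifest.counts["genes_profiled"] = len(profiles)
    manifest.stamp("annotate")

    # --- switching ---------------------------------------------------------
    pair_results = switching_analysis.pairwise_switch_scan(
        profiles, case_samples, control_samples, config
    )
    calls = switching_analysis.aggregate_gene_calls(pair_results, config)
    core_io.write_tsv(
        switching_analysis.pair_results_table(pair_results), out_dir / "pairs.tsv"
    )
    core_io.write_tsv(switching_analysis.gene_calls_table(calls), out_dir / "calls.tsv")
    manifest.counts["pairs_tested"] = len(case_samples) * len(control_samples)
    manifest.counts["pair_tests"] = len(pair_results)
    manifest.counts["genes_called"] = sum(c.called for c in calls)
    manifest.stamp("switch")

    # --- differential expression -------------------------------------------
    expr = expression_de.accumulate_expression(annotated, samples)
    de_results = expression_de.exact_de_test(
        expr, case_samples, control_samples, config.de_fdr_threshold
    )
    core_io.write_tsv(expression_de.de_results_table(de_results), out_dir / "de.tsv")
    crosstab = expression_de.crosstab_de_switching(de_results, calls)
    core_io.write_tsv(crosstab, out_dir / "de_by_direction.tsv", index=True)
    manifest.counts["genes_expressed"] = len(expr)
    manifest.counts["genes_de"] = sum(r.status != "ns" for r in de_results)
    manifest.stamp("de")

    # --- miRNA sites --------------------------------------------------------
    if mirna_fasta or (sim_config is not None and sim_config.plant_seed_site):
        if mirna_fasta:
            mirnas = core_io.read_mirna_fasta(mirna_fasta)
        else:
            # reconstruct a mature miRNA whose 8mer site is the planted
            # motif: seed positions 2-8 are the reverse complement of the
            # site's first 7 bases (position 1 is arbitrary)
            site = sim_config.plant_seed_site.upper().replace("U", "T")  # type: ignore[union-attr]
            mirnas = {"planted": "A" + core_io.reverse_complement(site[:-1])}
        gene_map = {g.gene_id: g for g in genes}
        hits = mirna_sites.scan_called_genes(genome, gene_map, profiles, calls, mirnas)
        summary, totals = mirna_sites.gain_loss_summary(hits, calls)
        core_io.write_tsv(mirna_sites.hits_table(hits), out_dir / "mirna_hits.tsv")
        core_io.write_tsv(summary, out_dir / "mirna_gainloss.tsv")
        manifest.counts["mirna_sites_gained"] = totals["gained"]
        manifest.counts["mirna_sites_lost"] = totals["lost"]
        manifest.stamp("mirna")

    manifest.write(out_dir / "manifest.json")
    return PipelineResult(
        manifest=manifest,
        sites=sites,
        annotated=annotated,
        profiles=profiles,
        pair_results=pair_results,
        calls=calls,
        de_results=de_results,
        truth=truth,
    )
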