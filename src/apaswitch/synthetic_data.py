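"""Synthetic 3'-end sequencing experiment generator.

Generates a small genome of tandem-APA genes, gene models, a known-site
catalog, and per-sample aligned cleavage records for a case-control study
(default 6 vs 6), with programmed 3'UTR switching effects and
internal-priming artifacts, so every downstream stage can be exercised and
scored against a per-gene truth table.

Construction guarantees used as oracles downstream:

* every true poly(A) site's strand-downstream 1-20 nt windows (for all
  jittered cleavage positions within +/-8 nt) are free of A's, so no true
  read can be internal-priming filtered;
* every injected artifact record sits immediately upstream of a planted
  >=8-nt A tract, so its window always contains ``AAAAAAAA``;
* per gene per sample, read totals are negative binomial with multinomial
  allocation across sites; programmed switch genes use a shifted
  proximal-usage vector in case samples only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CleavageRecord,
    GeneModel,
    GenomicInterval,
    reverse_complement,
    write_cleavage_records,
    write_fasta,
)

CHROM = "chr1"
JITTER_NT = 8  # cleavage heterogeneity, kept within the 24-nt cluster radius
PROTECT_UP = 7  # motif-free window upstream of a site: covers jitter - 8 + 1
PROTECT_DOWN = 28  # and downstream: jitter + 8 + 20
TRACT_LEN = 10
GUARD = "CGTCG"  # flank for planted seed motifs; A-free and revcomp T-free


@dataclass
class SimulationConfig:
    """Parameters of the synthetic 3'-end sequencing experiment.

    Defaults describe the simulated study: 6 case vs 6 control samples,
    2-4 tandem sites per gene spaced 150-600 nt apart, a mean of 200 reads
    per gene per sample (negative binomial, dispersion ``size`` = 10), 10%
    of genes programmed to switch with proximal usage 0.7 <-> 0.3, half
    lengthening and half shortening, ~20% library-depth spread, and
    internal-priming artifacts at A-rich tracts in ~30% of gene bodies.
    """

    n_genes: int = 500
    n_sites_min: int = 2
    n_sites_max: int = 4
    spacing_min: int = 150
    spacing_max: int = 600
    n_case: int = 6
    n_control: int = 6
    reads_per_gene_mean: float = 200.0
    reads_per_gene_dispersion: float = 10.0
    baseline_proximal_mean: float = 0.5
    usage_concentration: float = 10.0
    switch_fraction: float = 0.10
    switch_base_proximal: float = 0.7
    switch_effect: float = 0.4
    switch_direction_mix: float = 0.5
    ip_artifact_rate: float = 5.0
    a_rich_tract_prob: float = 0.3
    known_site_fraction: float = 0.6
    depth_variation: float = 0.2
    cds_length: int = 300
    utr_buffer: int = 50
    intergenic_gap: int = 600
    plant_seed_site: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "switch_fraction",
            "switch_direction_mix",
            "a_rich_tract_prob",
            "known_site_fraction",
            "baseline_proximal_mean",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.switch_effect <= self.switch_base_proximal):
            raise ValueError("switch_effect must lie in [0, switch_base_proximal]")
        if self.n_sites_min < 2 or self.n_sites_max < self.n_sites_min:
            raise ValueError("need 2 <= n_sites_min <= n_sites_max")
        if self.spacing_min < 2 * JITTER_NT * 2 + 24:
            raise ValueError("site spacing too small for the cluster radius")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per group")
        if not (0.0 <= self.depth_variation < 1.0):
            raise ValueError("depth_variation must lie in [0, 1)")

    @property
    def case_samples(self) -> list[str]:
        return [f"case_{i + 1}" for i in range(self.n_case)]

    @property
    def control_samples(self) -> list[str]:
        return [f"control_{i + 1}" for i in range(self.n_control)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthGeneRecord:
    gene_id: str
    strand: str
    programmed_direction: str  # lengthened | shortened | none
    site_positions: list[int]  # genomic, ordered proximal -> distal
    utr_lengths: list[int]
    control_usage: list[float]
    case_usage: list[float]
    artifact_position: int | None = None
    reads_emitted: dict[str, int] = field(default_factory=dict)
    artifact_reads: dict[str, int] = field(default_factory=dict)


@dataclass
class TruthTable:
    records: dict[str, TruthGeneRecord] = field(default_factory=dict)

    def __getitem__(self, gene_id: str) -> TruthGeneRecord:
        return self.records[gene_id]

    def programmed(self, direction: str | None = None) -> list[str]:
        out = []
        for gid, rec in self.records.items():
            if rec.programmed_direction == "none":
                continue
            if direction is None or rec.programmed_direction == direction:
                out.append(gid)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records.values():
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "strand": rec.strand,
                    "programmed_direction": rec.programmed_direction,
                    "site_positions": ",".join(map(str, rec.site_positions)),
                    "utr_lengths": ",".join(map(str, rec.utr_lengths)),
                    "control_usage": ",".join(f"{u:.6f}" for u in rec.control_usage),
                    "case_usage": ",".join(f"{u:.6f}" for u in rec.case_usage),
                    "artifact_position": (
                        rec.artifact_position if rec.artifact_position is not None else ""
                    ),
                    "total_reads_emitted": sum(rec.reads_emitted.values()),
                    "total_artifact_reads": sum(rec.artifact_reads.values()),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _draw_usage(
    rng: np.random.Generator, k: int, proximal: float | None, config: SimulationConfig
) -> np.ndarray:
    """Usage vector over k ordered sites. ``proximal`` fixes the proximal
    share exactly; None draws it from a Beta centred on the baseline mean."""
    if proximal is None:
        m, c = config.baseline_proximal_mean, config.usage_concentration
        proximal = float(rng.beta(m * c, (1.0 - m) * c))
    rest = rng.dirichlet(np.ones(k - 1)) if k > 1 else np.array([])
    return np.concatenate([[proximal], (1.0 - proximal) * rest])


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], list[tuple[str, int, str]], TruthTable]:
    """Build the genome, gene models, known-site catalog and truth table.

    Returns ``(genome, genes, known_sites, truth)`` where ``genome`` maps
    chromosome name to sequence and ``known_sites`` is a configurable
    subset (default 60%) of the true sites as (chrom, position, strand).
    """
    rng = np.random.default_rng([config.seed, 17])

    n_switch = int(round(config.switch_fraction * config.n_genes))
    n_lengthened = int(round(config.switch_direction_mix * n_switch))
    switch_ids = rng.choice(config.n_genes, size=n_switch, replace=False)
    lengthened = set(switch_ids[:n_lengthened].tolist())
    shortened = set(switch_ids[n_lengthened:].tolist())

    genes: list[GeneModel] = []
    truth = TruthTable()
    known_sites: list[tuple[str, int, str]] = []
    # deferred sequence edits: (start, end, kind) with kind in
    # {"noA", "noT"} or a literal string to write
    protected: list[tuple[int, int, str]] = []
    literals: list[tuple[int, str]] = []
    scrub_regions: list[tuple[str, int, int, str, str]] = []  # gid,start,end,strand,planted

    cursor = config.intergenic_gap
    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        k = int(rng.integers(config.n_sites_min, config.n_sites_max + 1))
        spacings = rng.integers(config.spacing_min, config.spacing_max + 1, size=k)
        offsets = np.cumsum(spacings)  # strand-oriented nt past the stop codon

        if gi in lengthened:
            direction = "lengthened"
            ctrl_prox = config.switch_base_proximal
            case_prox = config.switch_base_proximal - config.switch_effect
        elif gi in shortened:
            direction = "shortened"
            ctrl_prox = config.switch_base_proximal - config.switch_effect
            case_prox = config.switch_base_proximal
        else:
            direction = "none"
            ctrl_prox = case_prox = None

        if direction == "none":
            usage = _draw_usage(rng, k, None, config)
            ctrl_usage = case_usage = usage
        else:
            rest = rng.dirichlet(np.ones(k - 1)) if k > 1 else np.array([])
            ctrl_usage = np.concatenate([[ctrl_prox], (1.0 - ctrl_prox) * rest])
            case_usage = np.concatenate([[case_prox], (1.0 - case_prox) * rest])

        has_tract = bool(rng.random() < config.a_rich_tract_prob)
        artifact_pos: int | None = None
        utr_len_total = int(offsets[-1]) + config.utr_buffer
        gene_len = config.utr_buffer + config.cds_length + utr_len_total

        if strand == "+":
            gene_start = cursor
            cds_start = gene_start + config.utr_buffer
            cds_end = cds_start + config.cds_length
            stop = cds_end - 1
            sites = [stop + int(o) for o in offsets]
            gene_end = gene_start + gene_len
            utr3 = GenomicInterval(CHROM, cds_end, gene_end, strand)
            cds = GenomicInterval(CHROM, cds_start, cds_end, strand)
            terminal = gene_end - 1
            for s in sites:
                protected.append((s - PROTECT_UP, s + PROTECT_DOWN + 1, "noA"))
            if has_tract:
                tract_start = cds_start + config.cds_length // 3
                literals.append((tract_start, "A" * TRACT_LEN))
                artifact_pos = tract_start - 1
            utr_seq_start, utr_seq_end = stop + 1, sites[-1] + 1
        else:
            gene_end = cursor + gene_len
            cds_end = gene_end - config.utr_buffer
            cds_start = cds_end - config.cds_length
            stop = cds_start
            sites = [stop - int(o) for o in offsets]
            gene_start = cursor
            utr3 = GenomicInterval(CHROM, gene_start, cds_start, strand)
            cds = GenomicInterval(CHROM, cds_start, cds_end, strand)
            terminal = gene_start
            for s in sites:
                protected.append((s - PROTECT_DOWN, s + PROTECT_UP + 1, "noT"))
            if has_tract:
                tract_start = cds_start + config.cds_length // 3
                literals.append((tract_start, "T" * TRACT_LEN))
                artifact_pos = tract_start + TRACT_LEN
            utr_seq_start, utr_seq_end = sites[-1], stop

        if config.plant_seed_site and direction == "lengthened":
            motif = config.plant_seed_site.upper().replace("U", "T")
            insert = GUARD + motif + GUARD
            # 5' base of the motif 60 nt into the extended region
            offset = int(offsets[0]) + 59
            if strand == "+":
                literals.append((stop + 1 + offset - len(GUARD), insert))
            else:
                g_end = stop - 1 - offset + 1 + len(GUARD)
                literals.append((g_end - len(insert), reverse_complement(insert)))
            planted = motif
        else:
            planted = ""
        if config.plant_seed_site:
            scrub_regions.append((gene_id, utr_seq_start, utr_seq_end, strand, planted))

        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(CHROM, gene_start, gene_end, strand),
                stop_codon_pos=stop,
                utr3=[utr3],
                cds=[cds],
                introns=[],
                known_terminal_ends=[terminal],
                is_noncoding=False,
            )
        )
        truth.records[gene_id] = TruthGeneRecord(
            gene_id=gene_id,
            strand=strand,
            programmed_direction=direction,
            site_positions=sites,
            utr_lengths=[int(o) for o in offsets],
            control_usage=list(map(float, ctrl_usage)),
            case_usage=list(map(float, case_usage)),
            artifact_position=artifact_pos if has_tract else None,
        )
        for s in sites:
            if rng.random() < config.known_site_fraction:
                known_sites.append((CHROM, s, strand))
        cursor = gene_end + config.intergenic_gap

    total_len = cursor + config.intergenic_gap
    seq = rng.choice(_BASES, size=total_len)
    no_a = np.frombuffer(b"CGT", dtype="S1")
    no_t = np.frombuffer(b"ACG", dtype="S1")
    for start, end, kind in protected:
        seq[start:end] = rng.choice(no_a if kind == "noA" else no_t, size=end - start)
    for start, literal in literals:
        seq[start : start + len(literal)] = np.frombuffer(
            literal.encode(), dtype="S1"
        )

    genome_str = seq.tobytes().decode()
    if config.plant_seed_site:
        genome_str = _scrub_seed_matches(genome_str, config.plant_seed_site, scrub_regions)

    return {CHROM: genome_str}, genes, known_sites, truth


def _scrub_seed_matches(
    genome: str,
    motif: str,
    regions: Sequence[tuple[str, int, int, str, str]],
) -> str:
    """Remove chance seed-family occurrences from simulated 3'UTRs so the
    planted motif is each region's only countable seed match."""
    # the planted motif IS an 8mer site, so the 7-mer site patterns of the
    # same miRNA derive from it directly
    core = motif.upper().replace("U", "T")[:-1]  # 7mer-m8
    a1 = core[1:] + "A"  # 7mer-A1
    replacement = "CGTCGTC"
    seq = list(genome)
    for gene_id, start, end, strand, planted in regions:
        for _ in range(200):
            region = "".join(seq[start:end])
            oriented = region if strand == "+" else reverse_complement(region)
            if planted:
                keep = oriented.find(planted)
            else:
                keep = -1
            hit = None
            for pat in (core, a1):
                i = oriented.find(pat)
                while i != -1:
                    overlaps_plant = keep != -1 and i < keep + len(planted) and keep < i + len(pat)
                    if not overlaps_plant:
                        hit = (i, len(pat))
                        break
                    i = oriented.find(pat, i + 1)
                if hit:
                    break
            if hit is None:
                break
            i, plen = hit
            oriented = oriented[:i] + replacement[:plen] + oriented[i + plen :]
            back = oriented if strand == "+" else reverse_complement(oriented)
            seq[start:end] = list(back)
        else:
            raise RuntimeError(f"could not scrub seed matches in {gene_id}")
    return "".join(seq)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: TruthTable,
) -> tuple[dict[str, list[CleavageRecord]], TruthTable]:
    """Draw per-sample cleavage records from the configured count model.

    Per sample and gene, the read total is negative binomial (mean =
    ``reads_per_gene_mean`` x the sample's depth factor, dispersion =
    ``reads_per_gene_dispersion``); reads are allocated to sites by the
    gene's group-specific usage vector and jittered uniformly within +/-8
    nt. Poisson(``ip_artifact_rate``) artifact records are placed at the
    gene's artifact position when it carries an A-rich tract.
    """
    rng = np.random.default_rng([config.seed, 43])
    samples = config.case_samples + config.control_samples
    case_set = set(config.case_samples)
    depth = {
        s: float(
            rng.uniform(1.0 - config.depth_variation, 1.0 + config.depth_variation)
        )
        for s in samples
    }

    size = config.reads_per_gene_dispersion
    records: dict[str, list[CleavageRecord]] = {s: [] for s in samples}
    for gene in genes:
        rec = truth[gene.gene_id]
        sites = np.asarray(rec.site_positions)
        for sample in samples:
            mu = config.reads_per_gene_mean * depth[sample]
            n = int(rng.negative_binomial(size, size / (size + mu))) if mu > 0 else 0
            usage = np.asarray(
                rec.case_usage if sample in case_set else rec.control_usage
            )
            alloc = rng.multinomial(n, usage) if n > 0 else np.zeros(len(sites), int)
            for site, count in zip(sites, alloc):
                if count == 0:
                    continue
                jitter = rng.integers(-JITTER_NT, JITTER_NT + 1, size=int(count))
                for pos in site + jitter:
                    records[sample].append(
                        CleavageRecord(gene.chrom, gene.strand, int(pos), sample)
                    )
            rec.reads_emitted[sample] = int(n)
            if rec.artifact_position is not None and config.ip_artifact_rate > 0:
                n_art = int(rng.poisson(config.ip_artifact_rate))
                for _ in range(n_art):
                    records[sample].append(
                        CleavageRecord(
                            gene.chrom, gene.strand, rec.artifact_position, sample
                        )
                    )
                rec.artifact_reads[sample] = n_art
    return records, truth


def simulate_experiment(config: SimulationConfig):
    """Convenience wrapper: genome + reads in one call."""
    genome, genes, known_sites, truth = simulate_genome(config)
    records, truth = simulate_reads(config, genes, truth)
    return genome, genes, known_sites, truth, records


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------

def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Single-transcript GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            biotype = "noncoding" if g.is_noncoding else "protein_coding"
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{biotype}";'
            tx_attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; gene_biotype "{biotype}";'
            fh.write(
                f"{iv.chrom}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{iv.chrom}\tsim\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{tx_attrs}\n"
            )
            fh.write(
                f"{iv.chrom}\tsim\texon\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{tx_attrs}\n"
            )
            for c in g.cds:
                fh.write(
                    f"{c.chrom}\tsim\tCDS\t{c.start + 1}\t{c.end}\t.\t{c.strand}\t0\t{tx_attrs}\n"
                )


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            if g.cds:
                thick_start = min(c.start for c in g.cds)
                thick_end = max(c.end for c in g.cds)
            else:
                thick_start = thick_end = iv.start
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t1\t{len(iv)},\t0,\n"
            )


def write_known_sites_bed(
    sites: Sequence[tuple[str, int, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom, pos, strand in sites:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tknown\t0\t{strand}\n")


def write_sample_beds(
    records: dict[str, list[CleavageRecord]], out_dir: str | Path
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample, recs in records.items():
        p = out_dir / f"{sample}.cleavage.bed"
        write_cleavage_records(recs, p)
        paths[sample] = p
    return paths


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    write_fasta(genome, path)


def write_fastq(
    records: Sequence[CleavageRecord],
    genome: dict[str, str],
    path: str | Path,
    read_length: int = 58,
) -> None:
    """Optional end-to-end realism: 58-nt reads ending at each cleavage base
    (strand-oriented); alignment is never required downstream."""
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            chrom_seq = genome[r.chrom]
            if r.strand == "+":
                seq = chrom_seq[max(r.position - read_length + 1, 0) : r.position + 1]
            else:
                seq = reverse_complement(
                    chrom_seq[r.position : r.position + read_length]
                )
            fh.write(f"@{r.sample_id}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
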