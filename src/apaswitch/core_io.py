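"""Shared coordinate types, run configuration, and readers/writers.

All internal coordinates are 0-based, half-open, the BED convention. GTF
input (1-based, closed) is converted on read. "Downstream" is always
strand-relative: increasing coordinate on ``+``, decreasing on ``-``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("apaswitch")

STRANDS = ("+", "-")

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """One gene with the landmarks the pipeline needs.

    ``stop_codon_pos`` is the 0-based position of the last base of the stop
    codon in transcript orientation: the highest CDS coordinate on ``+``,
    the lowest on ``-``. 3'UTR exons lie strand-downstream of it.
    ``known_terminal_ends`` are annotated transcript 3' ends (cleavage bases).
    """

    gene_id: str
    interval: GenomicInterval
    stop_codon_pos: int | None
    utr3: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)
    known_terminal_ends: list[int] = field(default_factory=list)
    is_noncoding: bool = False

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def utr_distance(self, pos: int) -> int:
        """Strand-oriented distance (nt) from the base after the stop codon
        to ``pos``, inclusive; the 3'UTR length of an isoform ending there."""
        if self.stop_codon_pos is None:
            raise ValueError(f"gene {self.gene_id} has no stop codon")
        if self.strand == "+":
            return pos - self.stop_codon_pos
        return self.stop_codon_pos - pos


@dataclass(frozen=True)
class CleavageRecord:
    """One read's 3'-end cleavage position, tagged with its sample."""

    chrom: str
    strand: str
    position: int
    sample_id: str


@dataclass
class RunConfig:
    """Pipeline thresholds.

    cluster_distance: nt; cleavage positions within this distance chain into
        one poly(A) site (single linkage).
    min_cluster_reads: pooled reads needed for a cluster to become a site.
    ip_window: 1-based downstream window scanned for internal-priming motifs.
    fdr_threshold: per-pair Benjamini-Hochberg cutoff for a switching call.
    min_significant_pairs: case-control pairs a gene must reach to be called.
    min_pair_reads: per-sample read floor for testing a gene in a pair
        (0 disables).
    de_fdr_threshold: BH cutoff for the differential-expression stand-in.
    """

    cluster_distance: int = 24
    min_cluster_reads: int = 2
    ip_window: tuple[int, int] = (1, 20)
    fdr_threshold: float = 0.01
    min_significant_pairs: int = 10
    min_pair_reads: int = 10
    de_fdr_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.ip_window = tuple(self.ip_window)  # type: ignore[assignment]
        if self.cluster_distance <= 0 or self.min_cluster_reads <= 0:
            raise ValueError("cluster thresholds must be positive")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if not (0.0 < self.de_fdr_threshold < 1.0):
            raise ValueError("de_fdr_threshold must lie in (0, 1)")
        if self.min_significant_pairs <= 0:
            raise ValueError("min_significant_pairs must be positive")
        lo, hi = self.ip_window
        if lo < 1 or hi < lo:
            raise ValueError("ip_window must be 1 <= lo <= hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ip_window"] = list(self.ip_window)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# genome access
# ---------------------------------------------------------------------------

class GenomeSource:
    """Uniform 0-based slicing over a FASTA file (pyfaidx) or an in-memory
    {chrom: sequence} mapping. Out-of-bounds slices are truncated."""

    def __init__(self, source: str | Path | Mapping[str, str]):
        if isinstance(source, (str, Path)):
            from pyfaidx import Fasta

            self._fasta = Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._mapping = None
        else:
            self._fasta = None
            self._mapping = {k: str(v).upper() for k, v in source.items()}

    def __contains__(self, chrom: str) -> bool:
        if self._mapping is not None:
            return chrom in self._mapping
        return chrom in self._fasta  # type: ignore[operator]

    def length(self, chrom: str) -> int:
        if self._mapping is not None:
            return len(self._mapping[chrom])
        return len(self._fasta[chrom])  # type: ignore[index]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(start, 0)
        end = min(end, self.length(chrom))
        if start >= end:
            return ""
        if self._mapping is not None:
            return self._mapping[chrom][start:end]
        return str(self._fasta[chrom][start:end])  # type: ignore[index]


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# gene model input
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF/GFF or BED12, dispatching on extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".gtf", ".gff", ".gff2", ".gff3"}:
        return _read_gene_models_gtf(path)
    if suffix in {".bed", ".bed12"}:
        return _read_gene_models_bed12(path)
    raise ValueError(f"unrecognised gene-model format: {path.name}")


def _validate_gtf_lines(path: Path) -> bool:
    """Cheap structural pre-check so malformed records fail with a line
    number. Returns True if the file has any feature lines."""
    any_lines = False
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            any_lines = True
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"malformed GTF record at line {i}: {line.strip()!r}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"malformed GTF coordinates at line {i}") from exc
            if start > end or fields[6] not in STRANDS + (".",):
                raise ValueError(f"malformed GTF record at line {i}")
    return any_lines


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _assemble_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]],
    terminal_ends: list[int],
    noncoding_flagged: bool,
) -> GeneModel:
    exons = _merge_intervals(exons)
    cds = _merge_intervals(cds)
    gene_start = min(s for s, _ in exons)
    gene_end = max(e for _, e in exons)
    interval = GenomicInterval(chrom, gene_start, gene_end, strand)

    introns = [
        GenomicInterval(chrom, e0, s1, strand)
        for (_, e0), (s1, _) in zip(exons, exons[1:])
        if s1 > e0
    ]

    if not cds:
        if not noncoding_flagged:
            warnings.warn(
                f"gene {gene_id} has no CDS and no noncoding flag; "
                "treating as noncoding"
            )
        return GeneModel(
            gene_id=gene_id,
            interval=interval,
            stop_codon_pos=None,
            introns=introns,
            known_terminal_ends=sorted(set(terminal_ends)),
            is_noncoding=True,
        )

    if strand == "+":
        stop_codon_pos = max(e for _, e in cds) - 1
        utr3 = [
            (max(s, stop_codon_pos + 1), e)
            for s, e in exons
            if e > stop_codon_pos + 1
        ]
    else:
        stop_codon_pos = min(s for s, _ in cds)
        utr3 = [(s, min(e, stop_codon_pos)) for s, e in exons if s < stop_codon_pos]
    utr3 = [(s, e) for s, e in utr3 if s < e]

    return GeneModel(
        gene_id=gene_id,
        interval=interval,
        stop_codon_pos=stop_codon_pos,
        utr3=[GenomicInterval(chrom, s, e, strand) for s, e in utr3],
        cds=[GenomicInterval(chrom, s, e, strand) for s, e in cds],
        introns=introns,
        known_terminal_ends=sorted(set(terminal_ends)),
        is_noncoding=False,
    )


def _read_gene_models_gtf(path: Path) -> list[GeneModel]:
    import gffutils

    if not _validate_gtf_lines(path):
        return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        gene_id = gene.attributes.get("gene_id", [gene.id])[0]
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        terminal_ends: list[int] = []
        for tx in db.children(gene, featuretype="transcript"):
            tx_exons = [
                (f.start - 1, f.end) for f in db.children(tx, featuretype="exon")
            ]
            if tx_exons:
                if gene.strand == "+":
                    terminal_ends.append(max(e for _, e in tx_exons) - 1)
                else:
                    terminal_ends.append(min(s for s, _ in tx_exons))
        for f in db.children(gene, featuretype="exon"):
            exons.append((f.start - 1, f.end))
        for f in db.children(gene, featuretype="CDS"):
            cds.append((f.start - 1, f.end))
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        biotype = gene.attributes.get("gene_biotype", [""])[0]
        genes.append(
            _assemble_gene(
                gene_id,
                gene.seqid,
                gene.strand,
                exons,
                cds,
                terminal_ends,
                noncoding_flagged=(biotype not in ("", "protein_coding")),
            )
        )
    return genes


def _read_gene_models_bed12(path: Path) -> list[GeneModel]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 12:
        raise ValueError(f"{path.name}: BED12 requires 12 columns, got {df.shape[1]}")
    genes: list[GeneModel] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        chrom, start, end, name = row[0], int(row[1]), int(row[2]), str(row[3])
        strand = str(row[5])
        if strand not in STRANDS:
            raise ValueError(f"malformed BED12 strand at line {lineno}")
        thick_start, thick_end = int(row[6]), int(row[7])
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        if thick_start < thick_end:
            cds = [
                (max(s, thick_start), min(e, thick_end))
                for s, e in exons
                if min(e, thick_end) > max(s, thick_start)
            ]
        else:
            cds = []
        terminal = end - 1 if strand == "+" else start
        genes.append(
            _assemble_gene(
                name, str(chrom), strand, exons, cds, [terminal],
                noncoding_flagged=not cds,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# cleavage records (BED6)
# ---------------------------------------------------------------------------

def read_cleavage_records(path: str | Path, sample_id: str) -> list[CleavageRecord]:
    """Read one sample's 3'-end positions from BED6.

    The cleavage base is the last aligned base of the read in transcript
    orientation: interval end - 1 on ``+``, interval start on ``-``.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 6:
        raise ValueError(f"{Path(path).name}: BED6 with a strand column required")
    records: list[CleavageRecord] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        chrom, start, end, strand = str(row[0]), int(row[1]), int(row[2]), str(row[5])
        if strand not in STRANDS:
            raise ValueError(f"invalid strand at line {lineno}: {strand!r}")
        if end <= start:
            raise ValueError(f"zero-length interval at line {lineno}")
        pos = end - 1 if strand == "+" else start
        records.append(CleavageRecord(chrom, strand, pos, sample_id))
    return records


def write_cleavage_records(records: Iterable[CleavageRecord], path: str | Path) -> None:
    """Write cleavage records as single-base BED6 intervals (score = 1)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.position}\t{r.position + 1}\t{r.sample_id}\t1\t{r.strand}\n"
            )


def read_site_bed(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a known-poly(A)-site catalog (BED6) as (chrom, position, strand).
    The site position is the interval's strand-oriented 3'-most base."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 6:
        raise ValueError(f"{Path(path).name}: BED6 with a strand column required")
    out = []
    for row in df.itertuples(index=False):
        chrom, start, end, strand = str(row[0]), int(row[1]), int(row[2]), str(row[5])
        if strand not in STRANDS:
            raise ValueError("invalid strand in site catalog")
        out.append((chrom, end - 1 if strand == "+" else start, strand))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_mirna_fasta(path: str | Path) -> dict[str, str]:
    """Mature miRNA sequences keyed by identifier (RNA or DNA alphabet)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
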