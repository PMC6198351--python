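"""miRNA seed-match scanning of common versus extended 3'UTR regions.

For a gene with a proximal and a distal poly(A) site, the *common* region
runs from the base after the stop codon to the proximal site (inclusive)
and the *extended* region from there to the distal site: the extended
region is present only in the long isoform. Canonical seed-match site
types on the mRNA (scanned in DNA alphabet):

* 7mer-m8 — reverse complement of miRNA positions 2-8;
* 8mer    — 7mer-m8 followed by an A;
* 7mer-A1 — reverse complement of positions 2-7 followed by an A.

At one locus only the longest matching type is reported (an 8mer subsumes
the 7mer-m8 at the same offset and the 7mer-A1 one base downstream). Genes
called lengthened gain their extended-region sites; genes called shortened
lose them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import GeneModel, GenomeSource, reverse_complement
from .site_annotation import TandemUTRProfile
from .switching_analysis import GeneSwitchCall

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass(frozen=True)
class SeedPatterns:
    mer8: str
    mer7_m8: str
    mer7_a1: str


@dataclass(frozen=True)
class MirnaSeedHit:
    mirna_id: str
    gene_id: str
    site_type: str
    position: int  # 0-based offset of the match in the 3'UTR
    region: str  # common | extended


def seed_patterns(mirna_seq: str) -> SeedPatterns:
    """Target-site match strings for one mature miRNA (DNA alphabet)."""
    seq = mirna_seq.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError(f"mature miRNA shorter than 8 nt: {mirna_seq!r}")
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"invalid miRNA alphabet: {mirna_seq!r}")
    mer7_m8 = reverse_complement(seq[1:8])
    mer7_a1 = reverse_complement(seq[1:7]) + "A"
    return SeedPatterns(mer8=mer7_m8 + "A", mer7_m8=mer7_m8, mer7_a1=mer7_a1)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def utr_sequence(genome: GenomeSource, gene: GeneModel, distal_pos: int) -> str:
    """Strand-oriented 3'UTR sequence, base after the stop codon through the
    distal cleavage base inclusive."""
    if gene.stop_codon_pos is None:
        raise ValueError(f"gene {gene.gene_id} has no stop codon")
    if gene.strand == "+":
        start, end = gene.stop_codon_pos + 1, distal_pos + 1
        if end > genome.length(gene.chrom):
            raise ValueError(f"3'UTR of {gene.gene_id} extends off contig")
        return genome.fetch(gene.chrom, start, end)
    start, end = distal_pos, gene.stop_codon_pos
    if start < 0:
        raise ValueError(f"3'UTR of {gene.gene_id} extends off contig")
    return reverse_complement(genome.fetch(gene.chrom, start, end))


def scan_utr_regions(
    genome: GenomeSource,
    gene: GeneModel,
    proximal_utr_length: int,
    distal_utr_length: int,
    mirnas: Mapping[str, str],
) -> list[MirnaSeedHit]:
    """Scan a gene's full (distal) 3'UTR for seed matches of each miRNA.

    A hit belongs to the common region when its 5'-most base lies at an
    offset < proximal UTR length, else to the extended region. Overlapping
    occurrences are all counted; at one offset only the longest type is
    kept.
    """
    if not (0 < proximal_utr_length < distal_utr_length):
        raise ValueError("need proximal UTR length < distal UTR length, both > 0")
    if gene.strand == "+":
        distal_pos = gene.stop_codon_pos + distal_utr_length  # type: ignore[operator]
    else:
        distal_pos = gene.stop_codon_pos - distal_utr_length  # type: ignore[operator]
    seq = utr_sequence(genome, gene, distal_pos)

    hits: list[MirnaSeedHit] = []
    for mirna_id, mirna_seq in mirnas.items():
        pats = seed_patterns(mirna_seq)
        starts_8 = set(_find_all(seq, pats.mer8))
        starts_m8 = [i for i in _find_all(seq, pats.mer7_m8) if i not in starts_8]
        # an 8mer at i-1 spells X + 7mer-A1, so the A1 site at i is subsumed
        starts_a1 = [i for i in _find_all(seq, pats.mer7_a1) if i - 1 not in starts_8]
        for site_type, starts in (
            ("8mer", sorted(starts_8)),
            ("7mer-m8", starts_m8),
            ("7mer-A1", starts_a1),
        ):
            for i in starts:
                region = "common" if i < proximal_utr_length else "extended"
                hits.append(MirnaSeedHit(mirna_id, gene.gene_id, site_type, i, region))
    hits.sort(key=lambda h: (h.mirna_id, h.position, h.site_type))
    return hits


def scan_called_genes(
    genome: GenomeSource,
    genes: Mapping[str, GeneModel],
    profiles: Sequence[TandemUTRProfile],
    calls: Sequence[GeneSwitchCall],
    mirnas: Mapping[str, str],
) -> list[MirnaSeedHit]:
    """Seed hits for every called switching gene with a directional call,
    using its shortest (proximal) and longest (distal) tandem UTR lengths."""
    prof_by_gene = {p.gene_id: p for p in profiles}
    hits: list[MirnaSeedHit] = []
    for call in calls:
        if not call.called or call.direction not in ("lengthened", "shortened"):
            continue
        prof = prof_by_gene.get(call.gene_id)
        gene = genes.get(call.gene_id)
        if prof is None or gene is None:
            continue
        hits.extend(
            scan_utr_regions(
                genome, gene, prof.utr_lengths[0], prof.utr_lengths[-1], mirnas
            )
        )
    return hits


def gain_loss_summary(
    hits: Iterable[MirnaSeedHit], calls: Sequence[GeneSwitchCall]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene and total gained/lost miRNA-site counts.

    Lengthened genes gain their extended-region hits; shortened genes lose
    theirs. Genes with an ambiguous direction contribute to neither total.
    """
    direction = {c.gene_id: c.direction for c in calls if c.called}
    ext_counts: dict[str, int] = {}
    for h in hits:
        if h.region == "extended":
            ext_counts[h.gene_id] = ext_counts.get(h.gene_id, 0) + 1

    rows = []
    totals = {"gained": 0, "lost": 0}
    for gene_id in sorted(direction):
        d = direction[gene_id]
        n_ext = ext_counts.get(gene_id, 0)
        gained = n_ext if d == "lengthened" else 0
        lost = n_ext if d == "shortened" else 0
        totals["gained"] += gained
        totals["lost"] += lost
        rows.append(
            {"gene_id": gene_id, "direction": d, "sites_gained": gained, "sites_lost": lost}
        )
    return pd.DataFrame(rows), totals


def hits_table(hits: Sequence[MirnaSeedHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": h.mirna_id,
                "gene_id": h.gene_id,
                "site_type": h.site_type,
                "position": h.position,
                "region": h.region,
            }
            for h in hits
        ]
    )
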