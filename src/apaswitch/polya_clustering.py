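"""Cluster cleavage records into poly(A) sites.

Cleavage positions on the same chromosome and strand whose consecutive
sorted gaps are at most ``max_gap`` nt (default 24) chain into one cluster
(single linkage, so a cluster may span more than 24 nt). Clusters with at
least ``min_reads`` pooled reads (default 2) become poly(A) sites; the
representative position is the modal cleavage base, ties broken toward the
strand-proximal (5') end.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core_io import CleavageRecord, GenomicInterval


@dataclass
class PolyASite:
    """A cluster of cleavage positions treated as one poly(A) site."""

    chrom: str
    strand: str
    span: GenomicInterval
    representative_pos: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.representative_pos}:{self.strand}"


def _chain_positions(positions: Sequence[int], max_gap: int) -> list[list[int]]:
    """Single-linkage chaining of sorted positions: a gap > max_gap starts a
    new cluster."""
    clusters: list[list[int]] = []
    for pos in positions:
        if clusters and pos - clusters[-1][-1] <= max_gap:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])
    return clusters


def cluster_cleavage_sites(
    records: Iterable[CleavageRecord],
    max_gap: int = 24,
    min_reads: int = 2,
) -> list[PolyASite]:
    """Cluster records into poly(A) sites; order is (chrom, strand, start).

    Input record order never affects the result: records are grouped by
    (chrom, strand) and sorted by position before chaining.
    """
    by_key: dict[tuple[str, str], list[CleavageRecord]] = defaultdict(list)
    for rec in records:
        by_key[(rec.chrom, rec.strand)].append(rec)

    sites: list[PolyASite] = []
    for (chrom, strand), recs in sorted(by_key.items()):
        recs.sort(key=lambda r: r.position)
        positions = [r.position for r in recs]
        idx = 0
        for cluster in _chain_positions(positions, max_gap):
            members = recs[idx : idx + len(cluster)]
            idx += len(cluster)
            if len(members) < min_reads:
                continue
            pooled = Counter(m.position for m in members)
            best = max(pooled.values())
            modal = [p for p, c in pooled.items() if c == best]
            # proximal = 5'-most in strand orientation
            rep = min(modal) if strand == "+" else max(modal)
            counts: Counter[str] = Counter(m.sample_id for m in members)
            sites.append(
                PolyASite(
                    chrom=chrom,
                    strand=strand,
                    span=GenomicInterval(chrom, cluster[0], cluster[-1] + 1, strand),
                    representative_pos=rep,
                    counts=dict(counts),
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.span.start, s.strand))
    return sites


def site_count_matrix(sites: Sequence[PolyASite], samples: Sequence[str]) -> pd.DataFrame:
    """Dense samples x sites count table; columns ordered by genomic position.

    Raises on a sample id present in a site's counts but absent from
    ``samples``.
    """
    known = set(samples)
    ordered = sorted(sites, key=lambda s: (s.chrom, s.span.start, s.strand))
    data = {}
    for site in ordered:
        unknown = set(site.counts) - known
        if unknown:
            raise ValueError(f"unknown sample id(s) {sorted(unknown)} at {site.site_id}")
        data[site.site_id] = [site.counts.get(s, 0) for s in samples]
    return pd.DataFrame(data, index=list(samples), dtype=int)


def write_sites_bed(sites: Sequence[PolyASite], path) -> None:
    """BED6 with the cluster span; score column carries the pooled read count."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.span.start}\t{s.span.end}\t{s.site_id}\t"
                f"{s.total_reads}\t{s.strand}\n"
            )
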