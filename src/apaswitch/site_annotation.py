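"""Annotate poly(A) sites against gene models and known-site catalogs, and
build per-gene tandem-3'UTR profiles.

Each site receives exactly one category, resolved by fixed priority:

1. ``ucsc_known_end`` — representative within 24 nt of an annotated
   transcript 3' end;
2. ``known_polyadb`` — within 24 nt of a site in a user-supplied poly(A)
   catalog (same strand);
3. the six putative-novel attributes, most specific first: ``novel_3utr``,
   ``novel_downstream_1kb`` (<=1 kb strand-downstream of a gene end),
   ``novel_cds``, ``novel_noncoding``, ``novel_intron``,
   ``novel_intergenic``.

Sites whose span overlaps an annotated 3'UTR of a same-strand gene — or
known-end/catalog sites attached to a gene's terminal exon — are tandem
poly(A) sites; genes with two or more tandem sites yield a
:class:`TandemUTRProfile`, the unit the switching test consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core_io import GeneModel, GenomicInterval
from .polya_clustering import PolyASite

logger = logging.getLogger("apaswitch")

CATEGORIES = (
    "ucsc_known_end",
    "known_polyadb",
    "novel_3utr",
    "novel_downstream_1kb",
    "novel_cds",
    "novel_noncoding",
    "novel_intron",
    "novel_intergenic",
)

PROXIMITY_NT = 24
DOWNSTREAM_NT = 1000


@dataclass
class AnnotatedSite:
    site: PolyASite
    category: str
    gene_id: str | None = None
    is_tandem: bool = False
    utr_length: int | None = None

    @property
    def site_id(self) -> str:
        return self.site.site_id


@dataclass
class TandemUTRProfile:
    """Per-gene ordered tandem poly(A) sites with 3'UTR lengths and a
    samples x sites count table (columns ordered by ascending UTR length)."""

    gene_id: str
    sites: list[AnnotatedSite]
    utr_lengths: list[int]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError("a tandem-UTR profile needs >= 2 sites")
        if any(b <= a for a, b in zip(self.utr_lengths, self.utr_lengths[1:])):
            raise ValueError("utr_lengths must be strictly increasing")


class SiteAnnotator:
    """Interval indexes over gene features and known-site catalogs."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        known_ends: Iterable[tuple[str, int, str]] = (),
        known_polyadb: Iterable[tuple[str, int, str]] = (),
    ):
        self.genes = {g.gene_id: g for g in genes}
        self._ends = self._point_tree()
        self._polyadb = self._point_tree()
        self._utr3: dict[tuple[str, str], IntervalTree] = {}
        self._cds: dict[tuple[str, str], IntervalTree] = {}
        self._intron: dict[tuple[str, str], IntervalTree] = {}
        self._noncoding: dict[tuple[str, str], IntervalTree] = {}
        self._downstream: dict[tuple[str, str], IntervalTree] = {}

        for g in genes:
            key = (g.chrom, g.strand)
            for pos in g.known_terminal_ends:
                self._add_point(self._ends, key, pos, g.gene_id)
            for iv in g.utr3:
                self._tree(self._utr3, key).addi(iv.start, iv.end, g.gene_id)
            for iv in g.cds:
                self._tree(self._cds, key).addi(iv.start, iv.end, g.gene_id)
            for iv in g.introns:
                self._tree(self._intron, key).addi(iv.start, iv.end, g.gene_id)
            if g.is_noncoding:
                self._tree(self._noncoding, key).addi(
                    g.interval.start, g.interval.end, g.gene_id
                )
            # <=1 kb strand-downstream of the annotated gene end
            if g.strand == "+":
                self._tree(self._downstream, key).addi(
                    g.interval.end, g.interval.end + DOWNSTREAM_NT + 1, g.gene_id
                )
            else:
                self._tree(self._downstream, key).addi(
                    max(g.interval.start - DOWNSTREAM_NT - 1, 0),
                    g.interval.start,
                    g.gene_id,
                )
        for chrom, pos, strand in known_ends:
            self._add_point(self._ends, (chrom, strand), pos, None)
        for chrom, pos, strand in known_polyadb:
            self._add_point(self._polyadb, (chrom, strand), pos, None)

    @staticmethod
    def _point_tree() -> dict[tuple[str, str], IntervalTree]:
        return {}

    @staticmethod
    def _tree(store: dict, key: tuple[str, str]) -> IntervalTree:
        if key not in store:
            store[key] = IntervalTree()
        return store[key]

    def _add_point(self, store, key, pos: int, gene_id: str | None) -> None:
        # a query position hits the interval iff |query - pos| <= 24
        self._tree(store, key).addi(
            max(pos - PROXIMITY_NT, 0), pos + PROXIMITY_NT + 1, gene_id
        )

    @staticmethod
    def _hit(store, key, pos: int):
        tree = store.get(key)
        if tree is None:
            return None
        hits = tree[pos]
        if not hits:
            return None
        if len(hits) > 1:
            gene_ids = sorted({h.data for h in hits if h.data})
            if len(gene_ids) > 1:
                warnings.warn(
                    f"position {key[0]}:{pos} hits multiple genes {gene_ids}; "
                    "using nearest feature"
                )
                return min(hits, key=lambda h: min(abs(pos - h.begin), abs(h.end - 1 - pos)))
        return next(iter(hits))

    def annotate_site(self, site: PolyASite) -> AnnotatedSite:
        key = (site.chrom, site.strand)
        pos = site.representative_pos

        hit = self._hit(self._ends, key, pos)
        if hit is not None:
            return AnnotatedSite(site, "ucsc_known_end", gene_id=hit.data)
        hit = self._hit(self._polyadb, key, pos)
        if hit is not None:
            return AnnotatedSite(site, "known_polyadb", gene_id=hit.data)
        for category, store in (
            ("novel_3utr", self._utr3),
            ("novel_downstream_1kb", self._downstream),
            ("novel_cds", self._cds),
            ("novel_noncoding", self._noncoding),
            ("novel_intron", self._intron),
        ):
            hit = self._hit(store, key, pos)
            if hit is not None:
                return AnnotatedSite(site, category, gene_id=hit.data)
        return AnnotatedSite(site, "novel_intergenic")

    def annotate(self, sites: Iterable[PolyASite]) -> list[AnnotatedSite]:
        return [self.annotate_site(s) for s in sites]

    # -- tandem marking ----------------------------------------------------

    def _utr_overlap_gene(self, site: PolyASite) -> str | None:
        tree = self._utr3.get((site.chrom, site.strand))
        if tree is None:
            return None
        hits = tree[site.span.start : site.span.end]
        if not hits:
            return None
        gene_ids = sorted({h.data for h in hits})
        if len(gene_ids) > 1:
            warnings.warn(
                f"site {site.site_id} overlaps 3'UTRs of {gene_ids}; using nearest"
            )
        return gene_ids[0]

    def mark_tandem_sites(self, annotated: Iterable[AnnotatedSite]) -> list[AnnotatedSite]:
        """Set ``is_tandem``, ``gene_id`` and ``utr_length`` in place.

        A site is tandem iff its span overlaps an annotated 3'UTR of a
        same-strand gene, or it is a known-end/catalog site whose position
        falls in (or within 24 nt of) such a 3'UTR / terminal end of a gene.
        """
        out = []
        for ann in annotated:
            gene_id = self._utr_overlap_gene(ann.site)
            if gene_id is None and ann.category in ("ucsc_known_end", "known_polyadb"):
                gene_id = ann.gene_id
            if gene_id is not None:
                gene = self.genes.get(gene_id)
                if gene is not None and not gene.is_noncoding:
                    ann.is_tandem = True
                    ann.gene_id = gene_id
                    ann.utr_length = utr_length(ann, gene)
            out.append(ann)
        return out


def utr_length(site: AnnotatedSite | PolyASite, gene: GeneModel) -> int:
    """3'UTR length implied by a site: strand-oriented distance from the base
    after the stop codon to the representative position, inclusive."""
    rep = site.representative_pos if isinstance(site, PolyASite) else site.site.representative_pos
    return gene.utr_distance(rep)


def build_profiles(
    annotated: Sequence[AnnotatedSite],
    samples: Sequence[str],
) -> list[TandemUTRProfile]:
    """One profile per gene with >= 2 tandem sites, ordered by UTR length.

    Sites of one gene sharing a UTR length are merged (counts summed) with a
    warning.
    """
    by_gene: dict[str, list[AnnotatedSite]] = {}
    for ann in annotated:
        if ann.is_tandem and ann.gene_id and ann.utr_length is not None:
            by_gene.setdefault(ann.gene_id, []).append(ann)

    profiles: list[TandemUTRProfile] = []
    for gene_id in sorted(by_gene):
        sites = sorted(by_gene[gene_id], key=lambda a: a.utr_length)  # type: ignore[arg-type]
        merged: list[AnnotatedSite] = []
        for ann in sites:
            if merged and ann.utr_length == merged[-1].utr_length:
                warnings.warn(
                    f"gene {gene_id}: duplicate UTR length {ann.utr_length}; merging sites"
                )
                tgt = merged[-1].site.counts
                for s, c in ann.site.counts.items():
                    tgt[s] = tgt.get(s, 0) + c
            else:
                merged.append(ann)
        if len(merged) < 2:
            continue
        counts = pd.DataFrame(
            {a.site_id: [a.site.counts.get(s, 0) for s in samples] for a in merged},
            index=list(samples),
            dtype=int,
        )
        profiles.append(
            TandemUTRProfile(
                gene_id=gene_id,
                sites=merged,
                utr_lengths=[a.utr_length for a in merged],  # type: ignore[list-item]
                counts=counts,
            )
        )
    return profiles


def annotated_sites_table(annotated: Sequence[AnnotatedSite]) -> pd.DataFrame:
    rows = [
        {
            "site_id": a.site_id,
            "chrom": a.site.chrom,
            "strand": a.site.strand,
            "representative_pos": a.site.representative_pos,
            "span_start": a.site.span.start,
            "span_end": a.site.span.end,
            "total_reads": a.site.total_reads,
            "category": a.category,
            "gene_id": a.gene_id or "",
            "is_tandem": int(a.is_tandem),
            "utr_length": a.utr_length if a.utr_length is not None else "",
        }
        for a in annotated
    ]
    return pd.DataFrame(rows)
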