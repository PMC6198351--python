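import numpy as np
import pytest

from apaswitch.core_io import GeneModel, GenomicInterval, GenomeSource
from apaswitch.polya_clustering import PolyASite, cluster_cleavage_sites
from apaswitch.read_processing import internal_priming_filter
from apaswitch.site_annotation import (
    SiteAnnotator,
    build_profiles,
    utr_length,
)


def make_site(pos, strand="+", chrom="chr1", counts=None, span=None):
    span = span or (pos, pos + 1)
    return PolyASite(
        chrom=chrom,
        strand=strand,
        span=GenomicInterval(chrom, span[0], span[1], strand),
        representative_pos=pos,
        counts=counts or {"s1": 2},
    )


@pytest.fixture()
def plus_gene():
    """+ strand gene: exon [700,1300), CDS [700,1000), 3'UTR [1000,1300),
    annotated terminal end at 1299, one intron-free structure."""
    return GeneModel(
        gene_id="gA",
        interval=GenomicInterval("chr1", 700, 1300, "+"),
        stop_codon_pos=999,
        utr3=[GenomicInterval("chr1", 1000, 1300, "+")],
        cds=[GenomicInterval("chr1", 700, 1000, "+")],
        introns=[],
        known_terminal_ends=[1299],
    )


@pytest.fixture()
def minus_gene():
    return GeneModel(
        gene_id="gB",
        interval=GenomicInterval("chr1", 1700, 2300, "-"),
        stop_codon_pos=2000,
        utr3=[GenomicInterval("chr1", 1700, 2000, "-")],
        cds=[GenomicInterval("chr1", 2000, 2300, "-")],
        introns=[],
        known_terminal_ends=[1700],
    )


class TestAnnotateSite:
    def test_within_24nt_of_known_end(self, plus_gene):
        ann = SiteAnnotator([plus_gene]).annotate_site(make_site(1299 + 24))
        assert ann.category == "ucsc_known_end" and ann.gene_id == "gA"

    def test_25nt_past_known_end_inside_utr_is_novel_3utr(self, plus_gene):
        ann = SiteAnnotator([plus_gene]).annotate_site(make_site(1299 - 25))
        assert ann.category == "novel_3utr"

    def test_polyadb_beats_novel(self, plus_gene):
        annot = SiteAnnotator([plus_gene], known_polyadb=[("chr1", 1100, "+")])
        assert annot.annotate_site(make_site(1110)).category == "known_polyadb"

    def test_downstream_1kb(self, plus_gene):
        annot = SiteAnnotator([plus_gene])
        assert annot.annotate_site(make_site(1300 + 900)).category == "novel_downstream_1kb"
        assert annot.annotate_site(make_site(1300 + 1100)).category == "novel_intergenic"

    def test_downstream_is_strand_oriented(self, minus_gene):
        annot = SiteAnnotator([minus_gene])
        assert annot.annotate_site(make_site(1700 - 900, "-")).category == "novel_downstream_1kb"
        assert annot.annotate_site(make_site(2300 + 900, "-")).category == "novel_intergenic"

    def test_cds_and_intergenic(self, plus_gene):
        annot = SiteAnnotator([plus_gene])
        assert annot.annotate_site(make_site(800)).category == "novel_cds"
        assert annot.annotate_site(make_site(50_000)).category == "novel_intergenic"

    def test_intron_category(self):
        gene = GeneModel(
            gene_id="gI",
            interval=GenomicInterval("chr1", 0, 1000, "+"),
            stop_codon_pos=899,
            utr3=[GenomicInterval("chr1", 900, 1000, "+")],
            cds=[GenomicInterval("chr1", 0, 900, "+")],
            introns=[GenomicInterval("chr1", 300, 600, "+")],
        )
        # carve the intron out of the CDS so priority does not interfere
        gene.cds = [
            GenomicInterval("chr1", 0, 300, "+"),
            GenomicInterval("chr1", 600, 900, "+"),
        ]
        assert SiteAnnotator([gene]).annotate_site(make_site(450)).category == "novel_intron"

    def test_noncoding_category(self):
        gene = GeneModel(
            gene_id="gN",
            interval=GenomicInterval("chr1", 0, 500, "+"),
            stop_codon_pos=None,
            is_noncoding=True,
        )
        assert SiteAnnotator([gene]).annotate_site(make_site(250)).category == "novel_noncoding"

    def test_every_site_gets_exactly_one_category(self, small_experiment):
        cfg, genome, genes, known, truth, records = small_experiment
        kept, _ = internal_priming_filter(
            [r for v in records.values() for r in v], GenomeSource(genome)
        )
        sites = cluster_cleavage_sites(kept)
        annotated = SiteAnnotator(genes, known_polyadb=known).annotate(sites)
        assert len(annotated) == len(sites)
        from apaswitch.site_annotation import CATEGORIES

        counts = {c: 0 for c in CATEGORIES}
        for a in annotated:
            counts[a.category] += 1
        assert sum(counts.values()) == len(sites)

    def test_known_fraction_matches_catalog_fraction(self):
        """With the catalog holding 60% of true sites, the fraction of sites
        annotated known is within binomial 2 SE of 0.6."""
        from apaswitch.synthetic_data import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(n_genes=120, a_rich_tract_prob=0.0, seed=21)
        genome, genes, known, truth, records = simulate_experiment(cfg)
        sites = cluster_cleavage_sites([r for v in records.values() for r in v])
        annotated = SiteAnnotator(genes, known_polyadb=known).annotate(sites)
        frac = np.mean([a.category == "known_polyadb" for a in annotated])
        n = len(annotated)
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(frac - 0.6) <= 2 * se + 1e-9


class TestTandemAndUTRLength:
    def test_novel_3utr_is_tandem(self, plus_gene):
        annot = SiteAnnotator([plus_gene])
        (ann,) = annot.mark_tandem_sites(annot.annotate([make_site(1100)]))
        assert ann.is_tandem and ann.gene_id == "gA" and ann.utr_length == 101

    def test_cds_site_not_tandem(self, plus_gene):
        annot = SiteAnnotator([plus_gene])
        (ann,) = annot.mark_tandem_sites(annot.annotate([make_site(800)]))
        assert not ann.is_tandem

    def test_opposite_strand_utr_not_matched(self, plus_gene, minus_gene):
        annot = SiteAnnotator([plus_gene, minus_gene])
        # inside gB's 3'UTR interval but on the + strand: no tandem call
        (ann,) = annot.mark_tandem_sites(annot.annotate([make_site(1800, "+")]))
        assert not ann.is_tandem

    def test_utr_length_examples(self, plus_gene, minus_gene):
        assert utr_length(make_site(1299), plus_gene) == 300
        assert utr_length(make_site(1700, "-"), minus_gene) == 300
        assert utr_length(make_site(1000), plus_gene) == 1

    def test_utr_length_strand_symmetry(self, plus_gene, minus_gene):
        """The mirrored gene pair gives identical length ladders."""
        for d in (1, 50, 299):
            assert utr_length(make_site(999 + d), plus_gene) == utr_length(
                make_site(2000 - d, "-"), minus_gene
            )


class TestBuildProfiles:
    def test_single_tandem_site_makes_no_profile(self, plus_gene):
        annot = SiteAnnotator([plus_gene])
        annotated = annot.mark_tandem_sites(annot.annotate([make_site(1100)]))
        assert build_profiles(annotated, ["s1"]) == []

    def test_two_sites_make_profile_ordered_by_length(self, plus_gene):
        annot = SiteAnnotator([plus_gene])
        sites = [
            make_site(1250, counts={"s1": 4, "s2": 1}),
            make_site(1050, counts={"s1": 3, "s2": 7}),
        ]
        annotated = annot.mark_tandem_sites(annot.annotate(sites))
        (profile,) = build_profiles(annotated, ["s1", "s2"])
        assert profile.utr_lengths == [51, 251]
        assert profile.counts.loc["s1"].tolist() == [3, 4]
        assert profile.counts.loc["s2"].tolist() == [7, 1]

    def test_duplicate_utr_length_merges_with_warning(self, plus_gene):
        import warnings

        annot = SiteAnnotator([plus_gene])
        sites = [
            make_site(1100, counts={"s1": 2}),
            make_site(1100, counts={"s1": 5}, span=(1098, 1101)),
            make_site(1250, counts={"s1": 1}),
        ]
        annotated = annot.mark_tandem_sites(annot.annotate(sites))
        with warnings.catch_warnings():
            warnings.simplefilter("error", UserWarning)
            with pytest.raises(UserWarning, match="duplicate UTR length"):
                build_profiles(annotated, ["s1"])
        profiles = build_profiles(annotated, ["s1"])
        (profile,) = profiles
        assert profile.counts.loc["s1"].tolist() == [7, 1]

    def test_profile_count_matches_truth(self, small_experiment):
        cfg, genome, genes, known, truth, records = small_experiment
        kept, _ = internal_priming_filter(
            [r for v in records.values() for r in v], GenomeSource(genome)
        )
        sites = cluster_cleavage_sites(kept)
        annot = SiteAnnotator(genes, known_polyadb=known)
        annotated = annot.mark_tandem_sites(annot.annotate(sites))
        profiles = build_profiles(annotated, cfg.case_samples + cfg.control_samples)
        # every gene's sites are deeply covered, so all genes keep >=2 sites
        assert len(profiles) == cfg.n_genes
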