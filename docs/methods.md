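# Methods

## Overview

`apaswitch` implements a 3'-end sequencing (SAPAS-style) analysis of
alternative polyadenylation (APA): one sequencing read marks one
transcript's cleavage/polyadenylation position, so the distribution of
read 3' ends across a gene's tandem poly(A) sites measures the relative
usage of its short and long 3'UTR isoforms. The pipeline takes aligned
cleavage positions (BED), a reference genome (FASTA) and gene models
(GTF/BED12), and produces poly(A)-site clusters, per-gene tandem-3'UTR
profiles, pair-wise case-control 3'UTR-switching calls, a simple
differential-expression screen, and miRNA seed-site gain/loss counts.

## Coordinate conventions

All internal coordinates are 0-based, half-open (the BED convention); GTF
is converted on read. "Downstream" is always strand-relative: increasing
coordinate on `+`, decreasing on `-`. A read's cleavage base is its last
aligned base in transcript orientation (interval end − 1 on `+`, interval
start on `-`). The stop-codon landmark is the last base of the stop codon,
derived from the CDS end in strand orientation; the 3'UTR length implied by
a poly(A) site is the strand-oriented distance from the base after the stop
codon to the site's representative position, inclusive.

## Read-level filters

**Internal-priming filter.** Oligo-dT priming at genomic A-rich tracts
produces false cleavage signals. A record is discarded when the genomic
window 1–20 nt strand-downstream of its cleavage base contains `AAAAAAAA`,
matches `G A{4,} G A{3,} G`, or contains more than 12 A's (strictly > 12,
i.e. ≥ 13). The window is evaluated on the transcribed strand
(reverse-complemented for `-` records); windows truncated at contig ends
are evaluated as-is, and records whose window cannot be extracted at all
are kept with a warning — there is no sequence evidence on which to filter
them.

**Trimming contract.** Reads entering as FASTQ may be trimmed: a trailing
run of ≥ 8 A's (the oligo-dT anchor remnant) is stripped; reads shorter
than 20 nt after trimming or with > 10% N are rejected. These three
thresholds are this package's own definition of a conventional 3'-end-read
cleanup; the pipeline's primary entry point is aligned positions, so the
trimming path is a convenience only.

**Singleton removal.** Candidate sites supported by exactly one pooled
read (across all samples) are discarded. Pooling before the threshold is
deliberate: clustering operates on the pooled read set, so support is a
property of the cluster, not of any one sample.

## Poly(A)-site clustering

Cleavage positions on the same chromosome and strand are clustered by
single-linkage chaining with a 24-nt gap threshold: consecutive sorted
positions at most 24 nt apart join one cluster. Chaining is the only
order-independent reading of "within 24 nt of each other" (it is the
transitive closure of the pairwise relation), and clusters may therefore
span more than 24 nt; no span cap is applied. Clusters with ≥ 2 pooled
reads become poly(A) sites. The representative position is the modal
cleavage base, ties broken toward the strand-proximal (5') end — a robust
choice under cleavage heterogeneity; the tests verify equivalence with a
connected-components oracle and permutation invariance.

## Site annotation and tandem-3'UTR profiles

Each site receives exactly one category by fixed priority: within 24 nt of
an annotated transcript end (`ucsc_known_end`), within 24 nt of a
user-supplied catalog site (`known_polyadb`), then the six putative-novel
attributes most-specific-first: in an annotated 3'UTR, ≤ 1 kb
strand-downstream of a gene end, in CDS, in a noncoding gene, in an
intron, intergenic. The priority order (knowns before novels, 3'UTR before
downstream before CDS, intergenic last) is this package's decision,
chosen to mirror the biological specificity of each label. Ambiguous
overlaps (two same-strand genes) resolve to the nearest feature with a
warning.

Sites whose span overlaps an annotated 3'UTR of a same-strand coding gene
(or known sites attached to a gene's terminal end) are tandem poly(A)
sites. Genes with ≥ 2 tandem sites yield a profile: sites ordered by
ascending 3'UTR length with a samples × sites count matrix. Sites of one
gene with identical UTR length are merged with summed counts.

## The switching test

For a case sample and a control sample, a gene's two count rows over its k
ordered sites form a 2 × k table. Association between group membership and
3'UTR length is scored with the linear-by-linear (Mantel–Haenszel) trend
statistic

M² = (N − 1) r²,

where r is the Pearson correlation between the 0/1 group indicator and the
column score over the N individual reads, and M² is referred to χ²(1).
Column scores are the 3'UTR lengths in nt; because r is invariant under
positive affine score transforms, rank scores give identical results for
k = 2 and differ only mildly for k > 2. The (N − 1) variance convention is
fixed and matches the classical linear-by-linear association statistic.
Degenerate margins (all reads in one group or at one site) return
r = 0, p = 1. A positive r means the case group favours longer 3'UTRs.

Within each (case, control) pair, p-values are Benjamini–Hochberg adjusted
across that pair's tested genes (the FDR family is per pair, not global,
because calls are counted per pair). A gene is tested in a pair only when
both samples carry ≥ 10 reads across its sites (config, 0 disables) — the
trend test is meaningless on near-empty tables. A gene is called a
switching gene when it is significant (q < 0.01) in ≥ 10 of the
n_case × n_control pairs (36 at the default 6 vs 6 design); direction is
the strict-majority sign of r among its significant pairs, with exact ties
reported as ambiguous. The ≥ 10 reading of the pair criterion is the
operative one and is config-exposed.

**Supersite ratios.** For comparison against isoform-ratio assays
(e.g. qPCR with proximal/distal primer sets), a gene's sites can be pooled
into a proximal and a distal supersite at a configurable split index
(default 1: first site vs the rest — no principled split rule exists when
k > 2, so the choice is exposed); the proximal/distal count ratio is
reported per sample, with zero-distal flagged as an infinite ratio.

## Differential expression

Gene expression is the sum of reads over the gene's poly(A) sites.
The DE screen is deliberately self-contained: per gene, a two-sided Fisher
exact test on the 2 × 2 table of (gene reads, library remainder) for the
pooled case vs pooled control groups, BH-adjusted across genes
(q < 0.05), with log2 fold changes on pooled counts normalised to the mean
library size plus a 0.5 pseudocount. This pooled-count test ignores
replicate dispersion, so its significance grows with depth; it is labelled
in the output metadata and is intended for the cross-tabulation of DE
status against switching direction, not as a replicate-aware DE method.

## miRNA seed sites

For each called switching gene, the 3'UTR splits at the proximal site into
a common region (stop codon → proximal site, inclusive) and an extended
region (proximal → distal site) present only in the long isoform. Mature
miRNA sequences are scanned as canonical seed matches in DNA space:
7mer-m8 (reverse complement of miRNA positions 2–8), 8mer (7mer-m8
followed by A), 7mer-A1 (reverse complement of positions 2–7 followed by
A). At one locus only the longest type is reported; a hit belongs to the
region containing its 5'-most base. Lengthened genes gain their
extended-region hits, shortened genes lose them. No context scoring or
conservation filtering is applied — the counts are pure seed matches.

## Synthetic-data generator

The generator emulates a 6-vs-6 case-control 3'-end experiment at desk
scale. Genes are tiled on one chromosome, alternating strands, each with a
300-nt CDS and 2–4 tandem poly(A) sites spaced 150–600 nt apart in the
3'UTR. Per sample and gene, read totals are negative binomial (mean 200,
dispersion size 10), with per-sample depth factors uniform in ±20%;
reads are allocated to sites multinomially and jittered uniformly within
±8 nt — inside the 24-nt cluster radius, so each true site stays one
cluster while exercising cleavage heterogeneity. Non-switching genes draw
their proximal-usage share from a Beta with mean 0.5 (concentration 10)
and split the remainder by a symmetric Dirichlet; programmed switchers
(10% of genes, half lengthening, half shortening) use proximal usage 0.7
in one group and 0.3 in the other, shifting only the proximal share.
The annotated transcript end is placed 50 nt past the distal site, so
known-site annotation is exercised purely through the catalog, which holds
a random 60% of true sites.

Two guarantees are built in as downstream oracles. First, all sequence
within the jitter-reachable downstream windows of true sites (site − 7 to
site + 28 in strand orientation) is drawn A-free, so no true read can
trigger the internal-priming rule; conversely, artifact reads are placed
immediately upstream of a planted 10-nt A tract mid-CDS (Poisson rate 5
per gene per sample in the ~30% of genes carrying a tract), so every
artifact window contains `AAAAAAAA`. Second, when a seed motif is planted
(for the miRNA gain/loss identity), it is inserted 60 nt into each
programmed-lengthened gene's extended region with guard flanks, and chance
occurrences of the same seed family are scrubbed from all simulated
3'UTRs, making the planted sites exactly countable. The scrub provably
cannot touch the protected windows: any 7-mer containing an A cannot occur
in an A-free window (and its reverse complement, containing a T, cannot
occur in the T-free windows of minus-strand genes).

What the generator does not emulate — and what passing tests therefore do
not show about real data: biological within-group usage variability (all
samples of a group share a gene's exact usage vector), sequencing errors,
multi-exon 3'UTRs and alternative last exons, overlapping genes, chimeric
or antisense reads, and any coupling between switching and expression
(the two effect channels are independent by construction, which is itself
used to test the DE × switching cross-tabulation for non-enrichment).

## Numerical and design choices

* Trend statistic computed from the 2 × k margins in closed form; verified
  to 1e−9 against Pearson correlation on expanded per-read vectors.
* BH adjustment delegates to `statsmodels` `multipletests(fdr_bh)`;
  tests pin it against a hand-coded step-up.
* r is clipped to [−1, 1] against rounding; M² uses the clipped value.
* Fisher exact tests delegate to `scipy.stats.fisher_exact`.
* Problem sizes in the verification suite — 500-gene recovery runs,
  1,000-gene null calibration, 10,000-window filter oracles — were chosen
  as the smallest scales at which the binomial error bands on the measured
  rates are informative.

## Known limitations

* The per-pair test treats reads as independent; overdispersion within a
  sample would inflate M², which is why calls require replication across
  ≥ 10 of the 36 pairs rather than a single pooled test.
* The DE stand-in is anti-conservative at high depth (see above).
* Annotation assumes a single merged 3'UTR per gene (union of annotated
  3'UTR exons); genes whose tandem sites sit in different last exons are
  out of scope.
* Cluster spans are uncapped; extremely dense data could chain distinct
  sites (not reachable at the generator's ≥ 150 nt spacing).
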