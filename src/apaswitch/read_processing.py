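"""Read-level filters applied before site calling.

Three filters run between alignment and clustering:

* an optional raw-read trimming contract (strip the oligo-dT anchor remnant,
  drop short or N-rich reads) for data entering as FASTQ;
* the internal-priming filter, which discards a cleavage record when the
  genomic window 1-20 nt strand-downstream of the cleavage base looks like a
  template for oligo-dT mispriming (an 8-nt A run, a G A{4,} G A{3,} G motif,
  or more than 12 A's in the 20-nt window);
* singleton removal — candidate sites supported by a single pooled read are
  discarded.
"""

from __future__ import annotations

import logging
import re
import warnings
from typing import Iterable, Sequence

from .core_io import CleavageRecord, GenomeSource, reverse_complement

logger = logging.getLogger("apaswitch")

_VALID_READ = re.compile(r"^[ACGTN]*$")
_TRAILING_A = re.compile(r"A{8,}$")
_GA_MOTIF = re.compile(r"GA{4,}GA{3,}G")

MIN_TRIMMED_LENGTH = 20
MAX_N_FRACTION = 0.10


def trim_raw_read(read: str) -> tuple[str, bool]:
    """Strip a trailing run of >=8 A's (the oligo-dT anchor remnant).

    Returns (trimmed read, accepted). A read is rejected when shorter than
    20 nt after trimming or when more than 10% of its trimmed bases are N.
    """
    read = read.upper()
    if not _VALID_READ.match(read):
        raise ValueError(f"read contains non-nucleotide characters: {read!r}")
    trimmed = _TRAILING_A.sub("", read)
    if len(trimmed) < MIN_TRIMMED_LENGTH:
        return trimmed, False
    if trimmed.count("N") > MAX_N_FRACTION * len(trimmed):
        return trimmed, False
    return trimmed, True


def is_internal_priming(window: str) -> bool:
    """Decide whether a downstream window indicates internal priming.

    True if the window contains ``AAAAAAAA``, matches G A{4,} G A{3,} G,
    or contains more than 12 A's in total (strictly > 12).
    """
    window = window.upper()
    if "AAAAAAAA" in window:
        return True
    if _GA_MOTIF.search(window):
        return True
    return window.count("A") > 12


def downstream_window(
    genome: GenomeSource,
    chrom: str,
    strand: str,
    position: int,
    window: tuple[int, int] = (1, 20),
) -> str:
    """Extract the strand-oriented genomic window ``window`` nt downstream of
    a cleavage base. Windows truncated at contig ends are returned as-is."""
    lo, hi = window
    if strand == "+":
        return genome.fetch(chrom, position + lo, position + hi + 1)
    return reverse_complement(genome.fetch(chrom, position - hi, position - lo + 1))


def internal_priming_filter(
    records: Iterable[CleavageRecord],
    genome: GenomeSource,
    window: tuple[int, int] = (1, 20),
) -> tuple[list[CleavageRecord], list[CleavageRecord]]:
    """Split records into (kept, filtered) by the internal-priming rule.

    A record whose window cannot be extracted at all (off-contig) is kept
    with a warning: there is no sequence evidence on which to filter it.
    """
    kept: list[CleavageRecord] = []
    filtered: list[CleavageRecord] = []
    for rec in records:
        win = downstream_window(genome, rec.chrom, rec.strand, rec.position, window)
        if not win:
            warnings.warn(
                f"empty downstream window for {rec.chrom}:{rec.position}({rec.strand});"
                " record kept"
            )
            kept.append(rec)
        elif is_internal_priming(win):
            filtered.append(rec)
        else:
            kept.append(rec)
    return kept, filtered


def remove_singletons(
    clusters: Sequence[Sequence[CleavageRecord]],
) -> list[Sequence[CleavageRecord]]:
    """Discard candidate sites supported by exactly one pooled read."""
    return [c for c in clusters if len(c) >= 2]
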