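"""Gene-level expression from poly(A)-site counts and a self-contained
differential-expression test.

A gene's expression in a sample is the sum of reads over all of its poly(A)
sites. Differential expression between the pooled case and control groups
is assessed per gene with a two-sided Fisher exact test on the 2 x 2 table

    [[case reads for gene,    case library remainder],
     [control reads for gene, control library remainder]],

with BH adjustment across genes; log2 fold changes are computed on pooled
counts normalised to a common library size, with a 0.5 pseudocount. This is
a deliberately simple pooled-count test (no replicate dispersion model) and
is labelled as such in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .site_annotation import AnnotatedSite
from .switching_analysis import GeneSwitchCall, bh_fdr

DE_METHOD_LABEL = "pooled-count Fisher exact (total-count normalised)"


@dataclass
class DEResult:
    gene_id: str
    log2_fold_change: float
    p: float
    q: float
    status: str  # up | down | ns


def accumulate_expression(
    annotated: Sequence[AnnotatedSite], samples: Sequence[str]
) -> pd.DataFrame:
    """Genes x samples table summing reads over each gene's sites.

    Any site with a gene assignment contributes, whatever its category;
    genes with no sites are absent.
    """
    totals: dict[str, np.ndarray] = {}
    for ann in annotated:
        if not ann.gene_id:
            continue
        row = totals.setdefault(ann.gene_id, np.zeros(len(samples), dtype=int))
        for i, s in enumerate(samples):
            row[i] += ann.site.counts.get(s, 0)
    df = pd.DataFrame(totals, index=list(samples), dtype=int).T
    return df.sort_index()


def exact_de_test(
    expr: pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    fdr_threshold: float = 0.05,
) -> list[DEResult]:
    """Pooled-count Fisher exact DE between case and control groups."""
    if not case_samples or not control_samples:
        raise ValueError("both sample groups must be nonempty")
    case_pooled = expr[list(case_samples)].sum(axis=1).to_numpy(dtype=np.int64)
    control_pooled = expr[list(control_samples)].sum(axis=1).to_numpy(dtype=np.int64)
    lib_case = int(case_pooled.sum())
    lib_control = int(control_pooled.sum())
    if lib_case == 0 or lib_control == 0:
        raise ValueError("zero library size in one group")

    mean_lib = 0.5 * (lib_case + lib_control)
    pvals = np.empty(len(expr))
    log2fc = np.empty(len(expr))
    for i, (c, n) in enumerate(zip(case_pooled, control_pooled)):
        table = [[int(c), lib_case - int(c)], [int(n), lib_control - int(n)]]
        pvals[i] = fisher_exact(table, alternative="two-sided")[1]
        norm_c = c * mean_lib / lib_case
        norm_n = n * mean_lib / lib_control
        log2fc[i] = np.log2((norm_c + 0.5) / (norm_n + 0.5))

    qvals = bh_fdr(pvals)
    results = []
    for gene_id, p, q, fc in zip(expr.index, pvals, qvals, log2fc):
        if q < fdr_threshold:
            status = "up" if fc > 0 else "down"
        else:
            status = "ns"
        results.append(DEResult(str(gene_id), float(fc), float(p), float(q), status))
    return results


def crosstab_de_switching(
    de: Sequence[DEResult], calls: Sequence[GeneSwitchCall]
) -> pd.DataFrame:
    """Counts of called switching genes by direction x DE status."""
    de_by_gene = {d.gene_id: d.status for d in de}
    table = pd.DataFrame(
        0,
        index=pd.Index(["lengthened", "shortened"], name="direction"),
        columns=pd.Index(["up", "down", "ns"], name="status"),
    )
    for call in calls:
        if not call.called or call.direction not in table.index:
            continue
        status = de_by_gene.get(call.gene_id, "ns")
        table.loc[call.direction, status] += 1
    return table


def de_results_table(results: Sequence[DEResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "log2_fold_change": r.log2_fold_change,
                "p": r.p,
                "q": r.q,
                "status": r.status,
            }
            for r in results
        ]
    )
    df.attrs["method"] = DE_METHOD_LABEL
    return df
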