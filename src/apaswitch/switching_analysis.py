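"""Pair-wise case-control detection of tandem-3'UTR switching.

For every (case, control) sample pair and every gene with at least two
tandem poly(A) sites, the two samples' site counts form a 2 x k contingency
table whose columns are ordered by 3'UTR length. Association between group
and UTR length is scored by the linear-by-linear (Mantel-Haenszel) trend
statistic

    M^2 = (N - 1) r^2,    r = Pearson correlation between the group
                              indicator (0 = control, 1 = case) and the
                              column score over the N individual reads,

referred to a chi-square distribution with 1 df. The sign of r gives the
direction: positive means the case sample favours longer 3'UTRs. Within
each pair, p-values are Benjamini-Hochberg adjusted across that pair's
tested genes; a gene is called a switching gene when it is significant
(q below the FDR threshold) in at least ``min_significant_pairs`` of the
n_case x n_control pairs, with direction by strict majority sign of r among
its significant pairs.

Column scores default to the UTR lengths in nt; because r is invariant
under positive affine transforms of the scores, rank scores give identical
results for two-site genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .core_io import RunConfig
from .site_annotation import TandemUTRProfile


@dataclass
class PairSwitchResult:
    gene_id: str
    case_sample: str
    control_sample: str
    r: float
    m2: float
    p: float
    q: float = math.nan
    significant: bool = False


@dataclass
class GeneSwitchCall:
    gene_id: str
    n_significant_pairs: int
    direction: str  # lengthened | shortened | ambiguous
    mean_r: float
    called: bool


def linear_trend_test(
    case_counts: Sequence[float],
    control_counts: Sequence[float],
    scores: Sequence[float],
) -> tuple[float, float, float]:
    """Linear-by-linear trend test on a 2 x k table.

    Returns (r, M^2, p). Degenerate margins (all reads in one group, or all
    reads at one site) give (0, 0, 1): no trend is estimable.
    """
    case = np.asarray(case_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    s = np.asarray(scores, dtype=float)
    if case.shape != control.shape or case.shape != s.shape:
        raise ValueError("case, control and scores must have equal length")
    k = case.size
    if k < 2:
        raise ValueError("trend test requires k >= 2 ordered sites")
    if (case < 0).any() or (control < 0).any():
        raise ValueError("negative counts")
    if np.any(np.diff(s) <= 0):
        raise ValueError("scores must be strictly increasing")

    n_case = case.sum()
    n_control = control.sum()
    n = n_case + n_control
    if n < 1:
        raise ValueError("empty table")

    col = case + control
    mean_g = n_case / n
    var_g = mean_g * (1.0 - mean_g)
    mean_s = float(col @ s) / n
    var_s = float(col @ (s - mean_s) ** 2) / n
    if var_g <= 0.0 or var_s <= 0.0:
        return 0.0, 0.0, 1.0

    # cov(g, s) = E[g*(s - E s)] since E[s - E s] = 0 and g is 0/1
    cov = float(case @ (s - mean_s)) / n
    r = cov / math.sqrt(var_g * var_s)
    r = max(-1.0, min(1.0, r))
    m2 = (n - 1.0) * r * r
    p = float(chi2.sf(m2, df=1))
    return float(r), float(m2), p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_switch_scan(
    profiles: Sequence[TandemUTRProfile],
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    config: RunConfig | None = None,
) -> list[PairSwitchResult]:
    """Run the trend test for every (case, control) pair and eligible gene.

    A gene enters a pair's test (and its BH family) only when both samples
    carry at least ``config.min_pair_reads`` reads across its sites
    (0 disables the floor).
    """
    if not case_samples or not control_samples:
        raise ValueError("both sample lists must be nonempty")
    config = config or RunConfig()
    floor = config.min_pair_reads

    # pre-extract per-profile arrays once
    gene_rows: list[tuple[str, dict[str, np.ndarray], np.ndarray]] = []
    for prof in profiles:
        missing = [
            s for s in (*case_samples, *control_samples) if s not in prof.counts.index
        ]
        if missing:
            raise ValueError(
                f"sample(s) {missing} absent from profile of {prof.gene_id}"
            )
        rows = {
            s: prof.counts.loc[s].to_numpy(dtype=float)
            for s in (*case_samples, *control_samples)
        }
        gene_rows.append((prof.gene_id, rows, np.asarray(prof.utr_lengths, dtype=float)))

    results: list[PairSwitchResult] = []
    for case in case_samples:
        for control in control_samples:
            pair_results: list[PairSwitchResult] = []
            for gene_id, rows, scores in gene_rows:
                c_row, n_row = rows[case], rows[control]
                if floor > 0 and (c_row.sum() < floor or n_row.sum() < floor):
                    continue
                r, m2, p = linear_trend_test(c_row, n_row, scores)
                pair_results.append(
                    PairSwitchResult(gene_id, case, control, r, m2, p)
                )
            if pair_results:
                q = bh_fdr([res.p for res in pair_results])
                for res, qv in zip(pair_results, q):
                    res.q = float(qv)
                    res.significant = bool(qv < config.fdr_threshold)
            results.extend(pair_results)
    return results


def aggregate_gene_calls(
    results: Sequence[PairSwitchResult],
    config: RunConfig | None = None,
) -> list[GeneSwitchCall]:
    """Aggregate per-pair outcomes into gene-level switching calls."""
    config = config or RunConfig()
    by_gene: dict[str, list[PairSwitchResult]] = {}
    for res in results:
        by_gene.setdefault(res.gene_id, []).append(res)

    calls: list[GeneSwitchCall] = []
    for gene_id in sorted(by_gene):
        sig = [r for r in by_gene[gene_id] if r.significant]
        n_sig = len(sig)
        n_pos = sum(1 for r in sig if r.r > 0)
        n_neg = sum(1 for r in sig if r.r < 0)
        if n_pos > n_sig / 2:
            direction = "lengthened"
        elif n_neg > n_sig / 2:
            direction = "shortened"
        else:
            direction = "ambiguous"
        mean_r = float(np.mean([r.r for r in sig])) if sig else math.nan
        calls.append(
            GeneSwitchCall(
                gene_id=gene_id,
                n_significant_pairs=n_sig,
                direction=direction if n_sig else "ambiguous",
                mean_r=mean_r,
                called=n_sig >= config.min_significant_pairs,
            )
        )
    return calls


def supersite_ratio(
    profile: TandemUTRProfile, split_index: int, sample: str
) -> tuple[float, bool]:
    """Proximal-to-distal supersite expression ratio for one sample.

    Sites with column index < ``split_index`` pool into the proximal
    supersite, the rest into the distal one. Returns (ratio, finite); a zero
    distal count is flagged as an infinite ratio (ratio = inf, finite =
    False).
    """
    k = profile.counts.shape[1]
    if not (1 <= split_index < k):
        raise ValueError(f"split_index must lie in [1, {k - 1}]")
    row = profile.counts.loc[sample].to_numpy(dtype=float)
    proximal = float(row[:split_index].sum())
    distal = float(row[split_index:].sum())
    if distal == 0.0:
        return math.inf, False
    return proximal / distal, True


def pair_results_table(results: Sequence[PairSwitchResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "case_sample": r.case_sample,
                "control_sample": r.control_sample,
                "r": r.r,
                "m2": r.m2,
                "p": r.p,
                "q": r.q,
                "significant": int(r.significant),
            }
            for r in results
        ]
    )


def gene_calls_table(calls: Sequence[GeneSwitchCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "n_significant_pairs": c.n_significant_pairs,
                "direction": c.direction,
                "mean_r": c.mean_r,
                "called": int(c.called),
            }
            for c in calls
        ]
    )
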