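import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from apaswitch.core_io import RunConfig
from apaswitch.site_annotation import TandemUTRProfile
from apaswitch.switching_analysis import (
    GeneSwitchCall,
    PairSwitchResult,
    aggregate_gene_calls,
    bh_fdr,
    linear_trend_test,
    pairwise_switch_scan,
    supersite_ratio,
)


def oracle_trend(case, control, scores):
    """Brute force: Pearson r over the N expanded (group, score) reads."""
    g = np.concatenate([np.ones(int(sum(case))), np.zeros(int(sum(control)))])
    s = np.concatenate(
        [
            np.repeat(scores, np.asarray(case, int)),
            np.repeat(scores, np.asarray(control, int)),
        ]
    ).astype(float)
    if g.std() == 0 or s.std() == 0:
        return 0.0, 0.0
    r = float(np.corrcoef(g, s)[0, 1])
    return r, (len(g) - 1) * r * r


def hand_coded_bh(p):
    """Textbook step-up: p(i) * m / i with monotone enforcement."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def make_profile(gene_id, rows, utr_lengths):
    """rows: {sample: [counts per site]}"""
    counts = pd.DataFrame(rows, index=[f"site{i}" for i in range(len(utr_lengths))]).T
    from apaswitch.polya_clustering import PolyASite
    from apaswitch.core_io import GenomicInterval
    from apaswitch.site_annotation import AnnotatedSite

    sites = []
    for i, ul in enumerate(utr_lengths):
        ps = PolyASite(
            "chr1", "+", GenomicInterval("chr1", 1000 + ul, 1001 + ul, "+"),
            1000 + ul, {s: int(v[i]) for s, v in rows.items()},
        )
        sites.append(
            AnnotatedSite(ps, "novel_3utr", gene_id, True, ul)
        )
    return TandemUTRProfile(gene_id, sites, list(utr_lengths), counts.astype(int))


class TestLinearTrendTest:
    def test_perfect_separation(self):
        r, m2, p = linear_trend_test([0, 10], [10, 0], [0, 1])
        assert r == pytest.approx(1.0)
        assert m2 == pytest.approx(19.0)
        assert p == pytest.approx(float(chi2.sf(19.0, 1)))

    def test_identical_distributions(self):
        r, m2, p = linear_trend_test([5, 5], [5, 5], [300, 800])
        assert (r, m2, p) == (0.0, 0.0, 1.0)

    def test_affine_score_invariance(self):
        r1, m1, p1 = linear_trend_test([3, 7], [7, 3], [0, 1])
        r2, m2, p2 = linear_trend_test([3, 7], [7, 3], [300, 800])
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert m1 == pytest.approx(m2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_negative_affine_flips_sign_only(self):
        r1, m1, p1 = linear_trend_test([3, 7, 5], [7, 3, 5], [1, 2, 4])
        r2, m2, p2 = linear_trend_test([5, 7, 3], [5, 3, 7], [-4, -2, -1])
        assert r2 == pytest.approx(-r1, abs=1e-12)
        assert m2 == pytest.approx(m1, abs=1e-9)

    def test_antisymmetry_in_groups(self):
        r1, m1, p1 = linear_trend_test([2, 9, 4], [8, 1, 6], [10, 20, 50])
        r2, m2, p2 = linear_trend_test([8, 1, 6], [2, 9, 4], [10, 20, 50])
        assert r2 == pytest.approx(-r1, abs=1e-12)
        assert m2 == pytest.approx(m1, abs=1e-9)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_degenerate_group_margin(self):
        assert linear_trend_test([0, 0], [5, 5], [0, 1]) == (0.0, 0.0, 1.0)

    def test_degenerate_site_margin(self):
        assert linear_trend_test([5, 0], [7, 0], [0, 1]) == (0.0, 0.0, 1.0)

    def test_matches_expanded_vector_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            k = int(rng.integers(2, 6))
            case = rng.integers(0, 40, k)
            control = rng.integers(0, 40, k)
            if case.sum() + control.sum() == 0:
                continue
            scores = np.sort(
                rng.choice(np.arange(1, 3000), size=k, replace=False)
            ).astype(float)
            r, m2, _ = linear_trend_test(case, control, scores)
            ro, m2o = oracle_trend(case, control, scores)
            assert abs(r - ro) < 1e-9 and abs(m2 - m2o) < 1e-9

    @pytest.mark.parametrize(
        "case,control,scores,err",
        [
            ([5], [5], [1], "k >= 2"),
            ([5, -1], [5, 5], [0, 1], "negative"),
            ([5, 5], [5, 5], [1, 1], "strictly increasing"),
        ],
    )
    def test_input_validation(self, case, control, scores, err):
        with pytest.raises(ValueError, match=err):
            linear_trend_test(case, control, scores)


class TestBHFDR:
    def test_textbook_example(self):
        q = bh_fdr([0.001, 0.02, 0.04, 0.9])
        assert np.allclose(q, [0.004, 0.04, 0.04 * 4 / 3, 0.9])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_hand_coded_step_up(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 60)))
            assert np.allclose(bh_fdr(p), hand_coded_bh(p), atol=1e-12)


class TestPairwiseScan:
    def test_exactly_36_pairs_for_6v6(self):
        rows = {f"case_{i}": [30, 70] for i in range(1, 7)}
        rows.update({f"control_{i}": [70, 30] for i in range(1, 7)})
        prof = make_profile("g1", rows, [100, 400])
        res = pairwise_switch_scan(
            [prof], list(rows)[:6], list(rows)[6:], RunConfig()
        )
        assert len(res) == 36
        assert len({(r.case_sample, r.control_sample) for r in res}) == 36

    def test_read_floor_excludes_gene_from_pair_family(self):
        rows = {
            "c1": [30, 70],
            "c2": [3, 4],  # below the 10-read floor
            "n1": [70, 30],
        }
        prof = make_profile("g1", rows, [100, 400])
        res = pairwise_switch_scan([prof], ["c1", "c2"], ["n1"], RunConfig())
        assert {(r.case_sample, r.control_sample) for r in res} == {("c1", "n1")}

    def test_floor_zero_disables(self):
        rows = {"c1": [1, 1], "n1": [1, 1]}
        prof = make_profile("g1", rows, [100, 400])
        res = pairwise_switch_scan(
            [prof], ["c1"], ["n1"], RunConfig(min_pair_reads=0)
        )
        assert len(res) == 1

    def test_missing_sample_errors(self):
        prof = make_profile("g1", {"c1": [5, 5], "n1": [5, 5]}, [100, 400])
        with pytest.raises(ValueError, match="absent"):
            pairwise_switch_scan([prof], ["c1"], ["n_missing"], RunConfig())

    def test_q_values_adjusted_within_pair(self):
        profs = [
            make_profile(f"g{i}", {"c1": [50, 50], "n1": [50, 50]}, [100, 400])
            for i in range(5)
        ] + [make_profile("gx", {"c1": [95, 5], "n1": [5, 95]}, [100, 400])]
        res = pairwise_switch_scan(profs, ["c1"], ["n1"], RunConfig())
        by_gene = {r.gene_id: r for r in res}
        ps = [by_gene[g].p for g in by_gene]
        qs = [by_gene[g].q for g in by_gene]
        assert np.allclose(qs, hand_coded_bh(ps))
        assert by_gene["gx"].significant


class TestAggregateGeneCalls:
    @staticmethod
    def results(gene, n_sig, rs, n_total=36):
        out = [
            PairSwitchResult(gene, f"c{i}", "n1", r, 10.0, 1e-5, 1e-4, True)
            for i, r in enumerate(rs[:n_sig])
        ]
        out += [
            PairSwitchResult(gene, f"c{i}", "n2", 0.0, 0.0, 1.0, 1.0, False)
            for i in range(n_total - n_sig)
        ]
        return out

    def test_called_lengthened(self):
        (call,) = aggregate_gene_calls(self.results("g1", 12, [0.5] * 12))
        assert call.called and call.direction == "lengthened"
        assert call.n_significant_pairs == 12
        assert call.mean_r == pytest.approx(0.5)

    def test_nine_pairs_not_called(self):
        (call,) = aggregate_gene_calls(self.results("g1", 9, [0.5] * 9))
        assert not call.called

    def test_exact_tie_is_ambiguous(self):
        (call,) = aggregate_gene_calls(
            self.results("g1", 10, [0.5] * 5 + [-0.5] * 5)
        )
        assert call.called and call.direction == "ambiguous"

    def test_majority_negative_is_shortened(self):
        (call,) = aggregate_gene_calls(
            self.results("g1", 11, [-0.4] * 8 + [0.4] * 3)
        )
        assert call.direction == "shortened"


class TestSupersiteRatio:
    def test_examples(self):
        prof = make_profile("g1", {"s1": [30, 10], "s2": [0, 10], "s3": [10, 0]}, [100, 400])
        assert supersite_ratio(prof, 1, "s1") == (3.0, True)
        assert supersite_ratio(prof, 1, "s2") == (0.0, True)
        ratio, finite = supersite_ratio(prof, 1, "s3")
        assert math.isinf(ratio) and not finite

    def test_split_index_bounds(self):
        prof = make_profile("g1", {"s1": [1, 2]}, [100, 400])
        with pytest.raises(ValueError):
            supersite_ratio(prof, 0, "s1")
        with pytest.raises(ValueError):
            supersite_ratio(prof, 2, "s1")
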