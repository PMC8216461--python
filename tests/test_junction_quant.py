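"""Anchor-junction classification, inclusion percentages, group comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methsplice.junction_quant import (
    JunctionClass,
    JunctionRecord,
    classify_junction,
    compare_inclusion,
    enumerate_anchor_junctions,
    inclusion_percentage,
    merge_junctions,
    read_junction_table,
)
from methsplice.synthetic_data import (
    SimConfig,
    expected_inclusion_pct,
    simulate_gene,
    simulate_junction_counts,
    write_sj_tab,
)

from conftest import make_junction


# ---------------------------------------------------------------------------
# readers

class TestReaders:
    def test_sj_tab_coordinate_conversion(self, tmp_path):
        p = tmp_path / "s1.SJ.tab"
        p.write_text("chr1\t1001\t1500\t1\t0\t1\t12\t3\t20\n")
        (j,) = read_junction_table(p, dialect="sj_tab")
        assert (j.intron_start, j.intron_end) == (1000, 1500)
        assert j.counts == {"s1": 12}  # unique reads only; multimappers ignored
        assert j.strand == "+"

    def test_bed_dialect_equivalent(self, tmp_path):
        sj = tmp_path / "a.SJ.tab"
        sj.write_text("chr1\t1001\t1500\t1\t0\t1\t12\t3\t20\n")
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t1000\t1500\tj1\t12\t+\n")
        (x,) = read_junction_table(sj, dialect="sj_tab")
        (y,) = read_junction_table(bed, dialect="bed")
        assert x.key == y.key and x.counts == y.counts and x.strand == y.strand

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        p = tmp_path / "empty.SJ.tab"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert read_junction_table(p) == []
        assert "empty" in caplog.text

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.SJ.tab"
        p.write_text("chr1\t1001\t1500\t1\t0\t1\t12\t3\t20\nchr1\tnotanint\n")
        with pytest.raises(ValueError, match=":2"):
            read_junction_table(p)

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "neg.SJ.tab"
        p.write_text("chr1\t1001\t1500\t1\t0\t1\t-3\t0\t20\n")
        with pytest.raises(ValueError, match="negative"):
            read_junction_table(p)

    def test_sj_tab_write_read_round_trip(self, model, tmp_path):
        cfg = SimConfig(seed=5, n_samples=2)
        junctions, groups = simulate_junction_counts(model, cfg)
        sample = groups.index[0]
        p = tmp_path / f"{sample}.SJ.tab"
        write_sj_tab(junctions, sample, p)
        back = read_junction_table(p, sample=sample)
        orig = {j.key: j.counts.get(sample, 0) for j in junctions}
        assert {j.key: j.counts[sample] for j in back} == orig


# ---------------------------------------------------------------------------
# classification

class TestClassify:
    @pytest.mark.parametrize(
        "donor, acceptor, expected",
        [
            ("C5", "v3", JunctionClass.INCLUSION),   # anchor to variant
            ("v6", "C16", JunctionClass.OTHER),      # anchor C5 not involved
            ("C5", "C16", JunctionClass.SKIPPING),   # fully skipped isoform
            ("v6", "v7", JunctionClass.OTHER),       # variant-variant
            ("C4", "C5", JunctionClass.OTHER),       # same-side constant
        ],
    )
    def test_anchor_classification(self, model, anchor, donor, acceptor, expected):
        j = make_junction(model, donor, acceptor, {"s": 1})
        assert classify_junction(j, model, anchor) is expected

    def test_c16_anchor_symmetry(self, model):
        c16 = model.exon("C16")
        inc = make_junction(model, "v10", "C16", {"s": 1})
        skp = make_junction(model, "C5", "C16", {"s": 1})
        assert classify_junction(inc, model, c16) is JunctionClass.INCLUSION
        assert classify_junction(skp, model, c16) is JunctionClass.SKIPPING

    def test_intronic_boundary_is_other(self, model, anchor):
        c5 = model.exon("C5")
        j = JunctionRecord(model.chrom, c5.end, c5.end + 50, model.strand, {"s": 1})
        assert classify_junction(j, model, anchor) is JunctionClass.OTHER

    def test_wrong_strand_is_other_but_unknown_matches(self, model, anchor):
        v3 = model.exon("v3")
        c5 = model.exon("C5")
        minus = JunctionRecord(model.chrom, c5.end, v3.start, "-", {"s": 1})
        unknown = JunctionRecord(model.chrom, c5.end, v3.start, "?", {"s": 1})
        assert classify_junction(minus, model, anchor) is JunctionClass.OTHER
        assert classify_junction(unknown, model, anchor) is JunctionClass.INCLUSION


class TestEnumerate:
    def test_per_sample_detection_filter(self, model):
        j1 = make_junction(model, "C5", "v3", {"s1": 1, "s2": 10})
        j2 = make_junction(model, "C5", "C16", {"s1": 5, "s2": 5})
        ajs = enumerate_anchor_junctions([j1, j2], model, "C5", min_reads=2)
        res = inclusion_percentage(ajs)
        # s1: v3 junction below detection -> pure skipping
        assert res.table.loc["s1", "inclusion_pct"] == 0.0
        assert res.table.loc["s2", "inclusion_pct"] == pytest.approx(100 * 10 / 15)

    def test_min_reads_monotone(self, model, toy_junctions):
        kept = []
        for mr in (1, 2, 5, 11, 36):
            ajs = enumerate_anchor_junctions(toy_junctions, model, "C5", min_reads=mr)
            res = inclusion_percentage(ajs)
            kept.append(res.table.loc["s1", "total_reads"])
        assert kept == sorted(kept, reverse=True)

    def test_unknown_anchor_errors(self, model, toy_junctions):
        with pytest.raises(KeyError):
            enumerate_anchor_junctions(toy_junctions, model, "C99")


# ---------------------------------------------------------------------------
# inclusion percentage

class TestInclusionPercentage:
    def test_hand_computed_value(self, model, toy_junctions):
        ajs = enumerate_anchor_junctions(toy_junctions, model, "C5")
        res = inclusion_percentage(ajs)
        assert res.table.loc["s1", "inclusion_pct"] == pytest.approx(30.0)
        assert res.table.loc["s1", "skipping_pct"] == pytest.approx(70.0)

    def test_all_skipping_gives_zero(self, model):
        j = make_junction(model, "C5", "C16", {"s": 40})
        res = inclusion_percentage(enumerate_anchor_junctions([j], model, "C5"))
        assert res.table.loc["s", "inclusion_pct"] == 0.0

    def test_equal_reads_give_fifty(self, model):
        js = [
            make_junction(model, "C5", "v3", {"s": 7}),
            make_junction(model, "C5", "C16", {"s": 7}),
        ]
        res = inclusion_percentage(enumerate_anchor_junctions(js, model, "C5"))
        assert res.table.loc["s", "inclusion_pct"] == pytest.approx(50.0)

    def test_zero_denominator_reported_missing(self, model):
        j = make_junction(model, "C5", "v3", {"s": 1})  # below min_reads=2
        res = inclusion_percentage(enumerate_anchor_junctions([j], model, "C5"))
        assert np.isnan(res.table.loc["s", "inclusion_pct"])

    def test_sums_to_hundred_and_order_invariant(self, model):
        rng = np.random.default_rng(7)
        js = [
            make_junction(model, "C5", f"v{i}", {"s": int(rng.integers(2, 100))})
            for i in range(2, 11)
        ] + [make_junction(model, "C5", "C16", {"s": 55})]
        res = inclusion_percentage(enumerate_anchor_junctions(js, model, "C5"))
        assert (
            res.table.loc["s", "inclusion_pct"] + res.table.loc["s", "skipping_pct"]
        ) == pytest.approx(100.0, abs=1e-9)
        shuffled = js[::-1]
        res2 = inclusion_percentage(enumerate_anchor_junctions(shuffled, model, "C5"))
        assert res2.table.loc["s", "inclusion_pct"] == res.table.loc["s", "inclusion_pct"]

    @given(scale=st.integers(min_value=1, max_value=50))
    @settings(max_examples=20, deadline=None)
    def test_count_scaling_invariance(self, scale):
        model = simulate_gene()
        js = [
            make_junction(model, "C5", "v3", {"s": 10 * scale}),
            make_junction(model, "C5", "C16", {"s": 35 * scale}),
        ]
        res = inclusion_percentage(enumerate_anchor_junctions(js, model, "C5"))
        assert res.table.loc["s", "inclusion_pct"] == pytest.approx(100 * 10 / 45)

    def test_junction_weighted_mode(self, model, toy_junctions):
        ajs = enumerate_anchor_junctions(toy_junctions, model, "C5")
        res = inclusion_percentage(ajs, weight="junctions")
        # 2 inclusion junctions of 3 detected
        assert res.table.loc["s1", "inclusion_pct"] == pytest.approx(100 * 2 / 3)

    def test_converges_to_simulated_mixture(self, model):
        cfg = SimConfig(seed=11, n_samples=4, depth=2e4)
        junctions, groups = simulate_junction_counts(model, cfg)
        res = inclusion_percentage(enumerate_anchor_junctions(junctions, model, "C5"))
        for g in ("A", "B"):
            samp = [s for s in groups.index if groups[s] == g]
            got = res.table.loc[samp, "inclusion_pct"].mean()
            assert got == pytest.approx(expected_inclusion_pct(cfg, g), abs=1.5)


# ---------------------------------------------------------------------------
# group comparison

def brute_force_signed_rank_p(diffs, alternative="two-sided"):
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, dtype=float)
    if alternative == "greater":
        return np.mean(ws >= w_obs)
    if alternative == "less":
        return np.mean(ws <= w_obs)
    return min(1.0, 2 * min(np.mean(ws >= w_obs), np.mean(ws <= w_obs)))


class TestCompareInclusion:
    def test_exact_wilcoxon_matches_full_enumeration(self):
        a = np.array([30.0, 42.0, 55.0, 61.0, 47.0])
        b = np.array([25.0, 44.0, 40.0, 50.0, 30.0])
        res = compare_inclusion(a, b, design="paired", test="wilcoxon_signed_rank")
        assert res.pvalue == pytest.approx(brute_force_signed_rank_p(a - b))

    def test_exact_wilcoxon_enumeration_eight_pairs_one_tailed(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(20, 80, 8)
        b = a - rng.uniform(-5, 15, 8)
        res = compare_inclusion(
            a, b, design="paired", test="wilcoxon_signed_rank",
            tails="one", alternative="greater",
        )
        assert res.pvalue == pytest.approx(
            brute_force_signed_rank_p(a - b, alternative="greater")
        )

    def test_identical_vectors_give_p_one(self):
        a = np.array([10.0, 20.0, 30.0])
        with pytest.warns(UserWarning, match="zero"):
            res = compare_inclusion(a, a, design="paired", test="wilcoxon_signed_rank")
        assert res.pvalue == 1.0 and res.degenerate

    def test_constant_nonzero_differences_flagged(self):
        a = np.array([2.0, 3.0])
        b = np.array([1.0, 2.0])
        with pytest.warns(UserWarning, match="variance"):
            res = compare_inclusion(a, b, design="paired", test="t")
        assert res.degenerate and np.isnan(res.pvalue)

    def test_too_few_observations_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_inclusion([1.0], [2.0], design="paired", test="t")

    def test_wilcoxon_requires_paired(self):
        with pytest.raises(ValueError, match="paired"):
            compare_inclusion([1, 2, 3], [4, 5, 6], design="unpaired",
                              test="wilcoxon_signed_rank")

    def test_unpaired_t_runs(self):
        res = compare_inclusion([1, 2, 3, 4], [5, 6, 7, 9], design="unpaired", test="t")
        assert 0 <= res.pvalue <= 1


class TestMerge:
    def test_merge_combines_sample_counts(self, model):
        a = [make_junction(model, "C5", "v3", {"s1": 3})]
        b = [make_junction(model, "C5", "v3", {"s2": 5})]
        (m,) = merge_junctions([a, b])
        assert m.counts == {"s1": 3, "s2": 5}
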