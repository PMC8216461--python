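"""%input quantification, TMM factors, DMR calling, locus-group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methsplice.methylation import (
    MethylProfile,
    aggregate_rois,
    call_dmrs,
    compare_locus_groups,
    default_locus_groups,
    medip_percent_input,
    tiling_rois,
    tmm_factors,
    tmm_log2_cpm,
)
from methsplice.synthetic_data import SimConfig, merge_truth_regions, simulate_gene, simulate_methylation


class TestPercentInput:
    def test_equal_ip_and_input_is_hundred(self):
        out = medip_percent_input(pd.Series([2.0]), pd.Series([2.0]))
        assert out.iloc[0] == 100.0

    def test_hand_computed(self):
        out = medip_percent_input(pd.Series([0.0, 2.0]), pd.Series([5.0, 40.0]))
        assert out.tolist() == [0.0, 5.0]

    def test_zero_input_flagged_missing(self):
        out = medip_percent_input(pd.Series([1.0]), pd.Series([0.0]))
        assert np.isnan(out.iloc[0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            medip_percent_input(pd.Series([-1.0]), pd.Series([2.0]))


def brute_force_tmm(obs, ref, trim_m=0.30, trim_a=0.05):
    """Independent trimmed-mean-of-M implementation: explicit rank loops,
    no vectorized shortcuts shared with the package code."""
    obs = np.asarray(obs, float)
    ref = np.asarray(ref, float)
    n_obs, n_ref = obs.sum(), ref.sum()
    rows = [
        (o, r) for o, r in zip(obs, ref) if o > 0 and r > 0
    ]
    ms, as_, ws = [], [], []
    for o, r in rows:
        po, pr = o / n_obs, r / n_ref
        ms.append(np.log2(po / pr))
        as_.append(0.5 * np.log2(po * pr))
        ws.append(1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)))
    if not ms:
        return 1.0
    if max(ms) - min(ms) < 1e-10:
        return 2.0 ** ms[0]
    n = len(ms)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(ms)
    rank_a = stats.rankdata(as_)
    num = den = 0.0
    for i in range(n):
        if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
            num += ws[i] * ms[i]
            den += ws[i]
    return 1.0 if den == 0 else 2.0 ** (num / den)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 200, 40, 7, 90, 33, 12, 61, 25])
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_doubled_column_equalizes_cpm(self):
        col = np.array([5, 10, 200, 40, 7, 90, 33, 12, 61, 25])
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        log_cpm = tmm_log2_cpm(counts, pseudocount=0.0)
        # identical composition: normalized values must agree exactly
        assert np.allclose(log_cpm["a"], log_cpm["b"])
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(1, 400, size=(30, 4)),
                              columns=list("abcd"))
        f1 = tmm_factors(counts, reference="a")
        f2 = tmm_factors(counts.sample(frac=1, random_state=1), reference="a")
        assert np.allclose(f1, f2)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_on_toy_matrices(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(10, 3)), columns=["a", "b", "c"]
        )
        f = tmm_factors(counts, reference="a")
        raw = np.array(
            [brute_force_tmm(counts[c].values, counts["a"].values) for c in counts]
        )
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(f.values, expected)

    def test_all_zero_sample_errors(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(counts)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.integers(1, 300, size=(50, 5)))
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)


def null_profile(n_bins=200, n_per_group=6, mu=125.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 1 / 0.1
    cols = {}
    groups = {}
    for g in ("A", "B"):
        for i in range(n_per_group):
            s = f"{g}{i+1}"
            cols[s] = rng.negative_binomial(n, n / (n + mu), size=n_bins)
            groups[s] = g
    bins = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n_bins) * 100,
         "end": (np.arange(n_bins) + 1) * 100,
         "label": [f"b{i}" for i in range(n_bins)]}
    )
    return MethylProfile(bins=bins, counts=pd.DataFrame(cols),
                         groups=pd.Series(groups))


class TestCallDMRs:
    def test_identical_distributions_no_significant(self):
        prof = null_profile(n_bins=50, seed=5)
        dmrs = call_dmrs(prof, prof.bins, "A", "B")
        assert sum(d.significant for d in dmrs) == 0
        assert abs(np.mean([d.log2fc for d in dmrs])) < 0.2

    def test_bonferroni_arithmetic(self):
        prof = null_profile(n_bins=5, seed=6)
        dmrs = call_dmrs(prof, prof.bins, "A", "B")
        for d in dmrs:
            assert d.p_adj == pytest.approx(min(1.0, d.p_raw * 5))
            assert d.p_adj >= d.p_raw
        # strict inequality: p_adj equal to alpha must not be significant
        assert all(d.significant == (d.p_adj < 0.05) for d in dmrs)
        alpha_edge = [d for d in dmrs if d.p_adj >= 0.05]
        assert all(not d.significant for d in alpha_edge)

    def test_null_false_positive_rate_calibrated(self):
        hits = total = 0
        for seed in range(10):
            prof = null_profile(n_bins=200, seed=seed)
            dmrs = call_dmrs(prof, prof.bins, "A", "B")
            hits += sum(d.p_raw < 0.05 for d in dmrs)
            total += len(dmrs)
        assert 0.03 <= hits / total <= 0.07

    def test_bonferroni_family_error_controlled(self):
        sig = 0
        for seed in range(10):
            prof = null_profile(n_bins=200, seed=seed)
            sig += sum(d.significant for d in call_dmrs(prof, prof.bins, "A", "B"))
        # family-wise alpha 0.05 over 10 null families
        assert sig <= 2

    def test_planted_fourfold_depletion_is_significant_hypo(self):
        model = simulate_gene()
        cfg = SimConfig(seed=2)  # meth 0.2 vs 0.8: 4-fold depletion in A
        profile, truth = simulate_methylation(model, cfg)
        regions = merge_truth_regions(truth)
        background = tiling_rois(
            model.chrom, int(profile.bins["start"].min()),
            int(profile.bins["end"].max()), width=500,
        )
        rois = pd.concat(
            [background, regions[["chrom", "start", "end", "label"]]],
            ignore_index=True,
        )
        dmrs = call_dmrs(profile, rois, "A", "B")
        planted = [d for d in dmrs if d.label.startswith("region")]
        assert planted, "truth regions present"
        assert all(d.significant and d.direction == "hypo" for d in planted)

    def test_no_direction_flips_among_significant_bins(self):
        model = simulate_gene()
        for seed in (0, 1, 2):
            cfg = SimConfig(seed=seed)
            profile, truth = simulate_methylation(model, cfg)
            dmrs = call_dmrs(profile, profile.bins, "A", "B")
            truth_starts = set(truth["start"])
            sig_planted = [
                d for d in dmrs if d.significant and d.start in truth_starts
            ]
            assert sig_planted and all(d.direction == "hypo" for d in sig_planted)

    def test_empty_roi_list_errors(self):
        prof = null_profile(n_bins=5)
        with pytest.raises(ValueError, match="empty"):
            call_dmrs(prof, prof.bins.iloc[:0], "A", "B")

    def test_aggregation_sums_overlapping_bins(self):
        prof = null_profile(n_bins=4, seed=1)
        roi = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [400]})
        agg = aggregate_rois(prof, roi)
        assert np.array_equal(agg.values[0], prof.counts.values.sum(axis=0))


class TestLocusGroups:
    @pytest.fixture
    def panel(self):
        loci = ["C2", "C5", "C16", "v3", "v6", "v8", "i10", "i11", "i15"]
        rng = np.random.default_rng(8)
        data = pd.DataFrame(
            {
                "WT": rng.uniform(1, 10, len(loci)),
            },
            index=loci,
        )
        # consistent per-locus loss of signal in the demethylated line
        data["DKO"] = data["WT"] - 0.9 + rng.normal(0, 0.05, len(loci))
        data["SAME"] = data["WT"]
        return data

    def test_group_definitions_cover_panel_rows(self, panel):
        gd = default_locus_groups(panel.index)
        assert set(gd) == {
            "all_loci", "constant_exons", "variant_region_incl_introns",
            "variant_exons_only", "introns_only",
        }
        assert gd["variant_exons_only"] == ["v3", "v6", "v8"]
        assert gd["introns_only"] == ["i10", "i11", "i15"]
        assert set(gd["variant_region_incl_introns"]) == set(
            gd["variant_exons_only"] + gd["introns_only"]
        )

    def test_identical_cellline_reported_nonsignificant(self, panel):
        gd = default_locus_groups(panel.index)
        table = compare_locus_groups(panel, gd, baseline="WT")
        assert (table["SAME"] == 1.0).all()

    def test_depleted_cellline_significant(self, panel):
        gd = default_locus_groups(panel.index)
        table = compare_locus_groups(panel, gd, baseline="WT")
        assert (table["DKO"] < 0.05).all()

    def test_two_tailed_symmetry(self, panel):
        gd = default_locus_groups(panel.index)
        p1 = compare_locus_groups(panel[["WT", "DKO"]], gd, baseline="WT")["DKO"]
        swapped = panel[["WT", "DKO"]].rename(columns={"WT": "DKO", "DKO": "WT"})
        p2 = compare_locus_groups(swapped, gd, baseline="WT")["DKO"]
        assert np.allclose(p1.values, p2.values)

    def test_small_group_errors(self, panel):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_locus_groups(panel, {"tiny": ["C2"]}, baseline="WT")
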