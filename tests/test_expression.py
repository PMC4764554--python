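"""Normalization chain, per-gene ANOVA, and protection-set classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway

from nmdshield import expression as ex
from nmdshield import stats


def make_table(counts: dict, replicates=3) -> ex.CountTable:
    rows = []
    for cond in ex.CONDITIONS:
        for rep in range(1, replicates + 1):
            rows.append({"sample": f"{cond}_{rep}", "condition": cond, "replicate": rep})
    design = pd.DataFrame(rows).set_index("sample")
    df = pd.DataFrame(counts, index=design.index).T
    return ex.CountTable(counts=df, design=design)


class TestRpkm:
    def test_unit_case(self):
        t = make_table({"g1": [10] * 12})
        rpkm = ex.compute_rpkm(t, {"g1": 1000}, {s: 1e6 for s in t.counts.columns})
        assert np.allclose(rpkm.values, 10.0)

    def test_scale_invariance_under_joint_doubling(self):
        t1 = make_table({"g1": [25] * 12, "g2": [100] * 12})
        t2 = make_table({"g1": [50] * 12, "g2": [200] * 12})
        lengths = {"g1": 500, "g2": 2000}
        r1 = ex.compute_rpkm(t1, lengths)
        r2 = ex.compute_rpkm(t2, lengths)
        assert np.allclose(r1.values, r2.values)

    def test_hand_arithmetic(self):
        t = make_table({"g1": [25] * 12})
        rpkm = ex.compute_rpkm(t, {"g1": 500}, {s: 2e6 for s in t.counts.columns})
        assert np.allclose(rpkm.values, 25.0)  # 25 / 0.5 / 2

    def test_missing_length_drops_gene(self):
        t = make_table({"g1": [10] * 12, "g2": [10] * 12})
        rpkm = ex.compute_rpkm(t, {"g1": 1000})
        assert list(rpkm.index) == ["g1"]


class TestUpperQuartile:
    def test_identical_samples_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        out = ex.upper_quartile_normalize(m)
        assert np.allclose(out.values, m.values)

    def test_equalizes_positive_75th_percentiles(self, rng):
        m = pd.DataFrame(rng.lognormal(0, 1, (200, 4)) * [1, 2, 5, 0.5])
        out = ex.upper_quartile_normalize(m)
        uqs = [
            stats.percentile(out[c].values[out[c].values > 0], 0.75)
            for c in out.columns
        ]
        assert np.allclose(uqs, uqs[0], rtol=1e-12)

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.lognormal(0, 1, (100, 3)) * [1, 3, 0.2])
        once = ex.upper_quartile_normalize(m)
        twice = ex.upper_quartile_normalize(once)
        assert np.allclose(once.values, twice.values, rtol=1e-12)

    def test_percentile_convention(self):
        assert stats.percentile([1, 2, 3, 4], 0.75) == pytest.approx(3.25)

    def test_all_zero_sample_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        with pytest.raises(ValueError):
            ex.upper_quartile_normalize(m)


class TestLog2Transform:
    @pytest.mark.parametrize("x, expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_values(self, x, expected):
        m = pd.DataFrame({"a": [x]})
        assert ex.log2_transform(m).iloc[0, 0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ex.log2_transform(pd.DataFrame({"a": [-1.0]}))


class TestFilterLowCounts:
    def test_threshold_is_inclusive_keep(self):
        # totals: 24, 25, 120
        t = make_table({"g24": [2] * 12, "g25": [2] * 11 + [3], "g100": [10] * 12})
        kept = ex.filter_low_counts(t, min_reads=25)
        assert set(kept.counts.index) == {"g25", "g100"}

    def test_zero_threshold_is_identity(self):
        t = make_table({"g1": [0] * 12, "g2": [1] * 12})
        assert ex.filter_low_counts(t, 0).counts.shape == t.counts.shape

    def test_all_below_threshold_gives_empty(self):
        t = make_table({"g1": [0] * 12})
        assert ex.filter_low_counts(t, 25).counts.empty


class TestDifferentialAnova:
    def test_matches_scipy_per_gene(self, rng):
        t = make_table({f"g{i}": rng.integers(10, 1000, 12) for i in range(20)})
        norm = np.log2(t.counts + 1.0)
        d = ex.differential_anova(norm, t.design)
        groups = {
            c: [s for s in norm.columns if t.design.loc[s, "condition"] == c]
            for c in ex.CONDITIONS
        }
        for g in norm.index:
            F, p = f_oneway(*[norm.loc[g, ss].values for ss in groups.values()])
            assert d.loc[g, "F"] == pytest.approx(F, abs=1e-10)
            assert d.loc[g, "p_anova"] == pytest.approx(p, abs=1e-10)

    def test_fold_changes_are_mean_log2_differences(self):
        vals = {}
        for cond, level in zip(ex.CONDITIONS, [8.0, 8.0, 4.0, 8.0]):
            for rep in range(1, 4):
                vals[f"{cond}_{rep}"] = level
        norm = pd.DataFrame(vals, index=["g1"])
        design = make_table({"g1": [0] * 12}).design
        d = ex.differential_anova(norm, design)
        assert d.loc["g1", "fc_ptb"] == pytest.approx(-4.0)
        assert d.loc["g1", "fc_rescue"] == pytest.approx(4.0)
        assert d.loc["g1", "fc_upf1"] == pytest.approx(0.0)
        assert d.loc["g1", "ptb_pairs_neg"] == 3

    def test_degenerate_constant_gene(self):
        norm = pd.DataFrame({s: 5.0 for s in make_table({"g": [0] * 12}).counts.columns},
                            index=["g"])
        d = ex.differential_anova(norm, make_table({"g": [0] * 12}).design)
        assert d.loc["g", "F"] == 0.0 and d.loc["g", "p_anova"] == 1.0


class TestClassification:
    def _diff(self, rows):
        df = pd.DataFrame(rows).set_index("gene")
        df["n_pairs"] = 3
        return df

    def test_planted_gene_lands_in_both_sets(self):
        d = self._diff([
            dict(gene="g1", fc_ptb=-1.0, fc_rescue=0.8, fc_upf1=0.0, F=30.0,
                 p_anova=0.001, ptb_pairs_neg=3, ptb_pairs_pos=0,
                 rescue_pairs_neg=0, rescue_pairs_pos=3,
                 upf1_pairs_neg=1, upf1_pairs_pos=2),
        ])
        s = ex.classify_protection_sets(d)
        assert s.down_genes == {"g1"} and s.rescued_genes == {"g1"}

    def test_inconsistent_replicate_sign_excluded(self):
        d = self._diff([
            dict(gene="g1", fc_ptb=-1.0, fc_rescue=0.8, fc_upf1=0.0, F=30.0,
                 p_anova=0.001, ptb_pairs_neg=2, ptb_pairs_pos=1,
                 rescue_pairs_neg=0, rescue_pairs_pos=3,
                 upf1_pairs_neg=1, upf1_pairs_pos=2),
        ])
        s = ex.classify_protection_sets(d)
        assert s.down_genes == frozenset()

    def test_rescued_subset_of_down(self, small_dataset):
        diff = ex.differential_anova(
            ex.normalize_pipeline(
                small_dataset["counts"],
                {t.gene_id: t.utr3_length for t in small_dataset["ann"].exemplars()},
            ),
            small_dataset["counts"].design,
        )
        s = ex.classify_protection_sets(diff)
        assert s.rescued_genes <= s.down_genes

    def test_monotone_in_alpha(self, small_dataset):
        diff = ex.differential_anova(
            ex.normalize_pipeline(
                small_dataset["counts"],
                {t.gene_id: t.utr3_length for t in small_dataset["ann"].exemplars()},
            ),
            small_dataset["counts"].design,
        )
        d1 = ex.classify_protection_sets(diff, alpha=0.01)
        d2 = ex.classify_protection_sets(diff, alpha=0.05)
        assert d1.down_genes <= d2.down_genes


class TestRescueCorrelation:
    def test_perfectly_monotone_decreasing(self):
        d = pd.DataFrame(
            {
                "fc_ptb": [-3.0, -2.0, -1.0, -0.5],
                "fc_rescue": [3.0, 2.0, 1.0, 0.5],
            },
            index=["a", "b", "c", "d"],
        )
        out = ex.rescue_correlation(d, {"a", "b", "c", "d"})
        assert out["overall"].statistic == pytest.approx(-1.0)

    def test_small_stratum_flagged(self):
        d = pd.DataFrame(
            {"fc_ptb": [-3.0, -2.0, -1.0], "fc_rescue": [1.0, 2.0, 0.5]},
            index=["a", "b", "c"],
        )
        out = ex.rescue_correlation(d, {"a", "b", "c"}, strata={"a": True, "b": True, "c": False})
        assert not out["hexamer_present"].defined
        assert not out["hexamer_absent"].defined

    def test_ols_line_matches_polyfit(self, rng):
        x = rng.normal(0, 1, 30)
        y = -0.8 * x + rng.normal(0, 0.1, 30)
        d = pd.DataFrame({"fc_ptb": x, "fc_rescue": y},
                         index=[f"g{i}" for i in range(30)])
        out = ex.rescue_correlation(d, set(d.index))
        slope, intercept = np.polyfit(x, y, 1)
        assert out["ols"]["slope"] == pytest.approx(slope)


class TestUtrLengthCdf:
    def test_self_comparison(self):
        out = ex.utr_length_cdf(
            {"all": [1.0, 2.0, 3.0], "sub": [1.0, 2.0, 3.0]}, reference="all"
        )
        assert out["sub"]["ks"].statistic == 0.0
        assert out["sub"]["ks"].p_value == 1.0

    def test_median(self):
        out = ex.utr_length_cdf({"all": [1, 2, 3]}, reference="all")
        assert out["all"]["median"] == 2.0

    def test_ecdf_is_proper(self):
        out = ex.utr_length_cdf({"all": [5, 1, 3]}, reference="all")
        assert list(out["all"]["sorted_values"]) == [1, 3, 5]
        assert list(out["all"]["ecdf_y"]) == pytest.approx([1 / 3, 2 / 3, 1.0])


def test_pipeline_order_preserves_uq_property(small_dataset):
    """After the full chain the per-sample 75th percentiles of the positive
    pre-log values are equal (the defining upper-quartile property)."""
    counts = small_dataset["counts"]
    lengths = {t.gene_id: t.utr3_length for t in small_dataset["ann"].exemplars()}
    filt = ex.filter_low_counts(counts)
    uq = ex.upper_quartile_normalize(ex.compute_rpkm(filt, lengths))
    uqs = [stats.percentile(uq[c].values[uq[c].values > 0], 0.75) for c in uq.columns]
    assert np.allclose(uqs, uqs[0], rtol=1e-10)
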