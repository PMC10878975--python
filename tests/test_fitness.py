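import numpy as np
import pandas as pd
import pytest

from crisprtile.fitness import (
    FrequencyMatrix,
    SampleMeta,
    bin_summary,
    coverage_calculator,
    fitness_stats,
    normalize_to_baseline,
    normalize_to_control_allele,
    positional_binning,
    presence_filter,
    to_frequencies,
)


def _matrix(counts: dict, days=None, treatments=None) -> FrequencyMatrix:
    df = pd.DataFrame(counts)
    meta = {}
    for i, sid in enumerate(df.columns):
        meta[sid] = SampleMeta(
            sample_id=sid,
            replicate=f"rep{i + 1}",
            day=(days or {}).get(sid, 7),
            treatment=(treatments or {}).get(sid, "mock"),
        )
    return FrequencyMatrix(counts=df, meta=meta)


class TestFrequencies:
    def test_counts_to_frequencies(self):
        m = _matrix({"s1": {"a": 80, "b": 20}})
        f = m.frequencies()
        assert f.loc["a", "s1"] == pytest.approx(0.8)
        assert f.loc["b", "s1"] == pytest.approx(0.2)

    def test_single_allele_sample(self):
        m = _matrix({"s1": {"a": 42}})
        assert m.frequencies().loc["a", "s1"] == 1.0

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            _matrix({"s1": {"a": 0, "b": 0}})

    def test_frequencies_sum_to_one(self, rng):
        m = _matrix({f"s{j}": {f"a{i}": int(rng.integers(1, 100)) for i in range(20)} for j in range(4)})
        sums = m.frequencies().sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestPresenceFilter:
    def _m(self):
        # three day-7 baseline replicates + one day-21 sample
        counts = {
            "d7_r1": {"a": 3, "b": 0, "c": 5, "wt": 900},
            "d7_r2": {"a": 5, "b": 2, "c": 6, "wt": 900},
            "d7_r3": {"a": 2, "b": 1, "c": 7, "wt": 900},
            "d21_r1": {"a": 25, "b": 100, "c": 19, "wt": 900},
        }
        return _matrix(counts, days={"d21_r1": 21})

    def test_rule(self):
        m = self._m()
        kept = presence_filter(m, ["d7_r1", "d7_r2", "d7_r3"], min_reads=20)
        # a: in all baselines, 25 reads at d21 -> kept
        # b: 0 reads in one baseline -> dropped
        # c: everywhere but max 19 reads -> dropped
        assert set(kept) == {"a", "wt"}

    def test_order_independent(self):
        m = self._m()
        kept1 = presence_filter(m, ["d7_r1", "d7_r2", "d7_r3"])
        kept2 = presence_filter(m, ["d7_r3", "d7_r1", "d7_r2"])
        assert set(kept1) == set(kept2)

    def test_no_baseline_error(self):
        with pytest.raises(ValueError):
            presence_filter(self._m(), [])


class TestNormalize:
    def test_unchanged_frequency_gives_log2_zero(self):
        m = _matrix({"d7": {"a": 100, "wt": 900}, "d21": {"a": 100, "wt": 900}},
                    days={"d21": 21})
        lfc = normalize_to_baseline(m, {"d21": "d7"})
        assert lfc.loc["a", "d21"] == pytest.approx(0.0)

    def test_halved_frequency_gives_minus_one(self):
        m = _matrix(
            {"d7": {"a": 200, "wt": 800}, "d21": {"a": 100, "wt": 900}}, days={"d21": 21}
        )
        lfc = normalize_to_baseline(m, {"d21": "d7"})
        # pseudocount 0.5: log2((100.5/1000)/(200.5/1000))
        assert lfc.loc["a", "d21"] == pytest.approx(np.log2(100.5 / 200.5))

    def test_dropout_with_pseudocount(self):
        """40 reads in mock, 0 under drug, 1e5 totals: log2 ~ -6.34."""
        total = 10**5
        m = _matrix(
            {"mock": {"a": 40, "wt": total - 40}, "drug": {"a": 0, "wt": total}},
            treatments={"drug": "niraparib_1uM"},
        )
        lfc = normalize_to_baseline(m, {"drug": "mock"})
        assert lfc.loc["a", "drug"] == pytest.approx(np.log2(0.5 / 40.5), abs=1e-6)
        assert lfc.loc["a", "drug"] == pytest.approx(-6.34, abs=0.01)

    def test_baseline_maps_to_itself_as_zero(self):
        m = _matrix({"d7": {"a": 10, "wt": 90}})
        lfc = normalize_to_baseline(m, {"d7": "d7"})
        assert np.allclose(lfc["d7"], 0.0)

    def test_control_allele_normalization_within_sample(self):
        """HDR mode: each allele is read against the WT (or synonymous)
        control allele in the same sample."""
        m = _matrix({"s1": {"mut": 10, "wt": 90}, "s2": {"mut": 5, "wt": 95}})
        ratios = normalize_to_control_allele(m, "wt")
        assert ratios.loc["mut", "s1"] == pytest.approx(10.5 / 90.5)
        assert ratios.loc["mut", "s2"] == pytest.approx(5.5 / 95.5)
        assert ratios.loc["wt", "s1"] == pytest.approx(1.0)

    def test_missing_control_allele_rejected(self):
        m = _matrix({"s1": {"mut": 10, "wt": 90}})
        with pytest.raises(ValueError, match="syn"):
            normalize_to_control_allele(m, "syn")


class TestFitnessStats:
    def test_identical_to_reference_p1(self):
        lfc = pd.DataFrame({"r1": [0.5, 0.5], "r2": [0.2, 0.2], "r3": [0.1, 0.1]},
                           index=["a", "wt"])
        res = fitness_stats(lfc, "wt")
        assert res.loc["a", "p"] == pytest.approx(1.0)
        assert res.loc["a", "q"] == pytest.approx(1.0)

    def test_one_tailed_less_than_two_tailed_for_depletion(self):
        lfc = pd.DataFrame({"r1": [-2.0, 0.1], "r2": [-1.8, -0.1], "r3": [-2.2, 0.0]},
                           index=["a", "wt"])
        p2 = fitness_stats(lfc, "wt", alternative="two-sided").loc["a", "p"]
        p1 = fitness_stats(lfc, "wt", alternative="less").loc["a", "p"]
        assert p1 < p2

    def test_zero_variance_both_groups_warns_p1(self):
        lfc = pd.DataFrame({"r1": [1.0, 0.0], "r2": [1.0, 0.0]}, index=["a", "wt"])
        with pytest.warns(UserWarning):
            res = fitness_stats(lfc, "wt")
        assert res.loc["a", "p"] == 1.0

    def test_single_replicate_rejected(self):
        lfc = pd.DataFrame({"r1": [1.0, 0.0]}, index=["a", "wt"])
        with pytest.raises(ValueError):
            fitness_stats(lfc, "wt")

    def test_paired_reference_dataframe_contrast(self):
        """Treatment-vs-mock contrast: the reference is the same allele's
        per-replicate mock values, passed as an aligned DataFrame."""
        drug = pd.DataFrame({"r1": [-2.0, 0.0], "r2": [-2.1, 0.1], "r3": [-1.9, -0.1]},
                            index=["a", "b"])
        mock = pd.DataFrame({"r1": [0.0, 0.0], "r2": [0.1, 0.0], "r3": [-0.1, 0.0]},
                            index=["a", "b"])
        res = fitness_stats(drug, mock, alternative="less")
        assert res.loc["a", "p"] < 0.01  # clearly depleted under drug
        assert res.loc["b", "p"] > 0.2  # unchanged

    def test_q_at_least_p(self, rng):
        n = 50
        lfc = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=["r1", "r2", "r3"],
                           index=[f"a{i}" for i in range(n)])
        ref = pd.Series([0.0, 0.0, 0.0], index=["r1", "r2", "r3"])
        res = fitness_stats(lfc, ref)
        ok = res["p"].notna()
        assert (res.loc[ok, "q"] >= res.loc[ok, "p"] - 1e-12).all()
        assert res["q"].max() <= 1.0


class TestPositionalBinning:
    def test_bin_labels(self):
        div = pd.Series({"a": 3299, "b": 3300, "c": 3301, "d": 3302, "e": 3310})
        binned = positional_binning(div, [3300, 3301, 3302])
        assert binned.loc["a", "bin"] == "before 3300"
        assert binned.loc["b", "bin"] == "at 3300"
        assert binned.loc["c", "bin"] == "at 3301"
        assert binned.loc["d", "bin"] == "at 3302"
        assert binned.loc["e", "bin"] == "after 3302"

    def test_alleles_without_divergence_excluded(self):
        div = pd.Series({"a": 3299.0, "b": np.nan})
        binned = positional_binning(div, [3300])
        assert list(binned.index) == ["a"]

    def test_grouped_medians_permutation_invariant(self, rng):
        div = pd.Series(rng.integers(3290, 3310, 60), index=[f"a{i}" for i in range(60)])
        vals = pd.DataFrame(rng.normal(0, 1, (60, 3)), index=div.index)
        b1 = bin_summary(positional_binning(div, [3300, 3301, 3302], vals), [3300, 3301, 3302])
        perm = rng.permutation(div.index)
        b2 = bin_summary(
            positional_binning(div.loc[perm], [3300, 3301, 3302], vals.loc[perm]),
            [3300, 3301, 3302],
        )
        pd.testing.assert_frame_equal(b1, b2)


class TestCoverage:
    def test_screen_scale(self):
        assert coverage_calculator(1e6, 0.05, 0.0005) == pytest.approx(25.0)

    def test_zero_frequency(self):
        assert coverage_calculator(1e6, 0.5, 0.0) == 0.0

    def test_linear_in_cells(self):
        assert coverage_calculator(2e6, 0.05, 0.0005) == pytest.approx(50.0)

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValueError):
            coverage_calculator(1e6, 1.5, 0.0005)
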