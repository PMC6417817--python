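"""Density estimation, threshold derivation, assignment and co-segregation."""

import numpy as np
import pandas as pd
import pytest

from kircall import (
    CopyNumberMatrix,
    CosegRule,
    GeneCategoryConfig,
    KirCopyNumberModel,
    PopulationDensity,
    assign_copy_number,
    derive_thresholds,
    estimate_density,
    find_peaks_valleys,
    infer_cosegregating,
)
from kircall.exceptions import (
    ConfigError,
    DensityError,
    ParameterError,
    ThresholdError,
)


class TestEstimateDensity:
    def test_point_mass_gives_single_sharp_mode(self):
        d = estimate_density([1.5] * 200)
        peaks, valleys = find_peaks_valleys(d)
        assert len(peaks) == 1 and not valleys
        assert peaks[0].location == pytest.approx(1.5, abs=0.02)
        assert d.integral == pytest.approx(1.0, abs=0.01)

    def test_two_component_mixture_modes_recovered(self, rng):
        vals = np.concatenate([rng.normal(1, 0.1, 400), rng.normal(2, 0.1, 400)])
        d = estimate_density(vals)
        peaks, valleys = find_peaks_valleys(d)
        assert len(peaks) == 2
        assert peaks[0].location == pytest.approx(1.0, abs=0.05)
        assert peaks[1].location == pytest.approx(2.0, abs=0.05)
        assert 1.4 <= valleys[0] <= 1.6

    def test_zero_point_mass_kept_by_reflection(self, rng):
        """A spike of zero-copy samples at the origin keeps its mass."""
        vals = np.concatenate([np.zeros(300), rng.normal(0.5, 0.05, 200)])
        d = estimate_density(vals)
        assert d.integral == pytest.approx(1.0, abs=0.01)
        peaks, _ = find_peaks_valleys(d)
        assert peaks[0].location == pytest.approx(0.0, abs=0.01)

    def test_small_cohort_rejected(self):
        with pytest.raises(DensityError, match="cohort"):
            estimate_density([1.0] * 10)

    def test_negative_frequencies_rejected(self):
        with pytest.raises(ParameterError):
            estimate_density([-1.0] * 100)

    def test_deterministic_given_inputs(self, rng):
        vals = rng.normal(1, 0.2, 100)
        a = estimate_density(vals)
        b = estimate_density(vals)
        assert np.array_equal(a.density, b.density)


class TestFindPeaksValleys:
    def test_three_component_heights_ascend(self, rng):
        vals = np.concatenate(
            [
                rng.normal(0.1, 0.05, 100),
                rng.normal(1.0, 0.05, 300),
                rng.normal(2.0, 0.05, 600),
            ]
        )
        d = estimate_density(vals)
        peaks, valleys = find_peaks_valleys(d)
        assert len(peaks) == 3 and len(valleys) == 2
        heights = [p.height for p in peaks]
        assert heights[0] < heights[1] < heights[2]

    def test_flat_zero_density_is_degenerate(self):
        d = PopulationDensity(
            gene="g", grid=np.linspace(0, 1, 64), density=np.zeros(64), bandwidth=0.1
        )
        with pytest.raises(DensityError, match="degenerate"):
            find_peaks_valleys(d)

    def test_prominence_floor_drops_minor_wiggles(self, rng):
        vals = np.concatenate([rng.normal(1.0, 0.1, 990), rng.normal(2.4, 0.02, 10)])
        d = estimate_density(vals)
        strict, _ = find_peaks_valleys(d, min_prominence=0.2)
        loose, _ = find_peaks_valleys(d, min_prominence=0.001)
        assert len(strict) == 1
        assert len(loose) >= 2


class TestDeriveThresholds:
    def test_anchor_modal_interval_brackets_the_peak(self, rng):
        vals = rng.normal(1.0, 0.06, 800)
        d = estimate_density(vals, gene="A")
        peaks, valleys = find_peaks_valleys(d)
        ts = derive_thresholds(d, peaks, valleys, "anchor")
        assert assign_copy_number(1.0, ts) == 2
        c12, c23 = ts.cutoffs[-2], ts.cutoffs[-1]
        assert c12 < 1.0 < c23
        assert ts.exclusion_margin == pytest.approx(c12 / 50)

    def test_high_freq_cutoffs_fall_between_component_means(self, rng):
        vals = np.concatenate(
            [
                np.abs(rng.normal(0, 0.02, 100)),
                rng.normal(0.5, 0.04, 300),
                rng.normal(1.0, 0.05, 600),
            ]
        )
        d = estimate_density(vals, gene="H")
        peaks, valleys = find_peaks_valleys(d)
        ts = derive_thresholds(d, peaks, valleys, "high_freq_non_anchor")
        c01, c12, c23 = ts.cutoffs
        assert 0 < c01 < 0.5 < c12 < 1.0 < c23
        labels = [assign_copy_number(v, ts) for v in (0.0, 0.5, 1.0)]
        assert labels == [0, 1, 2]

    def test_high_freq_with_single_peak_is_an_error(self, rng):
        vals = rng.normal(1.0, 0.05, 500)
        d = estimate_density(vals, gene="H")
        peaks, valleys = find_peaks_valleys(d)
        with pytest.raises(ThresholdError, match="H.*high_freq"):
            derive_thresholds(d, peaks, valleys, "high_freq_non_anchor")

    def test_low_freq_extrapolates_interpeak_distance(self, rng):
        vals = np.concatenate(
            [np.abs(rng.normal(0, 0.01, 700)), rng.normal(0.5, 0.04, 300)]
        )
        d = estimate_density(vals, gene="L")
        peaks, valleys = find_peaks_valleys(d)
        ts = derive_thresholds(d, peaks, valleys, "low_freq_non_anchor")
        c01, c12, c23 = ts.cutoffs
        dist = peaks[1].location - peaks[0].location
        assert c12 == pytest.approx(c01 + dist, abs=1e-9)
        assert c23 == pytest.approx(c01 + 2 * dist, abs=1e-9)
        # symmetric components: extrapolated boundaries land near 0.75/1.25
        assert c12 == pytest.approx(0.75, abs=0.07)
        assert c23 == pytest.approx(1.25, abs=0.10)

    def test_low_freq_with_one_peak_is_an_error(self, rng):
        # explicit bandwidth: a genuinely unimodal, wiggle-free density
        vals = rng.normal(0.5, 0.04, 500)
        d = estimate_density(vals, gene="L", bandwidth=0.02)
        peaks, valleys = find_peaks_valleys(d)
        with pytest.raises(ThresholdError, match="low_freq"):
            derive_thresholds(d, peaks, valleys, "low_freq_non_anchor")

    def test_unknown_category_rejected(self, rng):
        d = estimate_density(rng.normal(1, 0.05, 100))
        peaks, valleys = find_peaks_valleys(d)
        with pytest.raises(ParameterError):
            derive_thresholds(d, peaks, valleys, "inferred")


class TestAssignCopyNumber:
    @pytest.fixture()
    def thresholds(self, rng):
        vals = np.concatenate(
            [
                np.abs(rng.normal(0, 0.02, 100)),
                rng.normal(0.5, 0.04, 300),
                rng.normal(1.0, 0.05, 600),
            ]
        )
        d = estimate_density(vals, gene="H")
        peaks, valleys = find_peaks_valleys(d)
        return derive_thresholds(d, peaks, valleys, "high_freq_non_anchor")

    def test_exactly_at_cutoff_excluded(self, thresholds):
        assert assign_copy_number(float(thresholds.cutoffs[0]), thresholds) is None

    def test_negative_frequency_rejected(self, thresholds):
        with pytest.raises(ParameterError):
            assign_copy_number(-0.1, thresholds)

    def test_sweep_is_monotone_step_function_matching_interval_scan(self, thresholds):
        """Labels over a dense sweep equal a brute-force interval scan and
        never decrease with frequency outside excluded zones."""
        sweep = np.linspace(0, 3, 10_000)
        got = [assign_copy_number(v, thresholds) for v in sweep]

        def oracle(v):
            for c in thresholds.cutoffs:
                if abs(v - c) < thresholds.exclusion_margin:
                    return None
            n_below = sum(v > c for c in thresholds.cutoffs)
            return thresholds.labels[n_below]

        assert got == [oracle(v) for v in sweep]
        called = [g for g in got if g is not None]
        assert all(a <= b for a, b in zip(called, called[1:]))


class TestCosegregation:
    def matrix(self, values: dict[str, list]) -> CopyNumberMatrix:
        return CopyNumberMatrix(pd.DataFrame(values))

    def test_inverse_rule_reproduces_documented_combinations(self):
        m = self.matrix({"KIR2DS2": [2, 1, 0]})
        out = infer_cosegregating(
            m, [CosegRule("KIR2DL3", ("KIR2DS2",), mode="inverse")]
        )
        assert out.calls["KIR2DL3"].tolist() == [0, 1, 2]

    def test_sum_rule_combines_two_sources(self):
        m = self.matrix({"KIR2DS3": [1, 0], "KIR2DS5": [1, 2]})
        out = infer_cosegregating(
            m, [CosegRule("KIR2DL5A", ("KIR2DS3", "KIR2DS5"))]
        )
        assert out.calls["KIR2DL5A"].tolist() == [2, 2]

    def test_inverse_overflow_clamps_to_zero_with_flag(self):
        m = self.matrix({"KIR2DS2": [3]})
        out = infer_cosegregating(
            m, [CosegRule("KIR2DL3", ("KIR2DS2",), mode="inverse")]
        )
        assert out.calls["KIR2DL3"].tolist() == [0]
        assert out.flags["KIR2DL3"].tolist() == ["inferred_clamped"]

    def test_excluded_source_excludes_target(self):
        m = self.matrix({"KIR3DS1": [2, None]})
        out = infer_cosegregating(m, [CosegRule("KIR2DS1", ("KIR3DS1",))])
        assert out.calls["KIR2DS1"].tolist() == [2, pd.NA]
        assert out.flags["KIR2DS1"].tolist() == ["inferred", "excluded"]

    def test_unknown_source_gene_is_a_config_error(self):
        m = self.matrix({"KIR3DS1": [1]})
        with pytest.raises(ConfigError, match="unknown gene"):
            infer_cosegregating(m, [CosegRule("X", ("NOPE",))])


class TestGeneCategoryConfig:
    def test_default_config_is_consistent(self):
        cfg = GeneCategoryConfig.default_kir()
        assert cfg.category["KIR3DL3"] == "anchor"
        targets = {r.target for r in cfg.coseg_rules}
        inferred = {g for g, c in cfg.category.items() if c == "inferred"}
        assert inferred <= targets

    def test_inferred_gene_without_rule_rejected(self):
        with pytest.raises(ConfigError):
            GeneCategoryConfig(category={"X": "inferred"})

    def test_unknown_category_rejected(self):
        with pytest.raises(ConfigError):
            GeneCategoryConfig(category={"X": "weird"})


class TestModelFit:
    @pytest.fixture()
    def frequencies(self, rng):
        n = 400
        anchor = rng.normal(1.0, 0.06, n)
        high = np.concatenate(
            [
                np.abs(rng.normal(0, 0.02, int(n * 0.1))),
                rng.normal(0.5, 0.04, int(n * 0.3)),
                rng.normal(1.0, 0.05, int(n * 0.6)),
            ]
        )
        low = np.concatenate(
            [np.abs(rng.normal(0, 0.01, int(n * 0.7))), rng.normal(0.5, 0.04, int(n * 0.3))]
        )
        rng.shuffle(high)
        rng.shuffle(low)
        return pd.DataFrame(
            {"ANCHOR": anchor, "HIGH": high, "LOW": low},
            index=[f"s{i}" for i in range(n)],
        )

    @pytest.fixture()
    def config(self):
        return GeneCategoryConfig(
            category={
                "ANCHOR": "anchor",
                "HIGH": "high_freq_non_anchor",
                "LOW": "low_freq_non_anchor",
                "TARGET": "inferred",
            },
            coseg_rules=(CosegRule("TARGET", ("LOW",)),),
        )

    def test_fit_produces_calls_thresholds_and_summary(self, frequencies, config):
        results = KirCopyNumberModel(frequencies, config).fit()
        assert set(results.thresholds) == {"ANCHOR", "HIGH", "LOW"}
        assert list(results.copy_numbers.genes) == ["ANCHOR", "HIGH", "LOW", "TARGET"]
        summary = results.summary()
        assert {"category", "n0", "n1", "n2", "n3plus", "excluded_frac"} <= set(
            summary.columns
        )
        # anchor cohort is overwhelmingly called diploid
        assert summary.loc["ANCHOR", "n2"] > 0.9 * len(frequencies)
        # inferred target mirrors its source where not excluded
        src, tgt = results.copy_numbers.calls["LOW"], results.copy_numbers.calls["TARGET"]
        mask = src.notna()
        assert (src[mask] == tgt[mask]).all()

    def test_small_cohort_rejected(self, frequencies, config):
        with pytest.raises(DensityError, match="floor"):
            KirCopyNumberModel(frequencies.head(20), config).fit()

    def test_gene_without_category_rejected(self, frequencies):
        with pytest.raises(ConfigError):
            KirCopyNumberModel(frequencies, GeneCategoryConfig(category={}))

    def test_thresholds_json_dump(self, frequencies, config, tmp_path):
        import json

        results = KirCopyNumberModel(frequencies, config).fit()
        path = tmp_path / "thr.json"
        results.thresholds_to_json(path)
        payload = json.loads(path.read_text())
        assert set(payload) == {"ANCHOR", "HIGH", "LOW"}
        assert payload["HIGH"]["labels"] == [0, 1, 2, 3]
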