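"""Z-scores, KS statistics, comparison matrices, class histograms, trimming."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptgg.compare import (ClassHistogram, SampleVector, class_histograms,
                          comparison_matrix, ks_critical_value, ks_ratio,
                          ks_statistic, trim_equilibration, zscore)
from ptgg.errors import PtggError
from ptgg.hbonds import FrameClassTable, classify_frames, frequency_table
from ptgg.helix_params import ParamTable, compute_param_table
from ptgg.synthetic import GeneratorSpec, plant_hbond_classes, sample_ensemble


def sv(values, label="x", parameter="p"):
    return SampleVector(np.asarray(values, dtype=float), label, parameter)


class TestZscore:
    def test_identical_samples_zero(self, rng):
        a = sv(rng.normal(size=30))
        assert zscore(a, a) == 0.0

    def test_antisymmetry(self, rng):
        a, b = sv(rng.normal(size=14)), sv(rng.normal(1.0, 1.0, size=14))
        assert zscore(a, b) == pytest.approx(-zscore(b, a), abs=1e-14)

    def test_formula_oracle(self, rng):
        """Matches an independently coded Welch Z to 1e-12."""
        a = sv(rng.normal(0.0, 1.0, size=14))
        b = sv(rng.normal(1.0, 1.0, size=14))
        expect = (a.values.mean() - b.values.mean()) / np.sqrt(
            a.values.var(ddof=1) / 14 + b.values.var(ddof=1) / 14)
        assert zscore(a, b) == pytest.approx(expect, abs=1e-12)

    def test_affine_invariance_up_to_sign(self, rng):
        a, b = sv(rng.normal(size=20)), sv(rng.normal(0.5, 2.0, size=25))
        z0 = zscore(a, b)
        for scale, sign in ((2.5, 1), (-1.3, -1)):
            za = sv(scale * a.values + 7.0)
            zb = sv(scale * b.values + 7.0)
            assert zscore(za, zb) == pytest.approx(sign * z0, abs=1e-10)

    def test_zero_variance(self):
        assert zscore(sv([2.0, 2.0]), sv([2.0, 2.0])) == 0.0
        with pytest.raises(ZeroDivisionError):
            zscore(sv([2.0, 2.0]), sv([3.0, 3.0]))

    def test_needs_two(self):
        with pytest.raises(ValueError):
            zscore(sv([1.0]), sv([1.0, 2.0]))


class TestKs:
    def test_identical_multisets(self):
        a = sv([1.0, 2.0, 2.0, 5.0])
        assert ks_statistic(a, sv([2.0, 5.0, 1.0, 2.0])) == 0.0

    def test_disjoint_supports(self, rng):
        a = sv(rng.uniform(0, 1, 40))
        b = sv(rng.uniform(5, 6, 60))
        assert ks_statistic(a, b) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle(self, seed):
        """Equals an O(n^2) scan of both ECDFs over all sample points."""
        rng = np.random.default_rng(seed)
        a = sv(np.round(rng.normal(size=rng.integers(5, 60)), 1))  # force ties
        b = sv(np.round(rng.normal(0.3, 1.2, size=rng.integers(5, 60)), 1))
        best = 0.0
        for x in np.concatenate([a.values, b.values]):
            fa = np.mean(a.values <= x)
            fb = np.mean(b.values <= x)
            best = max(best, abs(fa - fb))
        assert ks_statistic(a, b) == pytest.approx(best, abs=1e-15)

    def test_matches_scipy(self, rng):
        a = sv(rng.normal(size=80))
        b = sv(rng.normal(0.4, 1.0, size=95))
        expect = stats.ks_2samp(a.values, b.values, method="asymp").statistic
        assert ks_statistic(a, b) == pytest.approx(expect, abs=1e-12)


class TestKsRatio:
    def test_identical_zero(self, rng):
        a = sv(rng.normal(size=20))
        assert ks_ratio(a, a) == 0.0

    def test_ratio_one_at_critical_value(self, rng):
        """Choosing alpha so the critical value equals the observed D makes
        the ratio exactly 1."""
        a = sv(rng.normal(size=50))
        b = sv(rng.normal(0.7, 1.0, size=60))
        d = ks_statistic(a, b)
        c = d / np.sqrt((50 + 60) / (50 * 60))
        alpha = 2.0 * np.exp(-2.0 * c * c)
        assert ks_ratio(a, b, alpha) == pytest.approx(1.0, abs=1e-9)

    def test_linear_in_d(self, rng):
        a = sv(rng.normal(size=30))
        b = sv(rng.normal(1.0, 1.0, size=30))
        ratio = ks_ratio(a, b, 0.05)
        assert ratio == pytest.approx(
            ks_statistic(a, b) / ks_critical_value(30, 30, 0.05), abs=1e-12)

    def test_alpha_domain(self, rng):
        a = sv(rng.normal(size=10))
        with pytest.raises(ValueError):
            ks_ratio(a, a, alpha=1.5)


def small_tables(seed, delta_in_sd=0.0, n=500):
    """Two param tables differing only in central-step roll by delta SDs."""
    spec_a = GeneratorSpec(n_frames=n, seed=seed)
    spec_b = GeneratorSpec(n_frames=n, seed=seed + 10_000)
    spec_b.step_means.loc[5, "roll"] += delta_in_sd * spec_b.step_sds.loc[5, "roll"]
    ta = compute_param_table(sample_ensemble(spec_a).ensemble)
    tb = compute_param_table(sample_ensemble(spec_b).ensemble)
    return {"a": ta, "b": tb}


class TestComparisonMatrix:
    def test_self_comparison_zero(self):
        tables = small_tables(3, n=20)
        m = comparison_matrix({"a": tables["a"]}, [("a", "a")], "z")
        assert np.allclose(m.data.to_numpy(), 0.0)

    def test_planted_effect_is_matrix_max(self):
        tables = small_tables(17, delta_in_sd=2.0)
        m = comparison_matrix(tables, [("a", "b")], "z")
        param, _ = m.max_cell()
        assert param == "step_6_7_roll"

    def test_designation_mismatch(self):
        tables = small_tables(3, n=20)
        other = ParamTable(tables["b"].data.drop(columns=["step_6_7_roll"]),
                           tables["b"].pair_indices, tables["b"].step_indices)
        with pytest.raises(PtggError, match="designation"):
            comparison_matrix({"a": tables["a"], "b": other}, [("a", "b")], "z")

    def test_labels_match_designation(self):
        tables = small_tables(3, n=20)
        m = comparison_matrix(tables, [("a", "b")], "ks")
        assert list(m.data.columns) == ["a vs b"]
        assert set(m.data.index) == set(tables["a"].parameter_names())


class TestClassHistograms:
    def test_single_class_is_normalized_histogram(self, rng):
        values = sv(rng.normal(size=400))
        classes = FrameClassTable(["None"] * 400, ["G7-O6", "T8-O4"])
        hist = class_histograms(values, classes, bins=20)
        assert hist.class_mass("None") == pytest.approx(1.0, abs=1e-12)

    def test_mass_conservation_matches_frequency_table(self):
        spec = GeneratorSpec(pt=True, preset="pt_gg", n_frames=300, seed=6,
                             class_fractions=(0.3, 0.4, 0.1, 0.2))
        built = plant_hbond_classes(spec)
        table = compute_param_table(built.ensemble)
        classes = classify_frames(built.ensemble)
        hist = class_histograms(sv(table.column("step_6_7_roll")), classes)
        freq = frequency_table(classes, precision=6)
        total = 0.0
        for name in classes.class_names():
            assert 100 * hist.class_mass(name) == pytest.approx(
                freq.percentages[name], abs=1e-6)
            total += hist.class_mass(name)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_planted_bimodal_modes(self, rng):
        """Per-class modes land within one bin of the planted means."""
        a = rng.normal(-3.0, 0.5, size=600)
        b = rng.normal(3.0, 0.5, size=400)
        values = sv(np.concatenate([a, b]))
        classes = FrameClassTable(["G7-O6"] * 600 + ["None"] * 400,
                                  ["G7-O6", "T8-O4"])
        hist = class_histograms(values, classes)
        width = hist.bin_edges[1] - hist.bin_edges[0]
        centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2
        assert abs(centers[np.argmax(hist.masses["G7-O6"])] + 3.0) <= width
        assert abs(centers[np.argmax(hist.masses["None"])] - 3.0) <= width

    def test_misaligned_lengths(self, rng):
        values = sv(rng.normal(size=10))
        classes = FrameClassTable(["None"] * 9, ["G7-O6"])
        with pytest.raises(PtggError, match="misaligned"):
            class_histograms(values, classes)


class TestTrim:
    def make_table(self, n, runs=1):
        frames = np.arange(n * runs)
        df = pd.DataFrame({"frame_index": frames,
                           "step_6_7_roll": np.linspace(0, 1, n * runs)})
        if runs > 1:
            df["run_id"] = np.repeat(np.arange(runs), n)
        return ParamTable(df, (5,), (5,))

    def test_zero_burn_in_identity(self):
        t = self.make_table(50)
        assert trim_equilibration(t, 0.0).data.equals(t.data)

    def test_fraction_keeps_final_rows(self):
        t = self.make_table(100)
        out = trim_equilibration(t, 0.4)
        assert len(out.data) == 60
        assert list(out.data["frame_index"]) == list(range(40, 100))

    def test_per_run_bookkeeping(self):
        """5 concatenated 2000-frame runs at 40% burn-in leave 6000 rows,
        mirroring 5 x 10 ns -> the final 6 ns of each."""
        t = self.make_table(2000, runs=5)
        out = trim_equilibration(t, 0.4)
        assert len(out.data) == 6000
        assert (out.data.groupby("run_id").size() == 1200).all()

    def test_burn_in_too_large(self):
        t = self.make_table(10)
        with pytest.raises(PtggError):
            trim_equilibration(t, 10)
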