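import numpy as np
import pytest

from ftirxai.expected_gradients import AttributionVector
from ftirxai.fingerprint_analysis import (
    AggregateProfile,
    aggregate_profiles,
    error_report,
    extract_fingerprint_regions,
    group_statistics,
    jaccard,
    render_explanation,
    sum_in_ranges,
)
from ftirxai.spectra_io import CANONICAL_GRID, Spectrum

GRID = CANONICAL_GRID
X = GRID.wavenumbers()


def attr(values):
    return AttributionVector(values=np.asarray(values, dtype=float))


class TestSumInRanges:
    def test_full_span_counts_every_point(self):
        rs = sum_in_ranges(attr(np.ones(3106)), [(650.0, 3775.0)])
        assert rs.value == 3106

    def test_direct_sum_inside_interval(self):
        v = np.zeros(3106)
        inside = np.where((X >= 2200) & (X < 2280))[0][:3]
        v[inside] = 0.1
        rs = sum_in_ranges(attr(v), [(2200.0, 2280.0)])
        assert np.isclose(rs.value, 0.3)

    def test_overlapping_ranges_count_once(self):
        v = np.random.default_rng(0).normal(size=3106)
        merged = sum_in_ranges(attr(v), [(1000.0, 1500.0)])
        overlapping = sum_in_ranges(attr(v), [(1000.0, 1300.0), (1200.0, 1500.0)])
        assert np.isclose(merged.value, overlapping.value)

    def test_additive_over_disjoint_ranges(self):
        v = np.random.default_rng(1).normal(size=3106)
        both = sum_in_ranges(attr(v), [(700.0, 900.0), (2000.0, 2100.0)])
        parts = (sum_in_ranges(attr(v), [(700.0, 900.0)]).value
                 + sum_in_ranges(attr(v), [(2000.0, 2100.0)]).value)
        assert np.isclose(both.value, parts)

    def test_half_open_membership_adjacent_intervals(self):
        """Adjacent intervals share no grid point: lo <= x < hi."""
        v = np.ones(3106)
        left = sum_in_ranges(attr(v), [(1650.0, 1700.0)]).value
        right = sum_in_ranges(attr(v), [(1700.0, 1750.0)]).value
        union = sum_in_ranges(attr(v), [(1650.0, 1750.0)]).value
        assert left + right == union

    def test_grid_end_point_included(self):
        v = np.zeros(3106)
        v[-1] = 1.0
        assert sum_in_ranges(attr(v), [(3700.0, 3775.0)]).value == 1.0

    def test_out_of_span_interval_raises(self):
        with pytest.raises(ValueError):
            sum_in_ranges(attr(np.zeros(3106)), [(100.0, 700.0)])


class TestGroupStatistics:
    def test_arithmetic_example(self):
        vecs = []
        for total in (0.2, 0.4, -0.3):
            v = np.zeros(3106)
            v[np.argmin(np.abs(X - 2240))] = total
            vecs.append(attr(v))
        gs = group_statistics(vecs, [1, 1, 0], [(2200.0, 2280.0)], group="nitriles")
        assert np.isclose(gs.S_plus, 0.3)
        assert np.isclose(gs.S_minus, -0.3)
        assert (gs.n_positive, gs.n_negative) == (2, 1)

    def test_zero_attributions_give_zero_statistics(self):
        vecs = [attr(np.zeros(3106)) for _ in range(4)]
        gs = group_statistics(vecs, [1, 0, 1, 0], [(2200.0, 2280.0)])
        assert gs.S_plus == 0.0 and gs.S_minus == 0.0

    def test_missing_class_error_names_it(self):
        vecs = [attr(np.zeros(3106))] * 2
        with pytest.raises(ValueError, match="S-"):
            group_statistics(vecs, [1, 1], [(2200.0, 2280.0)])
        with pytest.raises(ValueError, match="S\\+"):
            group_statistics(vecs, [0, 0], [(2200.0, 2280.0)])


class TestAggregateProfiles:
    def test_single_pair_means(self):
        v = np.random.default_rng(0).normal(size=3106)
        w = np.random.default_rng(1).normal(size=3106)
        prof = aggregate_profiles([attr(v), attr(w)], [1, 0])
        assert np.array_equal(prof.FA, v)
        assert np.array_equal(prof.FB, -w)
        assert np.array_equal(prof.FC, v - w)

    def test_sign_convention_informative_absence(self):
        u = np.abs(np.random.default_rng(2).normal(size=3106))
        prof = aggregate_profiles([attr(u), attr(-u), attr(-u)], [1, 0, 0])
        assert np.all(prof.FB >= 0)

    def test_fc_identity_exact(self):
        rng = np.random.default_rng(3)
        vecs = [attr(rng.normal(size=3106)) for _ in range(10)]
        labels = [1, 0] * 5
        prof = aggregate_profiles(vecs, labels)
        assert np.array_equal(prof.FC, prof.FA + prof.FB)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        vecs = [attr(rng.normal(size=3106)) for _ in range(8)]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        p1 = aggregate_profiles(vecs, labels)
        perm = [5, 0, 7, 2, 1, 6, 3, 4]
        p2 = aggregate_profiles([vecs[i] for i in perm], [labels[i] for i in perm])
        assert np.allclose(p1.FA, p2.FA) and np.allclose(p1.FB, p2.FB)

    def test_sd_of_flipped_subset_equals_sd_of_raw(self):
        rng = np.random.default_rng(5)
        vecs = [attr(rng.normal(size=3106)) for _ in range(6)]
        labels = [1, 0, 0, 1, 0, 1]
        prof = aggregate_profiles(vecs, labels)
        raw = np.stack([vecs[i].values for i in (1, 2, 4)])
        assert np.allclose(prof.sd_FB, raw.std(axis=0, ddof=1))


class TestExtractFingerprintRegions:
    def _profile(self, fc):
        z = np.zeros(3106)
        return AggregateProfile(wavenumbers=X, FA=fc, FB=z, FC=fc,
                                sd_FA=z, sd_FB=z, sd_FC=z, n_A=1, n_B=1)

    def test_rectangular_bump_recovered(self):
        fc = np.where((X >= 2200) & (X <= 2280), 1.0, 0.0)
        region = extract_fingerprint_regions(self._profile(fc))
        assert len(region.intervals) == 1
        lo, hi = region.intervals[0]
        assert abs(lo - 2200) <= 2 and abs(hi - 2280) <= 2

    def test_all_zero_profile_empty_with_warning(self):
        with pytest.warns(UserWarning):
            region = extract_fingerprint_regions(self._profile(np.zeros(3106)))
        assert region.intervals == []

    def test_narrow_spikes_discarded_and_close_runs_merged(self):
        fc = np.zeros(3106)
        fc[np.abs(X - 1000) < 2] = 1.0  # too narrow alone
        fc[(X >= 1500) & (X <= 1540)] = 1.0
        fc[(X >= 1545) & (X <= 1580)] = 1.0  # gap 5 cm-1 < min width: merged
        region = extract_fingerprint_regions(self._profile(fc), min_width=15.0)
        assert len(region.intervals) == 1
        lo, hi = region.intervals[0]
        assert lo < 1510 and hi > 1570

    def test_window_restricts_search(self):
        fc = np.where((X >= 1000) & (X <= 1100), 5.0, 0.0) + \
            np.where((X >= 3000) & (X <= 3050), 1.0, 0.0)
        region = extract_fingerprint_regions(self._profile(fc), window=(2800.0, 3400.0))
        assert len(region.intervals) == 1
        assert region.intervals[0][0] >= 2990


class TestJaccard:
    def test_identical_intervals(self):
        assert jaccard((100.0, 200.0), [(100.0, 200.0)]) == 1.0

    def test_disjoint_intervals(self):
        assert jaccard((100.0, 200.0), [(300.0, 400.0)]) == 0.0

    def test_half_overlap(self):
        assert np.isclose(jaccard((0.0, 100.0), [(50.0, 150.0)]), 50.0 / 150.0)


class TestRenderExplanation:
    def test_sidecar_round_trips_attribution(self, tmp_path):
        rng = np.random.default_rng(0)
        s = Spectrum(absorbance=rng.random(3106), grid=GRID)
        a = attr(rng.normal(size=3106))
        out = render_explanation(s, a, tmp_path / "ex.png")
        assert out.exists()
        import pandas as pd

        # shortest round-trip reprs need a correctly-rounding parser
        table = pd.read_csv(tmp_path / "ex.csv", float_precision="round_trip")
        assert np.array_equal(table["shap_value"].to_numpy(), a.values)
        assert np.array_equal(table["absorbance"].to_numpy(), s.absorbance)

    def test_length_mismatch_raises(self, tmp_path):
        s = Spectrum(absorbance=np.zeros(3106), grid=GRID)
        with pytest.raises(ValueError):
            render_explanation(s, attr(np.zeros(10)), tmp_path / "x.png")


class TestErrorReport:
    def _model(self, prob):
        class Fixed:
            config = type("C", (), {"n_input": 3106, "threshold": 0.5})()

            def predict_proba(self, Xb):
                return np.array([prob])

        return Fixed()

    def test_verdict_labels(self):
        s = Spectrum(absorbance=np.zeros(3106), grid=GRID)
        a = attr(np.zeros(3106))
        rep = error_report(self._model(0.8), s, a, true_label=1)
        assert rep["verdict"] == "correct"
        rep = error_report(self._model(0.8), s, a, true_label=0)
        assert rep["verdict"] == "false positive"
        rep = error_report(self._model(0.2), s, a, true_label=1)
        assert rep["verdict"] == "false negative"

    def test_characteristic_range_sum_reported_unconditionally(self):
        v = np.zeros(3106)
        v[np.argmin(np.abs(X - 2240))] = 0.7
        s = Spectrum(absorbance=np.zeros(3106), grid=GRID)
        rep = error_report(self._model(0.1), s, attr(v), true_label=1,
                           target_ranges=[(2200.0, 2280.0)])
        assert rep["verdict"] == "false negative"
        assert np.isclose(rep["characteristic_range_sum"], 0.7)

    def test_top_intervals_disjoint_sorted_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=3106)
        s = Spectrum(absorbance=np.zeros(3106), grid=GRID)
        rep = error_report(self._model(0.9), s, attr(v), true_label=1, top_k=5)
        for key, sign in (("top_positive_intervals", 1), ("top_negative_intervals", -1)):
            ivs = rep[key]
            # sorted by |mean attribution|
            means = [abs(r["mean_attribution"]) for r in ivs]
            assert means == sorted(means, reverse=True)
            # disjoint
            spans = sorted((r["lo"], r["hi"]) for r in ivs)
            for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
                assert h1 < l2
            # brute force: every maximal constant-sign run, ranked
            runs = []
            i = 0
            while i < v.size:
                if sign * v[i] > 0:
                    j = i
                    while j + 1 < v.size and sign * v[j + 1] > 0:
                        j += 1
                    runs.append(abs(v[i:j + 1].mean()))
                    i = j + 1
                else:
                    i += 1
            expected = sorted(runs, reverse=True)[:5]
            assert np.allclose(means, expected)
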