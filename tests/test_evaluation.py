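"""Agreement-statistic tests: histology fractions, identity-line R^2,
Pearson r, Wolfe's dependent-correlation test, rim misassignment and the
three-criteria feature selection."""
import numpy as np
import pytest
from scipy import ndimage

from hifuseg.evaluation import (FractionPair, evaluate_feature_vectors,
                                histology_volume_fraction, pearson_r,
                                r2_to_identity, rim_misassignment_fraction,
                                wolfe_dependent_correlation_test)
from hifuseg.viability import VIABILITY_NONVIABLE, VIABILITY_VIABLE


class TestHistologyFraction:
    def test_simple_ratio(self):
        assert histology_volume_fraction([(2, 10), (3, 10)]) == pytest.approx(0.25)

    def test_area_weighting_not_mean_of_ratios(self):
        assert histology_volume_fraction([(9, 10), (0, 90)]) == pytest.approx(0.09)

    def test_all_viable(self):
        assert histology_volume_fraction([(0, 5), (0, 9)]) == 0.0

    def test_nonviable_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            histology_volume_fraction([(11, 10)])

    def test_matches_brute_force_on_random_sections(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            totals = rng.uniform(1, 50, rng.integers(2, 12))
            nv = totals * rng.uniform(0, 1, totals.size)
            got = histology_volume_fraction(list(zip(nv, totals)))
            assert got == pytest.approx(sum(nv) / sum(totals), abs=1e-12)


class TestR2ToIdentity:
    def test_perfect_agreement(self):
        x = np.array([0.05, 0.3, 0.55])
        assert r2_to_identity(x, x) == 1.0

    def test_hand_computed_zero(self):
        assert r2_to_identity(np.array([0.1, 0.2, 0.3]),
                              np.array([0.1, 0.3, 0.2])) == pytest.approx(0.0)

    def test_hand_computed_negative(self):
        # anti-correlated points: identity fits far worse than the mean
        assert r2_to_identity(np.array([0.0, 1.0]),
                              np.array([1.0, 0.0])) == pytest.approx(-3.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r2_to_identity(np.array([0.1, 0.2]), np.array([0.5, 0.5]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.uniform(0, 1, 9)
            y = rng.uniform(0, 1, 9)
            brute = 1 - ((y - x) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            assert r2_to_identity(x, y) == pytest.approx(brute, abs=1e-12)

    def test_noise_decreases_expected_r2(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0.0, 0.6, 12)
        clean = np.mean([r2_to_identity(x, x + 0.01 * rng.standard_normal(12))
                         for _ in range(200)])
        noisy = np.mean([r2_to_identity(x, x + 0.10 * rng.standard_normal(12))
                         for _ in range(200)])
        assert noisy < clean


class TestPearson:
    def test_positive_affine_relation(self):
        x = np.array([0.0, 0.1, 0.2, 0.5])
        assert pearson_r(x, 2 * x + 0.1) == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.array([0.0, 0.1, 0.2, 0.5])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_r(np.array([1.0, 2, 3, 4]),
                         np.array([2.0, 1, 4, 3])) == pytest.approx(0.6)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.standard_normal(15)
            y = rng.standard_normal(15)
            brute = (((x - x.mean()) * (y - y.mean())).sum()
                     / np.sqrt(((x - x.mean()) ** 2).sum()
                               * ((y - y.mean()) ** 2).sum()))
            assert pearson_r(x, y) == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.array([1.0, 1, 1]), np.array([0.0, 1, 2]))


class TestWolfeTest:
    def test_identical_correlations_give_null(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        stat, p = wolfe_dependent_correlation_test(x, y, y)
        assert stat == 0.0 and p == 1.0

    def test_detects_unequal_correlations(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        y1 = x + 0.3 * rng.standard_normal(50)   # strongly correlated
        y2 = rng.standard_normal(50)             # independent of x
        _, p = wolfe_dependent_correlation_test(x, y1, y2)
        assert p < 0.05

    def test_swapping_flips_sign_keeps_p(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        y1 = x + rng.standard_normal(40)
        y2 = 0.5 * x + rng.standard_normal(40)
        s12, p12 = wolfe_dependent_correlation_test(x, y1, y2)
        s21, p21 = wolfe_dependent_correlation_test(x, y2, y1)
        assert s12 == pytest.approx(-s21)
        assert p12 == pytest.approx(p21)

    def test_too_small_sample_rejected(self):
        x = np.array([1.0, 2, 3])
        with pytest.raises(ValueError):
            wolfe_dependent_correlation_test(x, x + 1, x + 2)


class TestRimMisassignment:
    @staticmethod
    def _disc_mask(radius=10, shape=(28, 28, 2)):
        g = np.ogrid[:shape[0], :shape[1]]
        disc = ((g[0] - shape[0] // 2) ** 2 + (g[1] - shape[1] // 2) ** 2
                <= radius ** 2)
        return np.repeat(disc[:, :, None], shape[2], axis=2)

    def test_all_viable_gives_zero(self):
        tumor = self._disc_mask()
        vmap = np.where(tumor, VIABILITY_VIABLE, -1)
        assert rim_misassignment_fraction(vmap, tumor, 3) == 0.0

    def test_fully_nonviable_rim_gives_one(self):
        tumor = self._disc_mask()
        vmap = np.where(tumor, VIABILITY_NONVIABLE, -1)
        assert rim_misassignment_fraction(vmap, tumor, 3) == 1.0

    def test_half_rim_by_construction(self):
        tumor = self._disc_mask()
        # label the left half-plane non-viable; the rim is symmetric, so
        # close to half its voxels fall in that half
        vmap = np.where(tumor, VIABILITY_VIABLE, -1)
        vmap[:14, :, :] = np.where(tumor[:14], VIABILITY_NONVIABLE, -1)
        frac = rim_misassignment_fraction(vmap, tumor, 3)
        cross = ndimage.generate_binary_structure(2, 1)
        rim = tumor[:, :, 0] & ~ndimage.binary_erosion(tumor[:, :, 0], cross,
                                                       iterations=3)
        expect = (rim[:14].sum()) / rim.sum()
        assert frac == pytest.approx(expect, abs=1e-12)

    def test_matches_distance_transform_oracle(self):
        rng = np.random.default_rng(7)
        tumor = self._disc_mask(radius=9)
        vmap = np.where(tumor & (rng.random(tumor.shape) < 0.4),
                        VIABILITY_NONVIABLE, VIABILITY_VIABLE)
        vmap[~tumor] = -1
        got = rim_misassignment_fraction(vmap, tumor, 3)
        # oracle: rim voxels are those within taxicab distance 3 of outside
        n_rim = n_bad = 0
        for z in range(tumor.shape[2]):
            dist = ndimage.distance_transform_cdt(tumor[:, :, z],
                                                  metric="taxicab")
            rim = tumor[:, :, z] & (dist <= 3)
            n_rim += rim.sum()
            n_bad += (vmap[:, :, z][rim] == VIABILITY_NONVIABLE).sum()
        assert got == pytest.approx(n_bad / n_rim, abs=1e-12)

    def test_thin_tumor_degenerates_to_whole_mask(self):
        tumor = np.zeros((10, 4, 1), dtype=bool)
        tumor[2:8, 1:3, 0] = True    # 2 voxels thick: erosion empties it
        vmap = np.where(tumor, VIABILITY_NONVIABLE, -1)
        assert rim_misassignment_fraction(vmap, tumor, 3) == 1.0


def _pairs(key, iso_fracs, hist_fracs, groups):
    return [FractionPair(f"A{i}", g, h, y)
            for i, (g, h, y) in enumerate(zip(groups, hist_fracs, iso_fracs))]


class TestFeatureSelection:
    groups = ["1h", "1h", "1h", "72h", "72h", "72h",
              "control", "control", "control"]
    hist = [0.1, 0.2, 0.3, 0.3, 0.4, 0.5, 0.0, 0.01, 0.0]

    def test_single_retained_vector_is_selected(self):
        good = np.asarray(self.hist) + 0.01
        bad = np.asarray(self.hist) * 0.1
        report = evaluate_feature_vectors(
            {"A": _pairs("A", good, self.hist, self.groups),
             "B": _pairs("B", bad, self.hist, self.groups)},
            {"A": 0.5, "B": 0.0})
        assert report.retained == ["A"]
        assert report.selected == "A"      # despite its larger rim fraction

    def test_no_retained_vector_reports_empty_selection(self):
        bad = np.asarray(self.hist) * 0.1
        report = evaluate_feature_vectors(
            {"A": _pairs("A", bad, self.hist, self.groups)}, {"A": 0.1})
        assert report.retained == [] and report.selected is None
        assert len(report.table) == 1      # statistics still reported

    def test_tie_falls_through_to_rim_criterion(self):
        exact = np.asarray(self.hist)
        report = evaluate_feature_vectors(
            {"A": _pairs("A", exact, self.hist, self.groups),
             "B": _pairs("B", exact, self.hist, self.groups)},
            {"A": 0.3, "B": 0.05})
        assert set(report.retained) == {"A", "B"}
        assert report.selected == "B"
        assert not report.wolfe.empty

    def test_group_correlations_use_sacrifice_groups(self):
        iso = np.asarray(self.hist) + 0.02
        report = evaluate_feature_vectors(
            {"A": _pairs("A", iso, self.hist, self.groups)}, {"A": 0.0})
        row = report.table.iloc[0]
        assert row["r_1h_control"] == pytest.approx(1.0)
        assert row["r_72h_control"] == pytest.approx(1.0)
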