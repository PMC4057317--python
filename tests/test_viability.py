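"""Viability classification tests: fraction tables, the paired-t rule with
its direction gate, viability maps and the per-class parameter summary."""
import numpy as np
import pandas as pd
import pytest

from hifuseg.synthetic import (LABEL_NONVIABLE, LABEL_VIABLE, CohortDesign)
from hifuseg.viability import (VIABILITY_EXCLUDED, VIABILITY_NONVIABLE,
                               VIABILITY_VIABLE, ClusterClassMap,
                               classify_clusters, cluster_fraction_table,
                               make_viability_map, nonviable_fraction,
                               paired_t_test, summarize_parameters)


class TestFractionTable:
    def test_counts_to_fractions(self):
        labels = np.repeat([3, 0], [40, 60])
        table = cluster_fraction_table({("A", "pre"): labels}, n_clusters=5)
        row = table[(table["cluster"] == 3)]
        assert row["fraction"].iloc[0] == pytest.approx(0.40)

    def test_fractions_sum_to_one_per_scan(self):
        rng = np.random.default_rng(0)
        assignments = {("A", "pre"): rng.integers(0, 6, 321),
                       ("A", "post1h"): rng.integers(0, 6, 123)}
        table = cluster_fraction_table(assignments, n_clusters=6)
        sums = table.groupby(["animal_id", "timepoint"])["fraction"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_absent_cluster_gets_zero(self):
        table = cluster_fraction_table({("A", "pre"): np.zeros(10, int)}, 3)
        absent = table[table["cluster"] == 2]
        assert absent["fraction"].iloc[0] == 0.0

    def test_exclusions_shrink_denominator_only(self):
        labels = np.repeat([1, 0], [40, 60])
        full = cluster_fraction_table({("A", "pre"): labels}, 2)
        # five excluded voxels from cluster 0 never reach the table
        reduced = cluster_fraction_table({("A", "pre"): labels[:-5]}, 2)
        f_full = full[full["cluster"] == 1]["fraction"].iloc[0]
        f_red = reduced[reduced["cluster"] == 1]["fraction"].iloc[0]
        assert f_full == pytest.approx(40 / 100)
        assert f_red == pytest.approx(40 / 95)


class TestPairedT:
    def test_hand_computed_example(self):
        d = np.array([0.30, 0.35, 0.40, 0.30, 0.35, 0.40, 0.35])
        res = paired_t_test(np.zeros(7), d)
        assert res.mean_diff == pytest.approx(0.35)
        assert res.t == pytest.approx(0.35 / (d.std(ddof=1) / np.sqrt(7)), rel=1e-12)
        assert res.t == pytest.approx(22.68, abs=0.01)
        assert res.p < 1e-6

    def test_no_change_gives_p_one(self):
        x = np.array([0.1, 0.4, 0.2])
        res = paired_t_test(x, x)
        assert res.p == 1.0 and res.mean_diff == 0.0

    def test_sign_flip_antisymmetry(self):
        before = np.array([0.1, 0.2, 0.3, 0.1])
        after = np.array([0.3, 0.25, 0.45, 0.3])
        a = paired_t_test(before, after)
        b = paired_t_test(after, before)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_zero_variance_nonzero_shift_convention(self):
        res = paired_t_test(np.zeros(5), np.full(5, 0.3))
        assert res.p == 0.0 and np.isinf(res.t)


def _table_from_fractions(design, fractions):
    """fractions: {cluster: {timepoint: per-animal fraction array}} over
    treated animals (controls get constant fractions)."""
    rows = []
    clusters = sorted(fractions)
    plans = design.animals()
    treated = [p for p in plans if p.group == "treated"]
    for p in plans:
        for tp in p.timepoints:
            remaining = 1.0
            for c in clusters[:-1]:
                if p.group == "treated":
                    i = treated.index(p)
                    f = float(fractions[c][tp][i])
                else:
                    f = float(np.mean(fractions[c]["pre"]))
                rows.append({"animal_id": p.animal_id, "timepoint": tp,
                             "cluster": c, "fraction": f})
                remaining -= f
            rows.append({"animal_id": p.animal_id, "timepoint": tp,
                         "cluster": clusters[-1], "fraction": remaining})
    return pd.DataFrame(rows)


class TestClassifyClusters:
    design = CohortDesign(n_treated=14, n_treated_72h=7, n_control=7)

    def _fractions(self, pre, post1h, post72h):
        n = self.design.n_treated
        return {0: {"pre": np.full(n, pre), "post1h": np.full(n, post1h),
                    "post72h": np.full(n, post72h)},
                1: {}}  # cluster 1 absorbs the remainder

    def test_clear_increase_is_nonviable(self):
        rng = np.random.default_rng(0)
        n = self.design.n_treated
        frac = {0: {"pre": np.full(n, 0.05),
                    "post1h": 0.40 + 0.04 * rng.standard_normal(n),
                    "post72h": 0.40 + 0.04 * rng.standard_normal(n)},
                1: {}}
        table = _table_from_fractions(self.design, frac)
        cm = classify_clusters(table, self.design, alpha=0.05)
        assert cm.classes[0] == "nonviable"
        assert cm.classes[1] == "viable"

    def test_unchanged_cluster_is_viable(self):
        table = _table_from_fractions(self.design,
                                      self._fractions(0.2, 0.2, 0.2))
        cm = classify_clusters(table, self.design)
        assert cm.classes[0] == "viable"

    def test_significant_decrease_stays_viable(self):
        # direction gate: shrinking clusters are never non-viable
        rng = np.random.default_rng(1)
        n = self.design.n_treated
        frac = {0: {"pre": np.full(n, 0.5),
                    "post1h": 0.2 + 0.02 * rng.standard_normal(n),
                    "post72h": 0.2 + 0.02 * rng.standard_normal(n)},
                1: {}}
        cm = classify_clusters(_table_from_fractions(self.design, frac),
                               self.design)
        assert cm.classes[0] == "viable"

    def test_zero_variance_increase_is_nonviable(self):
        # constant positive shift: p = 0 by convention, passes the gate
        cm = classify_clusters(
            _table_from_fractions(self.design, self._fractions(0.1, 0.4, 0.4)),
            self.design)
        assert cm.classes[0] == "nonviable"

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        n = self.design.n_treated
        frac = {0: {"pre": np.full(n, 0.05),
                    "post1h": 0.35 + 0.03 * rng.standard_normal(n),
                    "post72h": 0.35 + 0.03 * rng.standard_normal(n)},
                1: {}}
        table = _table_from_fractions(self.design, frac)
        cm = classify_clusters(table, self.design)
        swapped = table.assign(cluster=1 - table["cluster"])
        cm2 = classify_clusters(swapped, self.design)
        assert cm.classes[0] == cm2.classes[1]
        assert cm.classes[1] == cm2.classes[0]

    def test_no_treated_animals_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(n_treated=0, n_treated_72h=0, n_control=3)


class TestViabilityMap:
    def _class_map(self):
        return ClusterClassMap(classes={0: "viable", 1: "nonviable"},
                               tests=pd.DataFrame())

    def test_fraction_from_lookup(self):
        vol = np.full((10, 10, 1), -2, dtype=np.int16)
        vol[:10, :10, 0] = 0
        vol[:3, :10, 0] = 1          # 30 of 100 included voxels non-viable
        vmap, frac = make_viability_map(vol, self._class_map())
        assert frac == pytest.approx(0.30)
        assert nonviable_fraction(vmap) == pytest.approx(0.30)
        assert (vmap == VIABILITY_NONVIABLE).sum() == 30

    def test_all_viable_gives_zero(self):
        vol = np.zeros((5, 5, 1), dtype=np.int16)
        _, frac = make_viability_map(vol, self._class_map())
        assert frac == 0.0

    def test_excluded_voxels_in_neither_count(self):
        vol = np.full((10, 1, 1), 0, dtype=np.int16)
        vol[:4] = 1
        vol[4:6] = -1                # excluded
        vmap, frac = make_viability_map(vol, self._class_map())
        assert frac == pytest.approx(4 / 8)
        assert (vmap == VIABILITY_EXCLUDED).sum() == 2

    def test_unmapped_label_rejected(self):
        vol = np.full((2, 2, 1), 7, dtype=np.int16)
        with pytest.raises(KeyError):
            make_viability_map(vol, self._class_map())


class TestSummarizeParameters:
    def _truth_viability(self, cohort):
        # pure classes only: the edematous rim goes to neither, so class
        # means can be compared against the generating distributions
        out = {}
        for key, scan in cohort.scans.items():
            v = np.full(scan.truth.labels.shape, -1, dtype=np.int8)
            v[scan.truth.labels == LABEL_VIABLE] = VIABILITY_VIABLE
            v[scan.truth.labels == LABEL_NONVIABLE] = VIABILITY_NONVIABLE
            out[key] = v
        return out

    def test_recovers_generating_means(self, small_cohort):
        maps = small_cohort.truth_maps()
        summary, tests = summarize_parameters(small_cohort, maps,
                                              self._truth_viability(small_cohort))
        get = lambda p, c: summary[(summary["parameter"] == p)
                                   & (summary["tissue_class"] == c)]["mean"].iloc[0]
        assert get("R1", "viable") == pytest.approx(0.45, abs=0.02)
        assert get("R1", "nonviable_1h") == pytest.approx(0.61, abs=0.05)
        assert get("MTR", "nonviable_72h") == pytest.approx(26.4, abs=1.0)
        sig = tests[(tests["parameter"] == "ADC")
                    & (tests["comparison"] == "viable_vs_nonviable_1h")]
        assert sig["p"].iloc[0] < 0.05 and sig["mean_diff"].iloc[0] > 0

    def test_animal_without_nonviable_dropped_with_warning(self, small_cohort):
        maps = small_cohort.truth_maps()
        viability = self._truth_viability(small_cohort)
        key = ("T01", "post1h")
        v = viability[key].copy()
        v[v == VIABILITY_NONVIABLE] = VIABILITY_VIABLE
        viability[key] = v
        with pytest.warns(UserWarning, match="dropped"):
            summary, _ = summarize_parameters(small_cohort, maps, viability)
        n_1h = summary[(summary["parameter"] == "R1")
                       & (summary["tissue_class"] == "nonviable_1h")]["n"].iloc[0]
        assert n_1h == small_cohort.design.n_treated - 1
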