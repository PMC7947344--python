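import numpy as np
import pandas as pd
import pytest

from ryrclust.stats import (aggregate, blind, compare_groups, provenance_counts,
                            report_tables, unblind)


def long_table(rows):
    return pd.DataFrame(rows, columns=["patient", "group", "image", "metric",
                                       "value"])


class TestAggregate:
    def test_cluster_to_patient_mean(self):
        tab = long_table([("p1", "g1", "i1", "m", v) for v in (2.0, 4.0, 6.0)])
        out = aggregate(tab, level="patient")
        assert out["value"].tolist() == [4.0]

    def test_images_unweighted_by_cluster_count(self):
        rows = [("p1", "g1", "i1", "m", 10.0)]
        rows += [("p1", "g1", "i2", "m", v) for v in [20.0] * 9]
        out = aggregate(long_table(rows), level="patient")
        assert out["value"].tolist() == [15.0]

    def test_image_level(self):
        rows = [("p1", "g1", "i1", "m", 1.0), ("p1", "g1", "i1", "m", 3.0),
                ("p1", "g1", "i2", "m", 5.0)]
        out = aggregate(long_table(rows), level="image")
        assert sorted(out["value"]) == [2.0, 5.0]

    def test_duplicating_images_leaves_patient_values_unchanged(self):
        rng = np.random.default_rng(0)
        rows = []
        for p in range(4):
            for i in range(3):
                for _ in range(5):
                    rows.append((f"p{p}", "g", f"i{p}_{i}", "m",
                                 float(rng.normal())))
        tab = long_table(rows)
        dup = tab.copy()
        dup["image"] = dup["image"] + "_copy"
        out1 = aggregate(tab)
        out2 = aggregate(pd.concat([tab, dup], ignore_index=True))
        np.testing.assert_allclose(out1["value"], out2["value"])


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        comp = compare_groups({"a": v, "b": v, "c": v})
        assert comp.test == "one-way ANOVA"
        assert comp.p > 0.99

    def test_degenerate_constant_data(self):
        v = np.ones(5)
        comp = compare_groups({"a": v, "b": v, "c": v})
        assert comp.p == 1.0
        assert any("degenerate" in s for s in comp.decision_path)

    def test_nonnormal_data_routes_to_kruskal(self, rng):
        groups = {g: np.exp(rng.normal(size=30) * 3) for g in "abc"}
        comp = compare_groups(groups)
        assert comp.test == "Kruskal-Wallis"
        assert comp.posthoc is not None and "p_adj" in comp.posthoc

    def test_unequal_variance_routes_to_welch(self, rng):
        groups = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40),
                  "c": rng.normal(0, 12, 40)}
        comp = compare_groups(groups)
        assert comp.test == "Welch ANOVA"

    def test_small_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="'b'"):
            compare_groups({"a": np.arange(5.0), "b": np.arange(2.0),
                            "c": np.arange(4.0)})

    def test_type_i_error_calibrated_gaussian_null(self):
        """Full decision tree rejects ~5% of Gaussian nulls (n=10/9/8)."""
        rng = np.random.default_rng(42)
        reps, hits = 400, 0
        for _ in range(reps):
            comp = compare_groups({"a": rng.normal(size=10),
                                   "b": rng.normal(size=9),
                                   "c": rng.normal(size=8)})
            hits += comp.p < 0.05
        assert abs(hits / reps - 0.05) <= 0.025

    def test_power_at_three_pooled_sd_shift(self):
        """A 3-SD group shift at study group sizes is essentially always found."""
        rng = np.random.default_rng(7)
        reps, hits = 300, 0
        for _ in range(reps):
            comp = compare_groups({"a": rng.normal(0, 1, 10),
                                   "b": rng.normal(0, 1, 9),
                                   "c": rng.normal(3.0, 1, 8)})
            hits += comp.p < 0.05
        assert hits / reps > 0.95


class TestBlinding:
    def table(self):
        return long_table([("p1", "non-AF", "i1", "m", 1.0),
                           ("p2", "paroxysmal", "i1", "m", 2.0),
                           ("p3", "persistent", "i1", "m", 3.0)])

    def test_round_trip_identity(self):
        tab = self.table()
        blinded, key = blind(tab, seed=5)
        restored = unblind(blinded, key)
        pd.testing.assert_frame_equal(restored, tab)

    def test_no_group_string_leaks(self):
        tab = self.table()
        blinded, _ = blind(tab, seed=5)
        dump = blinded.to_csv()
        for name in ("non-AF", "paroxysmal", "persistent"):
            assert name not in dump

    def test_wrong_key_errors_without_partial_restore(self):
        tab = self.table()
        blinded, key = blind(tab, seed=5)
        bad_key = {"G0000000": "non-AF"}
        with pytest.raises(ValueError, match="wrong key"):
            unblind(blinded, bad_key)

    def test_different_seeds_differ(self):
        tab = self.table()
        assignments = set()
        for seed in range(100):
            _, key = blind(tab, seed=seed)
            assignments.add(tuple(sorted(key.items())))
        assert len(assignments) > 50


class TestReportTables:
    def study(self):
        rng = np.random.default_rng(0)
        rows = []
        for gi, g in enumerate(["gA", "gB", "gC"]):
            for p in range(4):
                for i in range(2):
                    for _ in range(3):
                        rows.append((f"{g}_p{p}", g, f"{g}_p{p}_i{i}",
                                     "size", float(rng.normal(10 + gi))))
        return long_table(rows)

    def test_empty_study_header_only(self):
        table, text = report_tables(long_table([]), [])
        assert len(table) == 0
        assert "metric" in text

    def test_footer_counts_match_provenance(self):
        study = self.study()
        prov = provenance_counts(study)
        per_patient = aggregate(study)
        comp = compare_groups(per_patient, metric="size")
        table, _ = report_tables(per_patient, [comp], provenance=prov)
        footer = table[table["metric"] == "# images(# patients)"].iloc[0]
        assert footer["gA"] == "8(4)"
        clusters = table[table["metric"] == "# clusters analyzed"].iloc[0]
        assert clusters["gA"] == "24"

    def test_csv_round_trip(self, tmp_path):
        study = self.study()
        per_patient = aggregate(study)
        comp = compare_groups(per_patient, metric="size")
        table, text = report_tables(per_patient, [comp])
        table.to_csv(tmp_path / "r.csv", index=False)
        back = pd.read_csv(tmp_path / "r.csv")
        assert back.shape == table.shape
        assert back["metric"].tolist() == table["metric"].tolist()
        assert back["p"].iloc[0] == pytest.approx(float(table["p"].iloc[0]))

    def test_missing_comparison_warns_blank(self):
        per_patient = aggregate(self.study())
        with pytest.warns(UserWarning, match="no comparison"):
            table, _ = report_tables(per_patient, [])
        assert (table["p"] == "").all()
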