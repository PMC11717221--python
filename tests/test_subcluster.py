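"""Change-matrix sub-clustering, Kruskal-Wallis test, report tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal as scipy_kruskal

from gmgait import subcluster as sc
from gmgait import synthetic as syn
from gmgait.errors import DegenerateInputError, MissingExamError


def make_exams(values_e1, values_e2, columns=None):
    if columns is None:
        columns = sc.DELTA_COLUMNS
    ids = [f"p{i}" for i in range(len(values_e1))]
    e1 = pd.DataFrame(values_e1, columns=columns)
    e1.insert(0, "subject_id", ids)
    e2 = pd.DataFrame(values_e2, columns=columns)
    e2.insert(0, "subject_id", ids)
    return e1, e2


class TestChangeMatrix:
    def test_identical_exams_give_zero(self):
        v = np.random.default_rng(0).normal(size=(4, 7))
        e1, e2 = make_exams(v, v)
        delta = sc.build_change_matrix(e1, e2).delta
        assert np.allclose(delta.to_numpy(), 0.0)

    def test_columnwise_arithmetic(self):
        e1, e2 = make_exams(np.full((3, 7), 15.4), np.full((3, 7), 10.5))
        delta = sc.build_change_matrix(e1, e2).delta
        assert np.allclose(delta.to_numpy(), -4.9)

    def test_shape_31_by_7(self, outcome_specs):
        e1, e2, _ = syn.generate_paired_outcomes(12, 19, outcome_specs["SUB_1"],
                                                 outcome_specs["SUB_2"], seed=0)
        assert sc.build_change_matrix(e1, e2).delta.shape == (31, 7)

    def test_unpaired_subject_raises_with_ids(self):
        e1, e2 = make_exams(np.zeros((3, 7)), np.zeros((3, 7)))
        with pytest.raises(MissingExamError, match="p2"):
            sc.build_change_matrix(e1, e2.iloc[:2])

    def test_exam_swap_negates(self):
        v1 = np.random.default_rng(1).normal(size=(5, 7))
        v2 = np.random.default_rng(2).normal(size=(5, 7))
        e1, e2 = make_exams(v1, v2)
        a = sc.build_change_matrix(e1, e2).delta
        b = sc.build_change_matrix(e2, e1).delta
        assert np.allclose(a.to_numpy(), -b.to_numpy())


class TestPcaSubcluster:
    def planted_delta(self, rng, n_resp=12, n_non=19):
        # responders: trunk obliquity RoM drops by 5 +- 1; others stay
        cols = sc.DELTA_COLUMNS
        d = rng.normal(0, 1, size=(n_resp + n_non, len(cols)))
        d[:n_resp, 0] -= 5.0
        delta = pd.DataFrame(d, columns=cols,
                             index=[f"p{i}" for i in range(n_resp + n_non)])
        truth = np.array(["SUB_1"] * n_resp + ["SUB_2"] * n_non)
        return sc.ChangeMatrix(delta=delta), truth

    def test_planted_recovery_over_20_seeds(self):
        """Planted responders (trunk RoM drop 5 +- 1, unit noise elsewhere)
        are recovered by PC1 sign.  The planted columns share a common
        scale, so the unscaled variant applies."""
        accs = []
        for seed in range(20):
            change, truth = self.planted_delta(np.random.default_rng(seed))
            res = sc.pca_subcluster(change, scale=False)
            accs.append((res.labels.to_numpy() == truth).mean())
        assert np.mean(accs) >= 0.90

    def test_dominant_column_concentrates_loading(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 0.05, size=(40, 7))
        d[:, 0] = rng.normal(0, 5.0, size=40)
        delta = pd.DataFrame(d, columns=sc.DELTA_COLUMNS,
                             index=[f"p{i}" for i in range(40)])
        res = sc.pca_subcluster(sc.ChangeMatrix(delta=delta), scale=False)
        assert abs(res.loadings["rom_trunk_obl"]) > 0.9

    def test_sign_flip_swaps_labels_exactly(self):
        change, _ = self.planted_delta(np.random.default_rng(3))
        a = sc.pca_subcluster(change)
        b = sc.pca_subcluster(sc.ChangeMatrix(delta=-change.delta))
        assert np.allclose(a.pc1_scores.to_numpy(), -b.pc1_scores.to_numpy())
        swap = {"SUB_1": "SUB_2", "SUB_2": "SUB_1"}
        assert (b.labels.map(swap) == a.labels).all()

    def test_orientation_improvement_is_positive(self):
        change, truth = self.planted_delta(np.random.default_rng(4))
        res = sc.pca_subcluster(change)
        assert res.loadings["rom_trunk_obl"] < 0
        # the group whose trunk RoM dropped scores positive on average
        assert res.pc1_scores[truth == "SUB_1"].mean() > 0

    def test_zero_delta_rejected(self):
        delta = pd.DataFrame(np.zeros((5, 7)), columns=sc.DELTA_COLUMNS)
        with pytest.raises(DegenerateInputError):
            sc.pca_subcluster(sc.ChangeMatrix(delta=delta))


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = sc.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(27.0 / 7.0, abs=1e-9)
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_identical_samples(self):
        h, p = sc.kruskal_wallis([2.0, 2.0], [2.0, 2.0])
        assert (h, p) == (0.0, 1.0)

    def test_equal_distributions_h_zero(self):
        h, p = sc.kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(size=9)
        h1, p1 = sc.kruskal_wallis(a, b)
        h2, p2 = sc.kruskal_wallis(a + 100.0, b + 100.0)
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_scipy_on_100_random_samples_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
            b = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            h, p = sc.kruskal_wallis(a, b)
            ref = scipy_kruskal(a, b)
            assert h == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestCompareTables:
    def make_sub(self, ids1, ids2):
        ids = list(ids1) + list(ids2)
        labels = pd.Series(["SUB_1"] * len(ids1) + ["SUB_2"] * len(ids2),
                           index=ids, name="subcluster")
        scores = pd.Series(np.r_[np.ones(len(ids1)), -np.ones(len(ids2))],
                           index=ids, name="pc1_score")
        return sc.SubclusterResult(pc1_scores=scores, labels=labels,
                                   loadings=pd.Series(dtype=float), flipped=False)

    def test_table_shapes(self, outcome_specs):
        e1, e2, truth = syn.generate_paired_outcomes(12, 19, outcome_specs["SUB_1"],
                                                     outcome_specs["SUB_2"], seed=0)
        sub = self.make_sub(truth.index[truth == "SUB_1"],
                            truth.index[truth == "SUB_2"])
        within, between = sc.compare_within_and_between(sub, e1, e2)
        assert len(within) == 8     # 2 groups x 4 parameters
        assert len(between) == 7    # 3 EMG summaries + 4 exam scalars

    def test_identical_groups_give_p_one(self):
        vals = np.tile(np.arange(6.0), (7, 1)).T   # same values in both groups
        e1, e2 = make_exams(vals, vals)
        sub = self.make_sub([f"p{i}" for i in range(3)],
                            [f"p{i}" for i in range(3, 6)])
        within, between = sc.compare_within_and_between(sub, e1, e2)
        assert (within["p"] == 1.0).all()
        assert not within["significant"].any()

    def test_between_group_emg_calibration(self, outcome_specs):
        e1, e2, truth = syn.generate_paired_outcomes(12, 19, outcome_specs["SUB_1"],
                                                     outcome_specs["SUB_2"], seed=0)
        sub = self.make_sub(truth.index[truth == "SUB_1"],
                            truth.index[truth == "SUB_2"])
        _, between = sc.compare_within_and_between(sub, e1, e2)
        row = between.set_index("parameter").loc["emg_mean"]
        assert abs(row["sub1_mean"] - 79.5) <= 2 * 19.2 / np.sqrt(12)
        assert abs(row["sub2_mean"] - 68.6) <= 2 * 8.7 / np.sqrt(19)


class TestSurgeryTable:
    @staticmethod
    def records_from_counts(counts_by_group):
        rows = []
        labels = {}
        for grp, (n, counts) in counts_by_group.items():
            for i in range(n):
                labels[f"{grp}_{i}"] = grp
            slot = 0
            for surg_type, cnt in counts.items():
                for _ in range(cnt):
                    rows.append({"subject_id": f"{grp}_{slot % n}",
                                 "surgery_type": surg_type})
                    slot += 1
        return pd.DataFrame(rows), pd.Series(labels, name="subcluster")

    def test_empty_records_all_zero(self):
        sub_labels = pd.Series({"a": "SUB_1", "b": "SUB_2"})
        rec = pd.DataFrame(columns=["subject_id", "surgery_type"])
        table = sc.tabulate_surgeries(rec, sub_labels)
        assert (table["total_distal"] == 0).all()
        assert (table["total_proximal"] == 0).all()

    def test_published_sub1_row_totals(self):
        rec, labels = self.records_from_counts({
            "SUB_1": (12, {"baumann": 4, "strayer": 2, "bony_foot": 3,
                           "tibialis_posterior_lengthening": 1,
                           "femoral_derotation": 6, "rectus_transfer": 3,
                           "hamstring_lengthening": 3})})
        table = sc.tabulate_surgeries(rec, labels).set_index("group")
        assert table.loc["SUB_1", "total_distal"] == 10
        assert table.loc["SUB_1", "total_proximal"] == 12

    def test_total_row_adds_groups(self):
        rec, labels = self.records_from_counts({
            "SUB_1": (3, {"baumann": 2, "rectus_transfer": 1}),
            "SUB_2": (4, {"baumann": 1, "strayer": 2})})
        table = sc.tabulate_surgeries(rec, labels).set_index("group")
        for col in ("baumann", "strayer", "total_distal", "total_proximal"):
            assert table.loc["Total", col] == (table.loc["SUB_1", col]
                                               + table.loc["SUB_2", col])

    def test_unknown_type_counted_as_other(self):
        rec = pd.DataFrame({"subject_id": ["a"], "surgery_type": ["tendo_achilles"]})
        labels = pd.Series({"a": "SUB_2"})
        table = sc.tabulate_surgeries(rec, labels).set_index("group")
        assert table.loc["SUB_2", "other"] == 1


@pytest.mark.parametrize("emg,rom,expected", [
    (80.0, 35.0, "likely_responder"),
    (60.0, 35.0, "motor_control_limitation"),
    (80.0, 25.0, "structural_limitation"),
])
def test_responder_heuristic_rule(emg, rom, expected):
    assert sc.responder_heuristic(emg, rom) == expected
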