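"""Mixed-group construction and univariate AUC screening."""

import numpy as np
import pandas as pd
import pytest

from kernelharm.converter import ConverterConfig, build_converter
from kernelharm.egfr import (
    GROUP_KEYS,
    assign_mixed,
    auc_distribution,
    build_groups,
    build_groups_from_tables,
    univariate_auc,
)
from kernelharm.radfeat import FeatureTable, extract_table

from oracles import auc_pair_counting


class TestAssignMixed:
    def test_near_equal_arms(self, tiny_cohort):
        a = assign_mixed(tiny_cohort, seed=3)
        assert a.counts == {"smooth": 3, "sharp": 3}

    def test_odd_split_sharp_gets_extra(self):
        # 223 patients -> 111 smooth / 112 sharp
        class FakeCohort:
            records = [type("R", (), {"id": f"p{i}"})() for i in range(223)]

            def __len__(self):
                return 223

        a = assign_mixed(FakeCohort(), seed=0)
        assert a.counts == {"smooth": 111, "sharp": 112}

    def test_deterministic(self, tiny_cohort):
        assert assign_mixed(tiny_cohort, 5).arms == assign_mixed(tiny_cohort, 5).arms


class TestUnivariateAUC:
    def test_perfect_separation(self):
        assert univariate_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_tied_values_give_half(self):
        assert univariate_auc([5, 5, 5, 5], [0, 1, 0, 1],
                              orientation_correct=False) == 0.5

    def test_hand_counted_examples(self):
        assert univariate_auc([1, 2, 3, 4], [0, 0, 1, 1],
                              orientation_correct=False) == 1.0
        assert univariate_auc([1, 3, 2, 4], [0, 0, 1, 1],
                              orientation_correct=False) == 0.75

    def test_matches_pair_counting_oracle(self, rng):
        """Rank-based AUC equals the exhaustive U-statistic on <=50 patients."""
        for _ in range(50):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            values = np.round(rng.normal(size=n), 1)  # induce ties
            got = univariate_auc(values, labels, orientation_correct=False)
            assert got == pytest.approx(auc_pair_counting(values, labels))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        values = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        assert univariate_auc(values, labels, orientation_correct=False) == (
            pytest.approx(roc_auc_score(labels, values))
        )

    def test_orientation_correction_floor(self, rng):
        values = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        assert univariate_auc(values, labels) >= 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            univariate_auc([1, 2, 3, 4], [1, 1, 1, 1])


@pytest.fixture(scope="module")
def identity_groups(tiny_cohort):
    to_smo = build_converter(ConverterConfig(direction="to_smooth", n_layers=2,
                                             channels=4, seed=0))
    to_shp = build_converter(ConverterConfig(direction="to_sharp", n_layers=2,
                                             channels=4, seed=0))
    assignment = assign_mixed(tiny_cohort, seed=9)
    return build_groups(tiny_cohort, assignment, to_smo, to_shp)


class TestBuildGroups:
    def test_identity_converters_collapse_to_ori_mix(self, identity_groups):
        ori = identity_groups.tables["ori_mix"].data
        for key in ("conv_mix_smo", "conv_mix_shp"):
            pd.testing.assert_frame_equal(identity_groups.tables[key].data, ori)

    def test_tables_share_patients_and_columns(self, identity_groups):
        pats = identity_groups.tables["ori_mix"].patients
        feats = identity_groups.tables["ori_mix"].features
        for key in GROUP_KEYS:
            assert identity_groups.tables[key].patients == pats
            assert identity_groups.tables[key].features == feats

    def test_direction_mismatch_rejected(self, tiny_cohort):
        wrong = build_converter(ConverterConfig(direction="to_sharp", n_layers=2,
                                                channels=4))
        a = assign_mixed(tiny_cohort, 1)
        with pytest.raises(ValueError):
            build_groups(tiny_cohort, a, wrong, wrong)

    def test_row_selection_matches_volume_path(self, tiny_cohort, identity_groups):
        """Assembling mixed tables from per-setting tables reproduces the
        volume-level construction exactly (identity converters)."""
        vols_smo = {r.id: r.smooth_image for r in tiny_cohort.records}
        vols_shp = {r.id: r.sharp_image for r in tiny_cohort.records}
        masks = {r.id: r.mask.values for r in tiny_cohort.records}
        t_smo = extract_table(vols_smo, masks, setting="ori_smo")
        t_shp = extract_table(vols_shp, masks, setting="ori_shp")
        # identity converters: conv_smo is the (unchanged) sharp rendering
        # and conv_shp the (unchanged) smooth rendering
        rebuilt = build_groups_from_tables(
            identity_groups.assignment, t_smo, t_shp, conv_smo=t_shp,
            conv_shp=t_smo,
        )
        for key in GROUP_KEYS:
            pd.testing.assert_frame_equal(
                rebuilt.tables[key].data, identity_groups.tables[key].data
            )


class TestAUCDistribution:
    def _labels(self, cohort):
        return {r.id: r.label for r in cohort.records}

    def test_identity_groups_report_no_difference(self, tiny_cohort, identity_groups):
        rep = auc_distribution(identity_groups, self._labels(tiny_cohort))
        for key in ("conv_mix_smo", "conv_mix_shp"):
            assert rep.comparisons[key]["no_difference"]
            assert rep.comparisons[key]["p"] == 1.0

    def test_median_mad_closed_form(self):
        from kernelharm.egfr import _mad

        v = np.array([0.5, 0.6, 0.7])
        assert np.median(v) == pytest.approx(0.6)
        assert _mad(v) == pytest.approx(0.1)

    def test_patient_order_invariance(self, tiny_cohort, identity_groups):
        labels = self._labels(tiny_cohort)
        rep1 = auc_distribution(identity_groups, labels)
        # permute rows of every table
        from kernelharm.egfr import GroupedFeatureTables

        perm = identity_groups.tables["ori_mix"].patients[::-1]
        shuffled = GroupedFeatureTables(
            tables={
                k: FeatureTable(data=t.data.loc[perm], setting=t.setting)
                for k, t in identity_groups.tables.items()
            },
            assignment=identity_groups.assignment,
        )
        rep2 = auc_distribution(shuffled, labels)
        pd.testing.assert_frame_equal(
            rep1.per_feature.sort_index(), rep2.per_feature.sort_index()
        )
        assert rep1.medians == rep2.medians

    def test_label_shuffle_null_centers_aucs(self, rng):
        """Shuffled labels: per-feature corrected AUCs stay near the analytic
        null expectation, with no systematic difference between groups."""
        n, nf = 40, 12
        ids = [f"p{i}" for i in range(n)]
        data = pd.DataFrame(rng.normal(size=(n, nf)), index=ids,
                            columns=[f"f{j}" for j in range(nf)])
        data.index.name = "id"
        means = {k: [] for k in GROUP_KEYS}
        for rep in range(200):
            labels = dict(zip(ids, rng.permutation([0, 1] * (n // 2))))
            y = np.array([labels[p] for p in ids])
            for key in GROUP_KEYS:
                aucs = [
                    univariate_auc(data[f].to_numpy(), y) for f in data.columns
                ]
                means[key].append(np.mean(aucs))
        grand = {k: np.mean(v) for k, v in means.items()}
        # corrected null mean is slightly above 0.5; all groups identical here
        assert 0.5 < grand["ori_mix"] < 0.65
        assert abs(grand["conv_mix_smo"] - grand["ori_mix"]) < 1e-12

    def test_missing_labels_rejected(self, tiny_cohort, identity_groups):
        with pytest.raises(ValueError):
            auc_distribution(identity_groups, {"nope": 1})
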