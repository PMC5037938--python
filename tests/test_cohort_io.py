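"""Cohort reading, validation, normalization and summaries."""

import numpy as np
import pandas as pd
import pytest

from tbinflam.cohort_io import (
    FIT_TIMES_H,
    canonical_mediator,
    denormalize_cohort,
    group_mean_curves,
    normalize_cohort,
    peak_times,
    read_cohort,
    write_cohort,
)


@pytest.fixture
def cohort_files(tmp_path, two_patient_cohort):
    clin = tmp_path / "clinical.csv"
    med = tmp_path / "mediators.csv"
    write_cohort(two_patient_cohort, clin, med)
    return clin, med


class TestRead:
    def test_two_patient_fixture_loads(self, cohort_files):
        cohort = read_cohort(*cohort_files)
        assert cohort.n_patients() == 2
        assert len(cohort.series.groupby(["patient_id", "mediator"])) == 26
        assert set(cohort.clinical["group"]) == {"survivor", "non-survivor"}

    def test_unknown_mediator_reported_and_dropped(self, cohort_files, tmp_path):
        clin, med = cohort_files
        df = pd.read_csv(med)
        bad = pd.DataFrame(
            [{"patient_id": "p1", "mediator": "IL-99", "time_h": 5.0,
              "conc_pg_ml": 1.0}]
        )
        pd.concat([df, bad]).to_csv(med, index=False)
        with pytest.warns(UserWarning, match="dropped 1"):
            cohort = read_cohort(clin, med)
        assert len(cohort.rejected_rows) == 1
        assert cohort.rejected_rows["reason"].iloc[0] == "unknown mediator"
        assert "IL-99" not in set(cohort.series["mediator"])

    def test_missing_gcs_column_is_format_error(self, cohort_files, tmp_path):
        clin, med = cohort_files
        df = pd.read_csv(clin).drop(columns=["gcs"])
        df.to_csv(clin, index=False)
        with pytest.raises(ValueError, match="gcs"):
            read_cohort(clin, med)

    def test_series_for_unknown_patient_is_linkage_error(self, cohort_files):
        clin, med = cohort_files
        df = pd.read_csv(med)
        df.loc[0, "patient_id"] = "ghost"
        df.to_csv(med, index=False)
        with pytest.raises(ValueError, match="unknown patients"):
            read_cohort(clin, med)

    def test_group_label_must_match_gos12(self, cohort_files):
        clin, med = cohort_files
        df = pd.read_csv(clin)
        df["group"] = ["non-survivor", "non-survivor"]  # p1 has gos12=4
        df.to_csv(clin, index=False)
        with pytest.raises(ValueError, match="contradicts"):
            read_cohort(clin, med)

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("tnf-a", "TNF-a"),
            ("TNF-α", "TNF-a"),
            ("mip-1β", "MIP-1b"),
            ("il-6", "IL-6"),
            ("IL-99", None),
        ],
    )
    def test_mediator_name_canonicalization(self, raw, expected):
        assert canonical_mediator(raw) == expected


class TestNormalize:
    def test_minmax_maps_to_0_10(self, two_patient_cohort):
        norm = normalize_cohort(two_patient_cohort)
        by_med = norm.series.groupby("mediator")["conc_pg_ml"]
        np.testing.assert_allclose(by_med.max().to_numpy(), 10.0)
        np.testing.assert_allclose(by_med.min().to_numpy(), 0.0, atol=1e-12)

    def test_midpoint_example(self, two_patient_cohort):
        """A value of 7 with cohort-wide min 2, max 12 normalizes to 5."""
        cohort = two_patient_cohort
        series = cohort.series.copy()
        mask = series["mediator"] == "IL-6"
        vals = np.full(mask.sum(), 7.0)
        vals[0], vals[1] = 2.0, 12.0
        series.loc[mask, "conc_pg_ml"] = vals
        from tbinflam.cohort_io import MediatorCohort

        norm = normalize_cohort(
            MediatorCohort(clinical=cohort.clinical, series=series)
        )
        out = norm.series.loc[norm.series["mediator"] == "IL-6", "conc_pg_ml"]
        assert sorted(set(np.round(out, 9))) == [0.0, 5.0, 10.0]

    def test_double_normalization_rejected(self, two_patient_cohort):
        norm = normalize_cohort(two_patient_cohort)
        with pytest.raises(ValueError, match="already normalized"):
            normalize_cohort(norm)

    def test_denormalization_recovers_raw(self, two_patient_cohort):
        norm = normalize_cohort(two_patient_cohort)
        back = denormalize_cohort(norm)
        np.testing.assert_allclose(
            back.series["conc_pg_ml"].to_numpy(),
            two_patient_cohort.series["conc_pg_ml"].to_numpy(),
            atol=1e-9,
        )

    def test_constant_mediator_maps_to_zero_with_warning(self, two_patient_cohort):
        cohort = two_patient_cohort
        series = cohort.series.copy()
        series.loc[series["mediator"] == "VEGF", "conc_pg_ml"] = 3.3
        from tbinflam.cohort_io import MediatorCohort

        with pytest.warns(UserWarning, match="constant"):
            norm = normalize_cohort(
                MediatorCohort(clinical=cohort.clinical, series=series)
            )
        out = norm.series.loc[norm.series["mediator"] == "VEGF", "conc_pg_ml"]
        assert (out == 0.0).all()


class TestGroupMeanCurves:
    def _mini_cohort(self, sample_times, values_by_patient):
        from tbinflam.cohort_io import MediatorCohort

        pids = list(values_by_patient)
        clinical = pd.DataFrame(
            {
                "patient_id": pids,
                "age": 30.0,
                "sex": "M",
                "gcs": 6,
                "gos6": [4] * (len(pids) - 1) + [1],
                "gos12": [4] * (len(pids) - 1) + [1],
                "group": ["survivor"] * (len(pids) - 1) + ["non-survivor"],
            }
        )
        rows = []
        for pid, vals in values_by_patient.items():
            for t, v in zip(sample_times, vals):
                rows.append(
                    {"patient_id": pid, "mediator": "IL-6", "time_h": t,
                     "conc_pg_ml": v}
                )
        return MediatorCohort(
            clinical=clinical, series=pd.DataFrame(rows), normalized=True
        )

    def test_exact_sample_times_pass_through(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        cohort = self._mini_cohort(
            FIT_TIMES_H, {"a": vals, "b": vals, "n": [9.0] * 6}
        )
        curves = group_mean_curves(cohort)
        np.testing.assert_allclose(curves.loc[("survivor", "IL-6")], vals)
        np.testing.assert_allclose(curves.loc[("non-survivor", "IL-6")], 9.0)

    def test_hand_computed_mean(self):
        cohort = self._mini_cohort(
            FIT_TIMES_H,
            {"a": [1, 1, 1, 1, 1, 1], "b": [3, 5, 3, 3, 3, 3], "n": [0] * 6},
        )
        curves = group_mean_curves(cohort)
        np.testing.assert_allclose(
            curves.loc[("survivor", "IL-6")], [2, 3, 2, 2, 2, 2]
        )

    def test_nearest_within_window_and_missing_cells(self):
        # samples at 5 h and 100 h: 5 h matches t=0 and t=17 (within 12 h);
        # 100 h matches t=104; t=35/60/82 have no sample in range
        cohort = self._mini_cohort(
            [5.0, 100.0], {"a": [2.0, 8.0], "n": [4.0, 4.0]}
        )
        curves = group_mean_curves(cohort)
        row = curves.loc[("survivor", "IL-6")]
        assert row[0.0] == 2.0 and row[17.0] == 2.0 and row[104.0] == 8.0
        assert row[[35.0, 60.0, 82.0]].isna().all()

    def test_permutation_invariance_over_patient_order(
        self, default_cohort_normalized
    ):
        from tbinflam.cohort_io import MediatorCohort

        cohort = default_cohort_normalized
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(cohort.clinical))
        shuffled = MediatorCohort(
            clinical=cohort.clinical.iloc[perm].reset_index(drop=True),
            series=cohort.series.sample(frac=1.0, random_state=5).reset_index(
                drop=True
            ),
            normalized=True,
        )
        a = group_mean_curves(cohort)
        b = group_mean_curves(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_group_is_error(self):
        cohort = self._mini_cohort(FIT_TIMES_H, {"a": [1] * 6, "b": [2] * 6})
        # both patients survivors -> no non-survivor group
        cohort.clinical.loc[:, "gos12"] = 4
        cohort.clinical.loc[:, "group"] = "survivor"
        with pytest.raises(ValueError, match="empty group"):
            group_mean_curves(cohort)


class TestPeakTimes:
    def _series_cohort(self, samples):
        from tbinflam.cohort_io import MediatorCohort

        clinical = pd.DataFrame(
            {
                "patient_id": list(samples),
                "age": 30.0, "sex": "M", "gcs": 6,
                "gos6": 4, "gos12": 4, "group": "survivor",
            }
        )
        rows = [
            {"patient_id": pid, "mediator": "TNF-a", "time_h": t, "conc_pg_ml": v}
            for pid, pts in samples.items()
            for t, v in pts
        ]
        return MediatorCohort(clinical=clinical, series=pd.DataFrame(rows))

    def test_monotone_decreasing_peaks_at_first_sample(self):
        cohort = self._series_cohort({"a": [(0, 9), (10, 5), (50, 1)]})
        assert peak_times(cohort, "TNF-a")["a"] == 0.0

    def test_interior_maximum(self):
        cohort = self._series_cohort({"a": [(0, 1), (20, 7), (50, 2)]})
        assert peak_times(cohort, "TNF-a")["a"] == 20.0

    def test_tie_resolves_to_earliest(self):
        cohort = self._series_cohort({"a": [(10, 5.0), (50, 5.0)]})
        assert peak_times(cohort, "TNF-a")["a"] == 10.0

    def test_patient_without_samples_skipped_with_warning(self):
        cohort = self._series_cohort({"a": [(0, 1), (10, 2)]})
        cohort.clinical.loc[1] = ["b", 30.0, "M", 6, 4, 4, "survivor"]
        with pytest.warns(UserWarning, match="no TNF-a samples"):
            out = peak_times(cohort, "TNF-a")
        assert "b" not in out.index
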