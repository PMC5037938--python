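"""PCA characterization and statistical screening."""

import numpy as np
import pandas as pd
import pytest

from tbinflam.cohort_io import MEDIATOR_PANEL
from tbinflam.pca_stats import (
    gcs_gos_correlation,
    group_time_anova,
    observation_matrix,
    run_pca,
    screen_mediators,
    top_mediators,
)

BLOCK = ("TNF-a", "MIP-1a", "MIP-1b", "IL-8", "IL-10", "IL-6")


def block_panel(rng, n=200, block_scale=3.0, noise=0.3) -> pd.DataFrame:
    """13-mediator observations with one dominant correlated block."""
    shared = rng.normal(0, block_scale, size=n)
    data = {}
    for m in MEDIATOR_PANEL:
        if m in BLOCK:
            data[m] = shared * rng.uniform(0.8, 1.2) + rng.normal(0, noise, n)
        else:
            data[m] = rng.normal(0, noise, n)
    return pd.DataFrame(data)


class TestRunPca:
    def test_single_direction_gives_pc1_everything(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=50)
        x = np.outer(t, rng.uniform(0.5, 1.5, 13))
        with pytest.warns(UserWarning, match="rank"):
            result = run_pca(x)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)
        assert result.effective_rank == 1

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        result = run_pca(block_panel(rng))
        gram = result.loadings @ result.loadings.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_variance_fractions_sum_to_at_most_one(self):
        rng = np.random.default_rng(2)
        result = run_pca(block_panel(rng))
        assert result.explained_variance_ratio.sum() <= 1.0 + 1e-12

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(3)
        x = block_panel(rng, n=40)
        result = run_pca(x)
        centered = x.to_numpy() - x.to_numpy().mean(axis=0)
        back = result.scores @ result.loadings
        np.testing.assert_allclose(back, centered, atol=1e-9)

    def test_dominant_block_carries_pc1(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            result = run_pca(block_panel(rng))
            top6 = top_mediators(result, 1)[:6]
            hits += set(top6) == set(BLOCK)
        assert hits >= 19

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            run_pca(np.zeros((1, 13)))


class TestTopMediators:
    def test_k_zero_rejected(self):
        rng = np.random.default_rng(1)
        result = run_pca(block_panel(rng))
        with pytest.raises(ValueError):
            top_mediators(result, 0)

    def test_ties_break_by_panel_order(self):
        from tbinflam.pca_stats import PcaResult

        n = 4
        loadings = np.eye(n) * 0.0
        loadings[0, :] = 0.5  # identical |loading| on all four mediators
        # orthonormalize: single component with equal weights
        result = PcaResult(
            loadings=loadings[:1],
            explained_variance_ratio=np.array([1.0]),
            scores=np.zeros((2, 1)),
            mediators=tuple(MEDIATOR_PANEL[:n]),
            effective_rank=1,
        )
        assert top_mediators(result, 1) == list(MEDIATOR_PANEL[:n])


class TestScreen:
    def test_identical_groups_fold_change_one(self, two_patient_cohort):
        """Mirror the same two distinct patients into both groups: the AUC
        ratio is exactly 1 and nothing is significant."""
        from tbinflam.cohort_io import MediatorCohort, normalize_cohort

        cohort = two_patient_cohort
        clinical = pd.DataFrame(
            {
                "patient_id": ["s1", "s2", "n1", "n2"],
                "age": 30.0, "sex": "M", "gcs": 6,
                "gos6": [4, 4, 1, 1], "gos12": [4, 4, 1, 1],
                "group": ["survivor", "survivor",
                          "non-survivor", "non-survivor"],
            }
        )
        p1 = cohort.series[cohort.series["patient_id"] == "p1"]
        p2 = cohort.series[cohort.series["patient_id"] == "p2"]
        mirrored = MediatorCohort(
            clinical=clinical,
            series=pd.concat(
                [
                    p1.assign(patient_id="s1"), p2.assign(patient_id="s2"),
                    p1.assign(patient_id="n1"), p2.assign(patient_id="n2"),
                ]
            ),
        )
        table = screen_mediators(normalize_cohort(mirrored))
        np.testing.assert_allclose(table["auc_fold_change"].to_numpy(), 1.0)
        assert not table["significant"].any()

    def test_constant_two_fold_series(self):
        """Non-survivor level constant at twice the survivor level gives an
        AUC fold change of exactly 2."""
        from tbinflam.cohort_io import MediatorCohort

        clinical = pd.DataFrame(
            {
                "patient_id": ["s1", "s2", "n1", "n2"],
                "age": 30.0, "sex": "M", "gcs": 6,
                "gos6": [4, 4, 1, 1], "gos12": [4, 4, 1, 1],
                "group": ["survivor", "survivor", "non-survivor", "non-survivor"],
            }
        )
        rows = []
        for pid, level in (("s1", 2.0), ("s2", 2.0), ("n1", 4.0), ("n2", 4.0)):
            for mediator in MEDIATOR_PANEL:
                for t in (0.0, 17.0, 35.0, 60.0, 82.0, 104.0):
                    rows.append(
                        {"patient_id": pid, "mediator": mediator,
                         "time_h": t, "conc_pg_ml": level}
                    )
        cohort = MediatorCohort(
            clinical=clinical, series=pd.DataFrame(rows), normalized=True
        )
        table = screen_mediators(cohort)
        np.testing.assert_allclose(table["auc_fold_change"].to_numpy(), 2.0)

    def test_auc_fold_change_scale_invariance(self, default_cohort_normalized):
        from tbinflam.cohort_io import MediatorCohort

        cohort = default_cohort_normalized
        scaled = MediatorCohort(
            clinical=cohort.clinical,
            series=cohort.series.assign(
                conc_pg_ml=cohort.series["conc_pg_ml"] * 0.37
            ),
            normalized=True,
        )
        a = screen_mediators(cohort)
        b = screen_mediators(scaled)
        np.testing.assert_allclose(
            a["auc_fold_change"].to_numpy(), b["auc_fold_change"].to_numpy(),
            rtol=1e-9,
        )

    def test_mechanistic_cohort_flags_planted_differences(
        self, default_cohort_normalized
    ):
        table = screen_mediators(default_cohort_normalized).set_index("mediator")
        # the strongly shifted model-driven analytes must be flagged
        for mediator in ("IL-6", "TNF-a", "IL-8"):
            assert table.loc[mediator, "significant"]


def _null_anova_frame(rng, n_s=29, n_ns=5, n_bins=5):
    rows = []
    for group, count in (("survivor", n_s), ("non-survivor", n_ns)):
        for i in range(count):
            for b in range(n_bins):
                rows.append(
                    {"value": rng.normal(), "group": group, "time_bin": b}
                )
    return pd.DataFrame(rows)


class TestAnovaCalibration:
    def test_type_i_error_near_alpha(self):
        """Under the null the interaction p-value flags ~5% at alpha=0.05."""
        rng = np.random.default_rng(99)
        flags = 0
        n_rep = 400
        for _ in range(n_rep):
            p = group_time_anova(_null_anova_frame(rng))["p_interaction"]
            flags += p < 0.05
        assert 0.03 <= flags / n_rep <= 0.07

    def test_planted_interaction_power(self):
        """A group-specific time slope of 3 sd over the window is detected
        with power at least 0.9."""
        rng = np.random.default_rng(7)
        detected = 0
        n_rep = 100
        for _ in range(n_rep):
            df = _null_anova_frame(rng)
            mask = df["group"] == "non-survivor"
            df.loc[mask, "value"] += 3.0 * df.loc[mask, "time_bin"] / 4.0
            detected += group_time_anova(df)["p_interaction"] < 0.05
        assert detected / n_rep >= 0.9


class TestGcsGos:
    def _patients(self, gcs, gos6):
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(len(gcs))],
                "gcs": gcs,
                "gos6": gos6,
                "group": ["survivor"] * len(gcs),
            }
        )

    def test_perfect_correlation(self):
        out = gcs_gos_correlation(self._patients([3, 6, 9, 12], [1, 2, 3, 4]))
        assert out["r"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        out = gcs_gos_correlation(self._patients([3, 6, 9, 12], [5, 4, 3, 2]))
        assert out["r"] == pytest.approx(-1.0)

    def test_null_r_small_on_average(self):
        rng = np.random.default_rng(21)
        rs = []
        for _ in range(100):
            gcs = rng.integers(3, 9, 30)
            gos = rng.integers(1, 6, 30)
            if np.std(gcs) == 0 or np.std(gos) == 0:
                continue
            rs.append(gcs_gos_correlation(self._patients(gcs, gos))["r"])
        assert abs(np.mean(rs)) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            gcs_gos_correlation(self._patients([6, 6, 6], [1, 2, 3]))


def test_observation_matrix_complete_rows(default_cohort_normalized):
    m = observation_matrix(default_cohort_normalized)
    assert list(m.columns) == list(MEDIATOR_PANEL)
    assert not m.isna().any().any()
    assert len(m) > 30
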