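"""PCA characterization and statistical screening of the mediator panel.

Screening follows the standard group-comparison battery for irregularly
sampled cytokine panels: a Welch t-test of overall levels, a two-way
fixed-effects ANOVA of group x time-bin (values first averaged into the
five 24-h slices, since sampling times differ across patients), a
trapezoidal AUC fold change of the group-mean curves
(non-survivor / survivor), and a Pearson correlation of admission GCS
against 6-month GOS.  Significance is assessed at alpha = 0.05 on the
group x time interaction term, with no multiple-testing correction.

PCA treats every normalized measurement as a point in 13-dimensional
mediator space; the first-component loadings identify the mediators
that carry the dominant shared variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .cohort_io import FIT_TIMES_H, MEDIATOR_PANEL, MediatorCohort, group_mean_curves
from .dybn import bin_slices

__all__ = [
    "PcaResult",
    "run_pca",
    "top_mediators",
    "screen_mediators",
    "group_time_anova",
    "gcs_gos_correlation",
    "plot_group_time_courses",
]

ALPHA = 0.05


@dataclass(frozen=True)
class PcaResult:
    """Loadings (components x mediators, orthonormal rows), explained
    variance fractions (non-increasing) and per-observation scores."""

    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray
    mediators: tuple[str, ...]
    effective_rank: int

    def __post_init__(self) -> None:
        k = self.loadings.shape[0]
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(k), atol=1e-9):
            raise ValueError("loadings are not orthonormal")
        if np.any(np.diff(self.explained_variance_ratio) > 1e-12):
            raise ValueError("explained variance fractions must be non-increasing")

    def loading_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings.T,
            index=list(self.mediators),
            columns=[f"PC{i + 1}" for i in range(self.loadings.shape[0])],
        )


def run_pca(
    matrix: pd.DataFrame | np.ndarray, mediators: tuple[str, ...] | None = None
) -> PcaResult:
    """Centered PCA of a (observations x 13 mediators) matrix.

    Components are ordered by explained variance.  With rank-deficient
    input the components beyond the data rank are flagged via
    ``effective_rank`` (their variance fractions are ~0).
    """
    if isinstance(matrix, pd.DataFrame):
        mediators = tuple(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        if mediators is None:
            mediators = tuple(MEDIATOR_PANEL[: x.shape[1]])
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two observations")
    if np.isnan(x).any():
        raise ValueError("observation matrix contains missing values")
    n_comp = min(x.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(x)
    evr = pca.explained_variance_ratio_
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
    if rank < n_comp:
        warnings.warn(
            f"input rank {rank} < {n_comp}; trailing components are noise",
            stacklevel=2,
        )
    return PcaResult(
        loadings=pca.components_,
        explained_variance_ratio=evr,
        scores=scores,
        mediators=mediators,
        effective_rank=rank,
    )


def top_mediators(pca: PcaResult, k: int) -> list[str]:
    """Mediators ranked by max |loading| over the first k components.

    Ties are broken by panel order.
    """
    if k < 1 or k > pca.loadings.shape[0]:
        raise ValueError(f"k must be in 1..{pca.loadings.shape[0]}")
    weight = np.abs(pca.loadings[:k]).max(axis=0)
    order = sorted(
        range(len(pca.mediators)), key=lambda i: (-weight[i], i)
    )
    return [pca.mediators[i] for i in order]


def observation_matrix(cohort: MediatorCohort) -> pd.DataFrame:
    """Complete patient x slice observations in 13-mediator space.

    Bins samples into the five 24-h slices and keeps rows observed for
    every panel mediator.
    """
    panel = bin_slices(cohort)
    cols = [m for m in MEDIATOR_PANEL if m in panel.values.columns]
    return panel.values[cols].dropna()


def group_time_anova(df: pd.DataFrame) -> pd.Series:
    """Two-way fixed-effects ANOVA of ``value ~ group * time_bin``.

    ``df`` needs columns ``value``, ``group``, ``time_bin``.  Returns
    p-values for the group main effect, the time main effect and the
    group x time interaction (type-II sums of squares, which are robust
    to the unbalanced survivor / non-survivor design).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("value ~ C(group) * C(time_bin)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return pd.Series(
        {
            "p_group": float(table.loc["C(group)", "PR(>F)"]),
            "p_time": float(table.loc["C(time_bin)", "PR(>F)"]),
            "p_interaction": float(table.loc["C(group):C(time_bin)", "PR(>F)"]),
        }
    )


def screen_mediators(cohort: MediatorCohort, alpha: float = ALPHA) -> pd.DataFrame:
    """Per-mediator statistical screen of survivors vs non-survivors.

    Returns one row per mediator with the Welch t-test p-value on all
    samples, the two-way group x time-bin ANOVA p-values, the AUC fold
    change (non-survivor / survivor, trapezoidal over the group-mean
    curves at the six fit times) and the significance flag
    (interaction p < alpha).  Mediators with a degenerate design (an
    empty group x bin cell) are skipped with a warning.
    """
    if not cohort.normalized:
        raise ValueError("cohort must be normalized before screening")
    panel = bin_slices(cohort)
    group_of = dict(zip(cohort.clinical["patient_id"], cohort.clinical["group"]))
    curves = group_mean_curves(cohort)
    times = np.array(FIT_TIMES_H)

    long = (
        panel.values.stack(future_stack=True)
        .rename("value")
        .reset_index()
        .rename(columns={"level_2": "mediator"})
        .dropna(subset=["value"])
    )
    long["group"] = long["patient_id"].map(group_of)
    long["time_bin"] = long["slice"]

    rows = []
    for mediator in panel.values.columns:
        sub = long[long["mediator"] == mediator]
        cell_counts = sub.groupby(["group", "time_bin"]).size()
        n_bins = sub["time_bin"].nunique()
        if len(cell_counts) < 2 * n_bins or (cell_counts < 1).any():
            warnings.warn(
                f"{mediator}: degenerate group x time design; skipped",
                stacklevel=2,
            )
            continue
        surv = sub.loc[sub["group"] == "survivor", "value"]
        nonsurv = sub.loc[sub["group"] == "non-survivor", "value"]
        t_p = float(sps.ttest_ind(surv, nonsurv, equal_var=False).pvalue)
        anova = group_time_anova(sub)

        s_curve = curves.loc[("survivor", mediator)].to_numpy(dtype=float)
        ns_curve = curves.loc[("non-survivor", mediator)].to_numpy(dtype=float)
        ok = ~(np.isnan(s_curve) | np.isnan(ns_curve))
        if ok.sum() < 2:
            warnings.warn(f"{mediator}: too few curve points for AUC", stacklevel=2)
            auc_s = auc_ns = fold = np.nan
        else:
            auc_s = float(np.trapezoid(s_curve[ok], times[ok]))
            auc_ns = float(np.trapezoid(ns_curve[ok], times[ok]))
            fold = auc_ns / auc_s if auc_s != 0 else np.inf
        rows.append(
            {
                "mediator": mediator,
                "t_p": t_p,
                "anova_p_group": anova["p_group"],
                "anova_p_time": anova["p_time"],
                "anova_p_interaction": anova["p_interaction"],
                "auc_survivor": auc_s,
                "auc_nonsurvivor": auc_ns,
                "auc_fold_change": fold,
                "significant": bool(anova["p_interaction"] < alpha),
            }
        )
    return pd.DataFrame(rows)


def gcs_gos_correlation(patients: pd.DataFrame) -> dict:
    """Pearson correlation of admission GCS vs 6-month GOS.

    Returns r, the p-value and a per-group scatter summary.  Raises when
    either variable has zero variance (the correlation is undefined).
    """
    if len(patients) < 3:
        raise ValueError("need at least three patients")
    gcs = patients["gcs"].to_numpy(dtype=float)
    gos = patients["gos6"].to_numpy(dtype=float)
    if np.std(gcs) == 0 or np.std(gos) == 0:
        raise ValueError("undefined correlation: a variable has zero variance")
    r, p = sps.pearsonr(gcs, gos)
    summary = (
        patients.groupby("group")[["gcs", "gos6"]]
        .agg(["mean", "std", "count"])
        .to_dict()
    )
    return {"r": float(r), "p": float(p), "by_group": summary}


def plot_group_time_courses(cohort: MediatorCohort, path) -> None:
    """Small-multiple group-mean time courses for the 13 mediators."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = group_mean_curves(cohort)
    fig, axes = plt.subplots(4, 4, figsize=(14, 10), sharex=True)
    mediators = [m for m in MEDIATOR_PANEL]
    for ax, mediator in zip(axes.flat, mediators):
        for group, style in (("survivor", "o-"), ("non-survivor", "s--")):
            row = curves.loc[(group, mediator)]
            ax.plot(list(row.index), row.to_numpy(), style, label=group)
        ax.set_title(mediator, fontsize=9)
    for ax in axes.flat[len(mediators):]:
        ax.axis("off")
    axes.flat[0].legend(fontsize=7)
    fig.supxlabel("hours post-injury")
    fig.supylabel("normalized level (0-10)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
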