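"""Reading, validation, normalization and summaries of CSF mediator cohorts.

A cohort couples a clinical table (one row per patient: demographics,
admission GCS, 6- and 12-month GOS) with a long-format mediator table
(one row per CSF sample: patient, mediator, hours post-injury,
concentration in pg/ml).  Outcome groups follow the 12-month Glasgow
Outcome Scale: GOS 1 = non-survivor, GOS > 1 = survivor.

Concentrations are min-max normalized per mediator to a common 0-10
scale across the whole cohort (both outcome groups jointly), matching
the 0-10 damage scale used by the mechanistic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MEDIATOR_PANEL",
    "FIT_TIMES_H",
    "MediatorCohort",
    "canonical_mediator",
    "read_cohort",
    "write_cohort",
    "normalize_cohort",
    "denormalize_cohort",
    "group_mean_curves",
    "peak_times",
]

#: The 13-analyte CSF Luminex panel, in canonical order.
MEDIATOR_PANEL: tuple[str, ...] = (
    "IL-1a", "IL-1b", "IL-2", "IL-4", "IL-5", "IL-6", "IL-8",
    "IL-10", "IL-13", "MIP-1a", "MIP-1b", "TNF-a", "VEGF",
)

#: Time points (hours post-injury) at which group-mean cytokine values
#: are computed for model fitting.
FIT_TIMES_H: tuple[float, ...] = (0.0, 17.0, 35.0, 60.0, 82.0, 104.0)

#: Window for assigning an irregular sample to a fit time point.
MATCH_WINDOW_H = 12.0

CLINICAL_COLUMNS = ("patient_id", "age", "sex", "gcs", "gos6", "gos12")
MEDIATOR_COLUMNS = ("patient_id", "mediator", "time_h", "conc_pg_ml")

_CANON = {name.lower(): name for name in MEDIATOR_PANEL}


def canonical_mediator(name: str) -> str | None:
    """Case-insensitive panel lookup; Greek letters are spelled out.

    Returns the canonical panel name, or None if the name is not on the
    13-analyte panel.
    """
    key = (
        str(name).strip()
        .replace("α", "a").replace("β", "b")
        .lower()
    )
    return _CANON.get(key)


def _derive_group(gos12: int) -> str:
    return "non-survivor" if gos12 == 1 else "survivor"


@dataclass(frozen=True)
class MediatorCohort:
    """Clinical records joined with long-format mediator time series.

    ``clinical`` has columns ``patient_id, age, sex, gcs, gos6, gos12,
    group``; ``series`` has ``patient_id, mediator, time_h, conc_pg_ml``.
    ``norm_stats`` holds the per-mediator (min, max) used for
    normalization, so raw pg/ml values can be recovered.
    """

    clinical: pd.DataFrame
    series: pd.DataFrame
    normalized: bool = False
    norm_stats: pd.DataFrame | None = None
    rejected_rows: pd.DataFrame | None = field(default=None, compare=False)

    @property
    def patients(self) -> pd.DataFrame:
        return self.clinical

    def patient_ids(self) -> list[str]:
        return self.clinical["patient_id"].tolist()

    def group_of(self, patient_id: str) -> str:
        row = self.clinical.loc[self.clinical["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(f"unknown patient {patient_id!r}")
        return row["group"].iloc[0]

    def n_patients(self) -> int:
        return len(self.clinical)


def _validate_clinical(clin: pd.DataFrame) -> pd.DataFrame:
    missing = set(CLINICAL_COLUMNS) - set(clin.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    clin = clin.copy()
    clin["patient_id"] = clin["patient_id"].astype(str)
    for col in ("gcs", "gos6", "gos12"):
        clin[col] = clin[col].astype(int)
    bad_gcs = ~clin["gcs"].between(3, 15)
    if bad_gcs.any():
        raise ValueError(
            f"GCS outside 3..15 for patients {clin.loc[bad_gcs, 'patient_id'].tolist()}"
        )
    for col in ("gos6", "gos12"):
        bad = ~clin[col].between(1, 5)
        if bad.any():
            raise ValueError(
                f"{col} outside 1..5 for patients {clin.loc[bad, 'patient_id'].tolist()}"
            )
    derived = clin["gos12"].map(_derive_group)
    if "group" in clin.columns:
        mismatch = clin["group"] != derived
        if mismatch.any():
            raise ValueError(
                "supplied group label contradicts GOS12 for patients "
                f"{clin.loc[mismatch, 'patient_id'].tolist()}"
            )
    clin["group"] = derived
    if clin["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in clinical table")
    return clin


def _validate_series(
    med: pd.DataFrame, known_patients: set[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    missing = set(MEDIATOR_COLUMNS) - set(med.columns)
    if missing:
        raise ValueError(f"mediator table missing columns: {sorted(missing)}")
    med = med.copy()
    med["patient_id"] = med["patient_id"].astype(str)

    unknown_patient = ~med["patient_id"].isin(known_patients)
    if unknown_patient.any():
        raise ValueError(
            "mediator rows reference unknown patients: "
            f"{sorted(med.loc[unknown_patient, 'patient_id'].unique())}"
        )

    reasons = pd.Series("", index=med.index, dtype=object)
    canon = med["mediator"].map(lambda m: canonical_mediator(m))
    reasons[canon.isna()] = "unknown mediator"
    time = pd.to_numeric(med["time_h"], errors="coerce")
    conc = pd.to_numeric(med["conc_pg_ml"], errors="coerce")
    bad_time = time.isna() | (time < 0) | (time > 120)
    bad_conc = conc.isna() | (conc < 0)
    reasons[(reasons == "") & bad_time] = "malformed time"
    reasons[(reasons == "") & bad_conc] = "malformed concentration"

    rejected = med.loc[reasons != ""].assign(reason=reasons[reasons != ""])
    if len(rejected):
        warnings.warn(
            f"dropped {len(rejected)} mediator rows "
            f"({rejected['reason'].value_counts().to_dict()})",
            stacklevel=3,
        )
    ok = reasons == ""
    clean = med.loc[ok].copy()
    clean["mediator"] = canon[ok]
    clean["time_h"] = time[ok]
    clean["conc_pg_ml"] = conc[ok]
    clean = clean[list(MEDIATOR_COLUMNS)].sort_values(
        ["patient_id", "mediator", "time_h"], kind="stable"
    )
    clean = clean.reset_index(drop=True)
    return clean, rejected.reset_index(drop=True)


def read_cohort(clinical_path: str | Path, mediator_path: str | Path) -> MediatorCohort:
    """Read and validate a cohort from its two delimited-text files.

    Rows with mediator names outside the 13-analyte panel, or with
    malformed times/concentrations, are reported (warning + the
    ``rejected_rows`` attribute) and dropped.  A mediator row that
    references a patient absent from the clinical table is a hard error.
    """
    clin = _validate_clinical(pd.read_csv(clinical_path))
    med, rejected = _validate_series(
        pd.read_csv(mediator_path), set(clin["patient_id"])
    )
    return MediatorCohort(
        clinical=clin, series=med, normalized=False, rejected_rows=rejected
    )


def write_cohort(
    cohort: MediatorCohort, clinical_path: str | Path, mediator_path: str | Path
) -> None:
    """Write a cohort back to the two-file delimited dialect."""
    cohort.clinical[list(CLINICAL_COLUMNS)].to_csv(clinical_path, index=False)
    cohort.series[list(MEDIATOR_COLUMNS)].to_csv(mediator_path, index=False)


def normalize_cohort(cohort: MediatorCohort) -> MediatorCohort:
    """Min-max rescale each mediator to [0, 10] across the whole cohort.

    Both outcome groups share one scale per mediator so that group mean
    curves remain comparable and live on the same 0-10 range as the
    model's damage variable.  A mediator that is constant across the
    cohort carries no scale information and is mapped to 0 with a
    warning.  Normalizing an already-normalized cohort is an error.
    """
    if cohort.normalized:
        raise ValueError("cohort is already normalized")
    series = cohort.series.copy()
    stats = (
        series.groupby("mediator")["conc_pg_ml"].agg(["min", "max"]).rename(
            columns={"min": "raw_min", "max": "raw_max"}
        )
    )
    constant = stats["raw_max"] - stats["raw_min"] <= 0
    if constant.any():
        warnings.warn(
            f"constant mediators mapped to 0: {stats.index[constant].tolist()}",
            stacklevel=2,
        )
    lo = series["mediator"].map(stats["raw_min"])
    span = series["mediator"].map(stats["raw_max"] - stats["raw_min"])
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = 10.0 * (series["conc_pg_ml"] - lo) / span
    norm[span.values == 0] = 0.0
    series["conc_pg_ml"] = norm
    return MediatorCohort(
        clinical=cohort.clinical,
        series=series,
        normalized=True,
        norm_stats=stats,
        rejected_rows=cohort.rejected_rows,
    )


def denormalize_cohort(cohort: MediatorCohort) -> MediatorCohort:
    """Invert :func:`normalize_cohort` using the stored per-mediator stats."""
    if not cohort.normalized or cohort.norm_stats is None:
        raise ValueError("cohort is not normalized (or lacks stored stats)")
    series = cohort.series.copy()
    stats = cohort.norm_stats
    lo = series["mediator"].map(stats["raw_min"])
    span = series["mediator"].map(stats["raw_max"] - stats["raw_min"])
    series["conc_pg_ml"] = lo + span * series["conc_pg_ml"] / 10.0
    return MediatorCohort(
        clinical=cohort.clinical, series=series, normalized=False,
        rejected_rows=cohort.rejected_rows,
    )


def group_mean_curves(
    cohort: MediatorCohort, times: tuple[float, ...] = FIT_TIMES_H
) -> pd.DataFrame:
    """Per-group, per-mediator mean values at the fit time points.

    Each patient contributes, per target time, the sample nearest in
    time within +-12 h (ties broken toward the earlier sample); patients
    with no sample in the window are missing for that cell and excluded
    from the mean.  Returns a DataFrame indexed by (group, mediator)
    with one column per target time; cells with no contributing patient
    are NaN.
    """
    if not cohort.normalized:
        raise ValueError("cohort must be normalized before computing mean curves")
    groups = cohort.clinical["group"].unique().tolist()
    for g in ("survivor", "non-survivor"):
        if g not in groups:
            raise ValueError(f"empty group: {g!r}")
    group_of = dict(zip(cohort.clinical["patient_id"], cohort.clinical["group"]))

    rows = {}
    for (pid, mediator), sub in cohort.series.groupby(
        ["patient_id", "mediator"], sort=True
    ):
        t = sub["time_h"].to_numpy()
        v = sub["conc_pg_ml"].to_numpy()
        vals = []
        for target in times:
            dist = np.abs(t - target)
            j = int(np.argmin(dist))  # argmin returns first index on ties
            vals.append(v[j] if dist[j] <= MATCH_WINDOW_H else np.nan)
        rows[(group_of[pid], mediator, pid)] = vals

    per_patient = pd.DataFrame.from_dict(rows, orient="index", columns=list(times))
    per_patient.index = pd.MultiIndex.from_tuples(
        per_patient.index, names=["group", "mediator", "patient_id"]
    )
    means = per_patient.groupby(level=["group", "mediator"], sort=True).mean()
    return means


def peak_times(cohort: MediatorCohort, mediator: str) -> pd.Series:
    """Per patient, the sample time attaining the maximum concentration.

    Ties are resolved toward the earliest sample.  Patients with no
    samples for the mediator are skipped with a warning.
    """
    canon = canonical_mediator(mediator)
    if canon is None:
        raise ValueError(f"unknown mediator {mediator!r}")
    sub = cohort.series[cohort.series["mediator"] == canon]
    out = {}
    for pid in cohort.patient_ids():
        s = sub[sub["patient_id"] == pid]
        if s.empty:
            warnings.warn(f"no {canon} samples for patient {pid}", stacklevel=2)
            continue
        v = s["conc_pg_ml"].to_numpy()
        t = s["time_h"].to_numpy()
        order = np.lexsort((t,))  # stable; series already time-sorted per read
        v, t = v[order], t[order]
        out[pid] = float(t[int(np.argmax(v))])
    return pd.Series(out, name=f"peak_time_{canon}")
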