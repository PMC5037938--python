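"""Mechanistic synthetic-cohort generator.

The original 34-patient CSF Luminex dataset is not publicly deposited,
so every stage of the pipeline is exercised on synthetic cohorts built
from the mechanistic model itself.  Each virtual patient gets a GCS
draw, a patient-specific log-normal perturbation of the group parameter
set, a simulated six-state trajectory, and irregular sampling with
multiplicative measurement noise.  Group differences are planted
mechanistically: the non-survivor parameter set shifts d0 and init_M up
and d1 and i0 down relative to survivors, the reciprocals of the
headline survivor:non-survivor fold changes, so downstream
direction-recovery checks have known ground truth.

Three model outputs feed the cytokines measured in CSF (TNF -> TNF-a,
IL6 -> IL-6, IL10 -> IL-10), the chemokine pool feeds scaled copies of
IL-8 / MIP-1a / MIP-1b, and the seven remaining panel analytes --
which the six-state model does not describe -- are generated as
damage-scaled baselines with noise.  Concentrations are de-normalized
to plausible pg/ml ranges in which IL-6 and IL-8 are the high-abundance
analytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import (
    CLINICAL_COLUMNS,
    MEDIATOR_PANEL,
    FIT_TIMES_H,
    MediatorCohort,
    write_cohort,
)
from .core_model import ModelParameters, SolverFailure, gcs_to_damage, simulate

__all__ = [
    "SURVIVOR_BASE_PARAMS",
    "NONSURVIVOR_MULTIPLIERS",
    "CohortSpec",
    "sample_patient",
    "generate_cohort",
    "plant_dybn_cohort",
]

#: Survivor-group base parameter set.  Calibrated once so that the
#: simulated survivor course shows the qualitative timing seen in CSF:
#: TNF-a and IL-10 peak before 20 h, IL-6 near 30 h, and damage decays
#: toward 0 by 120 h from a GCS-6 initial value.
SURVIVOR_BASE_PARAMS = ModelParameters(
    d0=0.01, d1=0.1,
    m0=0.6, m1=0.5, m2=0.15, m3=0.5, m4=0.1, m5=0.5,
    m6=0.15, m7=0.5, m8=0.5, m9=0.25,
    c0=0.3, c1=0.5, c2=0.15,
    i0=0.2, i1=0.35,
    t0=0.3, t1=0.5, t2=0.45,
    b0=0.002, b1=0.25, b2=0.02,
    init_M=0.1, init_C=0.1,
)

#: Non-survivor parameter multipliers: reciprocals of the headline
#: survivor:non-survivor fold changes (d1 3.538564, i0 2.701914,
#: init_M 0.263824, d0 0.17567), so non-survivors produce more damage
#: per activated cell, start with more activated cells, clear damage
#: more slowly and mount a weaker IL-10 response.
NONSURVIVOR_MULTIPLIERS: dict[str, float] = {
    "d0": 1.0 / 0.17567,
    "init_M": 1.0 / 0.263824,
    "d1": 1.0 / 3.538564,
    "i0": 1.0 / 2.701914,
}

#: Model output (or derived signal) feeding each measured mediator.
#: ("state", name, gain) uses a simulated state; ("damage", base, gain)
#: is a damage-scaled baseline for analytes outside the model.
MEDIATOR_MAP: dict[str, tuple] = {
    "TNF-a": ("state", "TNF", 1.0),
    "IL-6": ("state", "IL6", 1.0),
    "IL-10": ("state", "IL10", 1.0),
    "IL-8": ("state", "C", 1.0),
    "MIP-1a": ("state", "C", 0.8),
    "MIP-1b": ("state", "C", 0.6),
    "IL-1a": ("damage", 0.4, 0.10),
    "IL-1b": ("damage", 0.5, 0.08),
    "IL-2": ("damage", 0.3, 0.05),
    "IL-4": ("damage", 0.4, 0.06),
    "IL-5": ("damage", 0.3, 0.04),
    "IL-13": ("damage", 0.4, 0.05),
    "VEGF": ("damage", 0.6, 0.12),
}

#: pg/ml per model unit; IL-6 and IL-8 are the high-abundance analytes.
PGML_SCALE: dict[str, float] = {
    "IL-1a": 20.0, "IL-1b": 25.0, "IL-2": 8.0, "IL-4": 10.0, "IL-5": 6.0,
    "IL-6": 900.0, "IL-8": 1600.0, "IL-10": 30.0, "IL-13": 9.0,
    "MIP-1a": 45.0, "MIP-1b": 70.0, "TNF-a": 14.0, "VEGF": 60.0,
}

#: Admission GCS distribution over 3..8 (severe TBI), mean ~ 6.
GCS_VALUES = np.arange(3, 9)
GCS_PROBS = np.array([0.05, 0.10, 0.20, 0.35, 0.20, 0.10])


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort draw."""

    n_survivors: int = 29
    n_nonsurvivors: int = 5
    base_params: ModelParameters = SURVIVOR_BASE_PARAMS
    nonsurvivor_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(NONSURVIVOR_MULTIPLIERS)
    )
    noise_sigma: float = 0.3      # multiplicative log-normal measurement noise
    patient_sigma: float = 0.2    # per-patient log-normal parameter spread
    min_samples: int = 8
    max_samples: int = 15
    time_jitter_h: float = 4.0    # jitter around the six nominal draw times
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_survivors < 1 or self.n_nonsurvivors < 1:
            raise ValueError("each group needs at least one patient")
        if self.noise_sigma < 0 or self.patient_sigma < 0:
            raise ValueError("noise levels must be non-negative")
        if any(v <= 0 for v in self.nonsurvivor_multipliers.values()):
            raise ValueError("parameter multipliers must be positive")

    def group_params(self, group: str) -> ModelParameters:
        if group == "survivor":
            return self.base_params
        if group == "non-survivor":
            updates = {
                name: getattr(self.base_params, name) * mult
                for name, mult in self.nonsurvivor_multipliers.items()
            }
            return self.base_params.replace(**updates)
        raise ValueError(f"unknown group {group!r}")


def _sample_times(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Irregular draw schedule: jittered nominal times plus extras.

    Always includes t=0 (the enrollment sample anchors the cytokine
    initial conditions downstream).
    """
    times = [0.0]
    for t in FIT_TIMES_H[1:]:
        times.append(
            float(np.clip(t + rng.uniform(-spec.time_jitter_h, spec.time_jitter_h),
                          0.5, 120.0))
        )
    n_total = int(rng.integers(spec.min_samples, spec.max_samples + 1))
    n_extra = max(n_total - len(times), 0)
    times.extend(rng.uniform(0.5, 120.0, size=n_extra).tolist())
    return np.unique(np.round(times, 2))


def _perturb_params(
    params: ModelParameters, sigma: float, rng: np.random.Generator
) -> ModelParameters:
    if sigma == 0:
        return params
    factors = np.exp(rng.normal(0.0, sigma, size=len(params.to_array())))
    return ModelParameters.from_array(params.to_array() * factors)


def sample_patient(
    spec: CohortSpec,
    group: str,
    patient_id: str,
    rng: np.random.Generator,
    max_retries: int = 5,
) -> tuple[dict, pd.DataFrame]:
    """Draw one virtual patient: clinical record + 13 mediator series.

    Simulates the patient-specific model from the GCS-mapped initial
    damage, maps model outputs onto the mediator panel, samples at an
    irregular schedule and applies multiplicative log-normal noise.
    Parameter draws that break the integrator are resampled (bounded
    retries).
    """
    gcs = int(rng.choice(GCS_VALUES, p=GCS_PROBS))
    if group == "non-survivor":
        gos12 = 1
        gos6 = 1
        age = float(np.clip(rng.normal(41.0, 10.0), 18, 85))
    else:
        gos12 = int(rng.integers(2, 6))
        gos6 = int(np.clip(gos12 - rng.integers(0, 2), 2, 5))
        age = float(np.clip(rng.normal(31.6, 10.0), 18, 85))
    sex = "M" if rng.random() < 27 / 34 else "F"

    grid = np.arange(0.0, 120.0 + 0.25, 0.25)
    traj = None
    for _ in range(max_retries):
        params = _perturb_params(spec.group_params(group), spec.patient_sigma, rng)
        try:
            traj = simulate(params, gcs_to_damage(gcs), grid, rtol=1e-7, atol=1e-9)
            break
        except SolverFailure:
            continue
    if traj is None:
        raise SolverFailure(
            f"could not simulate patient {patient_id} after {max_retries} draws"
        )

    times = _sample_times(spec, rng)
    damage = np.interp(times, grid, traj.column("D"))
    rows = []
    for mediator in MEDIATOR_PANEL:
        kind, a, b = MEDIATOR_MAP[mediator]
        if kind == "state":
            signal = b * np.interp(times, grid, traj.column(a))
        else:  # damage-scaled baseline around a constant level
            signal = a + b * damage
        conc = signal * PGML_SCALE[mediator]
        if spec.noise_sigma > 0:
            conc = conc * np.exp(rng.normal(0.0, spec.noise_sigma, size=conc.size))
        for t, c in zip(times, conc):
            rows.append(
                {
                    "patient_id": patient_id,
                    "mediator": mediator,
                    "time_h": float(t),
                    "conc_pg_ml": float(c),
                }
            )
    clinical = {
        "patient_id": patient_id,
        "age": round(age, 1),
        "sex": sex,
        "gcs": gcs,
        "gos6": gos6,
        "gos12": gos12,
        "group": group,
    }
    return clinical, pd.DataFrame(rows)


def generate_cohort(
    spec: CohortSpec,
    clinical_path: str | Path | None = None,
    mediator_path: str | Path | None = None,
) -> MediatorCohort:
    """Generate a full cohort; optionally write the two-file dialect.

    Non-survivors get GOS12 = 1 and survivors GOS12 in 2-5, so outcome
    groups derive exactly as in real cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    clin_rows, series_frames = [], []
    for i in range(spec.n_survivors):
        c, s = sample_patient(spec, "survivor", f"S{i + 1:02d}", rng)
        clin_rows.append(c)
        series_frames.append(s)
    for i in range(spec.n_nonsurvivors):
        c, s = sample_patient(spec, "non-survivor", f"N{i + 1:02d}", rng)
        clin_rows.append(c)
        series_frames.append(s)
    clinical = pd.DataFrame(clin_rows, columns=list(CLINICAL_COLUMNS) + ["group"])
    series = pd.concat(series_frames, ignore_index=True).sort_values(
        ["patient_id", "mediator", "time_h"], kind="stable"
    ).reset_index(drop=True)
    cohort = MediatorCohort(clinical=clinical, series=series, normalized=False)
    if clinical_path is not None and mediator_path is not None:
        write_cohort(cohort, clinical_path, mediator_path)
    return cohort


def plant_dybn_cohort(
    edges: list[tuple[str, str]],
    n_patients: int,
    seed: int = 0,
    noise_sd: float = 0.75,
) -> MediatorCohort:
    """Slice-structured cohort with a planted first-order dependence.

    Each (parent, child) edge means child at slice t+1 is a noisy
    average of its parents at slice t; all other mediators are drawn
    independently each slice.  Values live on the normalized 0-10
    scale, sampled once per 24-h slice at the slice midpoint, so the
    returned cohort plugs straight into the DyBN stage.
    """
    for p, c in edges:
        if p not in MEDIATOR_PANEL or c not in MEDIATOR_PANEL:
            raise ValueError(f"edge ({p!r}, {c!r}) references non-panel mediators")
    parents_of: dict[str, list[str]] = {}
    for p, c in edges:
        parents_of.setdefault(c, []).append(p)

    from .dybn import N_SLICES, SLICE_WIDTH_H

    rng = np.random.default_rng(seed)
    rows, clin_rows = [], []
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        values = {m: rng.uniform(0.0, 10.0) for m in MEDIATOR_PANEL}
        for t in range(N_SLICES):
            if t > 0:
                new = {}
                for m in MEDIATOR_PANEL:
                    if m in parents_of:
                        mean_parent = float(
                            np.mean([values[p] for p in parents_of[m]])
                        )
                        new[m] = float(
                            np.clip(mean_parent + rng.normal(0.0, noise_sd), 0, 10)
                        )
                    else:
                        new[m] = rng.uniform(0.0, 10.0)
                values = new
            midpoint = (t + 0.5) * SLICE_WIDTH_H
            for m in MEDIATOR_PANEL:
                rows.append(
                    {
                        "patient_id": pid,
                        "mediator": m,
                        "time_h": midpoint,
                        "conc_pg_ml": values[m],
                    }
                )
        # outcome labels are irrelevant to the planted structure; keep
        # both groups represented so the cohort is valid everywhere
        gos12 = 1 if i == 0 else int(rng.integers(2, 6))
        clin_rows.append(
            {
                "patient_id": pid,
                "age": 35.0,
                "sex": "M",
                "gcs": 6,
                "gos6": gos12,
                "gos12": gos12,
                "group": "non-survivor" if gos12 == 1 else "survivor",
            }
        )
    clinical = pd.DataFrame(clin_rows)
    series = pd.DataFrame(rows)
    return MediatorCohort(clinical=clinical, series=series, normalized=True)
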