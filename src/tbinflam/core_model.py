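"""Six-state ODE model of post-TBI cerebrospinal-fluid inflammation.

The model lumps the acute inflammatory response to traumatic brain injury
into six coupled states on a dimensionless 0-10 scale:

* ``D``    -- tissue damage / dysfunction / DAMPs, seeded by the injury
              (mapped from the admission Glasgow Coma Scale score),
* ``M``    -- activated inflammatory cells (microglia and recruited
              leukocytes), the hub that drives every cytokine,
* ``C``    -- a lumped chemokine pool (IL-8 / MIP-1 family),
* ``IL10`` -- the prototypical anti-inflammatory cytokine,
* ``TNF``  -- the prototypical early pro-inflammatory cytokine,
* ``IL6``  -- the positive-feedback cytokine, produced with sixth-order
              cooperativity in ``M`` to mimic the self-amplifying IL-6
              response inferred from the network analyses.

Activation of ``M`` by damage, chemokine, TNF and IL-6 saturates
(Michaelis-Menten-like ``x/(1+kx)`` terms) and is globally suppressed by
IL-10 through a ``1/(1+m8*IL10)`` factor.  Every state also decays
linearly, so the origin is an equilibrium and the non-negative orthant is
forward-invariant.

The model has 23 rate/saturation constants plus two estimated initial
conditions (``init_M``, ``init_C``), 25 free parameters in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "ModelParameters",
    "ModelState",
    "Trajectory",
    "SolverFailure",
    "rhs",
    "simulate",
    "gcs_to_damage",
    "terminal_damage",
]

#: Canonical parameter order used for arrays, files and ensemble tables.
PARAM_NAMES: tuple[str, ...] = (
    "d0", "d1",
    "m0", "m1", "m2", "m3", "m4", "m5", "m6", "m7", "m8", "m9",
    "c0", "c1", "c2",
    "i0", "i1",
    "t0", "t1", "t2",
    "b0", "b1", "b2",
    "init_M", "init_C",
)

STATE_NAMES: tuple[str, ...] = ("D", "M", "C", "IL10", "TNF", "IL6")

#: Observation window in hours post-injury.
T_MAX_HOURS = 120.0


class SolverFailure(RuntimeError):
    """Raised when numerical integration of the model fails.

    Carries the offending parameter set so ensemble drivers can report
    (and resample) the failing fit.
    """

    def __init__(self, message: str, params: "ModelParameters | None" = None):
        super().__init__(message)
        self.params = params


def _check_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class ModelParameters:
    """The 23 rate constants plus the two estimated initial conditions.

    All values are non-negative and finite; rates are per hour on the
    normalized 0-10 concentration scale.
    """

    d0: float  # damage/DAMP production by activated cells
    d1: float  # damage/DAMP decay
    m0: float  # cell activation by damage
    m1: float  # saturation of activation by damage
    m2: float  # cell activation by chemokine
    m3: float  # saturation of activation by chemokine
    m4: float  # cell activation by TNF
    m5: float  # saturation of activation by TNF
    m6: float  # cell activation by IL-6
    m7: float  # saturation of activation by IL-6
    m8: float  # IL-10 suppression of cell activation
    m9: float  # inflammatory-cell death rate
    c0: float  # chemokine production by damage
    c1: float  # saturation of chemokine production
    c2: float  # chemokine decay
    i0: float  # IL-10 production by activated cells
    i1: float  # IL-10 decay
    t0: float  # TNF production by activated cells
    t1: float  # IL-10 suppression of TNF
    t2: float  # TNF decay
    b0: float  # IL-6 production (sixth order in M)
    b1: float  # IL-10 suppression of IL-6
    b2: float  # IL-6 decay
    init_M: float  # initial activated-cell level (estimated)
    init_C: float  # initial chemokine level (estimated)

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_finite_nonneg(f.name, getattr(self, f.name))

    def to_array(self) -> np.ndarray:
        """Values in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ModelParameters":
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(
                f"expected {len(PARAM_NAMES)} parameter values, got shape {arr.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, arr.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def replace(self, **updates: float) -> "ModelParameters":
        d = self.to_dict()
        d.update(updates)
        return ModelParameters(**d)

    # -- flat key-value text interchange ---------------------------------
    def to_file(self, path: str | Path) -> None:
        """Write one ``name value`` pair per line."""
        lines = [f"{n} {getattr(self, n):.17g}" for n in PARAM_NAMES]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        values: dict[str, float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                name, raw = line.split()
            except ValueError as exc:
                raise ValueError(f"line {lineno}: expected 'name value'") from exc
            if name not in PARAM_NAMES:
                raise ValueError(f"line {lineno}: unknown parameter {name!r}")
            values[name] = float(raw)
        missing = set(PARAM_NAMES) - set(values)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        return cls(**values)


@dataclass(frozen=True)
class ModelState:
    """One point of the model's six-dimensional state."""

    D: float
    M: float
    C: float
    IL10: float
    TNF: float
    IL6: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_finite_nonneg(f.name, getattr(self, f.name))
        if self.D > 10.0:
            raise ValueError(
                f"initial damage D must be on the 0-10 scale, got {self.D}"
            )

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.D, self.M, self.C, self.IL10, self.TNF, self.IL6], dtype=float
        )


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course: ``times`` (hours) and a (n, 6) state array."""

    times: np.ndarray
    states: np.ndarray  # columns in STATE_NAMES order

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "states", np.asarray(self.states, dtype=float))
        if self.times.ndim != 1 or self.states.shape != (self.times.size, 6):
            raise ValueError("times and states have mismatched shapes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _rhs_odeint_py(y, t, p):
    """Integrator callback (odeint signature); pure-Python fallback."""
    D, M, C, IL10, TNF, IL6 = y
    act = (
        p[2] * D / (1.0 + p[3] * D)
        + p[4] * C / (1.0 + p[5] * C)
        + p[6] * TNF / (1.0 + p[7] * TNF)
        + p[8] * IL6 / (1.0 + p[9] * IL6)
    )
    out = np.empty(6)
    out[0] = p[0] * M - p[1] * D
    out[1] = act / (1.0 + p[10] * IL10) - p[11] * M
    out[2] = p[12] * D / (1.0 + p[13] * D) - p[14] * C
    out[3] = p[15] * M - p[16] * IL10
    out[4] = p[17] * M / (1.0 + p[18] * IL10) - p[19] * TNF
    out[5] = p[20] * M**6 / (1.0 + p[21] * IL10) - p[22] * IL6
    return out


try:  # compiled callback cuts the fit loop's solve time ~5x
    from numba import njit as _njit

    _rhs_odeint = _njit(cache=False)(_rhs_odeint_py)
except ImportError:  # pragma: no cover - numba is a hard dependency
    _rhs_odeint = _rhs_odeint_py


def _rhs_arrays(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vector field on raw arrays; hot path for the integrator."""
    D, M, C, IL10, TNF, IL6 = y
    (d0, d1, m0, m1, m2, m3, m4, m5, m6, m7, m8, m9,
     c0, c1, c2, i0, i1, t0, t1, t2, b0, b1, b2, _im, _ic) = p
    activation = (
        m0 * D / (1.0 + m1 * D)
        + m2 * C / (1.0 + m3 * C)
        + m4 * TNF / (1.0 + m5 * TNF)
        + m6 * IL6 / (1.0 + m7 * IL6)
    )
    dD = d0 * M - d1 * D
    dM = activation / (1.0 + m8 * IL10) - m9 * M
    dC = c0 * D / (1.0 + c1 * D) - c2 * C
    dIL10 = i0 * M - i1 * IL10
    dTNF = t0 * M / (1.0 + t1 * IL10) - t2 * TNF
    dIL6 = b0 * M**6 / (1.0 + b1 * IL10) - b2 * IL6
    return np.array([dD, dM, dC, dIL10, dTNF, dIL6])


def rhs(state: ModelState | Sequence[float], params: ModelParameters) -> np.ndarray:
    """Evaluate the six-component vector field at one state.

    Returns ``(dD, dM, dC, dIL10, dTNF, dIL6)``.
    """
    if isinstance(state, ModelState):
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
        if y.shape != (6,):
            raise ValueError(f"state must have 6 components, got shape {y.shape}")
        if not np.all(np.isfinite(y)):
            raise ValueError("state components must be finite")
        if np.any(y < 0):
            raise ValueError("state components must be non-negative")
    out = _rhs_arrays(y, params.to_array())
    if not np.all(np.isfinite(out)):
        raise SolverFailure("non-finite derivative", params)
    return out


def gcs_to_damage(gcs: int) -> float:
    """Map an admission Glasgow Coma Scale score to initial damage.

    GCS 15 (normal) maps to damage 0 and GCS 3 (worst) to damage 10;
    the map is linear between the two anchors.
    """
    if int(gcs) != gcs or not 3 <= int(gcs) <= 15:
        raise ValueError(f"GCS must be an integer in 3..15, got {gcs!r}")
    return 10.0 * (15 - int(gcs)) / 12.0


def terminal_damage(group: str) -> float:
    """Damage anchor at the end of the observation window.

    Survival anchors damage at the minimal value 0; death at the maximal
    value 10.
    """
    if group == "survivor":
        return 0.0
    if group == "non-survivor":
        return 10.0
    raise ValueError(f"unknown group label {group!r}")


# Negative excursions within solver round-off (a fixed multiple of the
# absolute tolerance) are clipped; anything larger aborts the simulation.
_NEG_TOL_FACTOR = 1e4


def simulate(
    params: ModelParameters,
    d0_initial: float,
    t_grid: Iterable[float],
    init_cytokines: Sequence[float] = (0.0, 0.0, 0.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model from an assembled initial state.

    The initial state is ``D = d0_initial`` (from the GCS map),
    ``M = params.init_M``, ``C = params.init_C`` and the three cytokines
    from ``init_cytokines = (IL10, TNF, IL6)``, normally the group-mean
    data values at t = 0.

    Uses the adaptive stiff-capable LSODA integrator; the sixth-power
    IL-6 production term can make the system stiff at large ``M``.
    """
    t = np.asarray(list(t_grid), dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be increasing with at least two points")
    if t[0] < 0 or t[-1] > T_MAX_HOURS:
        raise ValueError(f"t_grid must lie within [0, {T_MAX_HOURS}] h")
    il10_0, tnf_0, il6_0 = (float(v) for v in init_cytokines)
    y0 = ModelState(
        D=float(d0_initial), M=params.init_M, C=params.init_C,
        IL10=il10_0, TNF=tnf_0, IL6=il6_0,
    ).to_array()
    p = params.to_array()

    with np.errstate(over="ignore", invalid="ignore"):
        states, info = odeint(
            _rhs_odeint,
            y0,
            t,
            args=(p,),
            rtol=rtol,
            atol=atol,
            full_output=True,
            mxstep=10000,
        )
    if info["message"] != "Integration successful." or not np.all(
        np.isfinite(states)
    ):
        raise SolverFailure(
            f"integration failed: {info['message']} (params={params.to_dict()})",
            params,
        )
    states = np.asarray(states, dtype=float)
    min_val = states.min()
    if min_val < -_NEG_TOL_FACTOR * atol:
        raise SolverFailure(
            f"trajectory left the non-negative orthant (min {min_val:.3e}); "
            f"params={params.to_dict()}",
            params,
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times=t, states=states)
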