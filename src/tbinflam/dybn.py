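"""Dynamic Bayesian network inference over 24-hour mediator time slices.

The mediator panel is binned into five adjacent 24-h slices (0-24,
24-48, ..., 96-120 h post-injury), discretized into quantile levels, and
modeled as a first-order discrete Markov chain: each mediator at slice
t+1 may depend on any mediator at slice t (including itself -- a
self-edge is temporal self-feedback).  The transition structure is
stationary: one edge set shared by all four consecutive slice pairs,
learned from the pooled transitions by greedy hill-climbing on the
BDeu score, with conditional probability tables estimated by maximum
likelihood with add-one smoothing.

"Central nodes" follow the switch-motif definition used in dynamic
network studies of inflammation: mediators with a self-edge that also
exchange at least one edge with another self-edged mediator, ranked by
total degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort_io import MEDIATOR_PANEL, MediatorCohort

__all__ = [
    "N_SLICES",
    "SLICE_WIDTH_H",
    "SlicedPanel",
    "DybnStructure",
    "bin_slices",
    "discretize",
    "learn_structure",
    "central_nodes",
    "write_edge_list",
    "to_networkx",
]

N_SLICES = 5
SLICE_WIDTH_H = 24.0

#: Parsimony cap on the number of parents per node.
MAX_PARENTS = 3


@dataclass(frozen=True)
class SlicedPanel:
    """Per patient x slice mean normalized mediator levels.

    ``values`` is indexed by (patient_id, slice) with one column per
    mediator; missing cells are NaN.  ``discrete`` marks whether values
    are quantile codes rather than 0-10 levels.
    """

    values: pd.DataFrame
    discrete: bool = False
    n_levels: int | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.nlevels != 2 or list(idx.names) != ["patient_id", "slice"]:
            raise ValueError("panel must be indexed by (patient_id, slice)")
        slices = idx.get_level_values("slice")
        if len(slices) and not set(slices) <= set(range(N_SLICES)):
            raise ValueError(f"slice index must lie in 0..{N_SLICES - 1}")

    @property
    def mediators(self) -> list[str]:
        return list(self.values.columns)

    def patient_ids(self) -> list[str]:
        return sorted(set(self.values.index.get_level_values("patient_id")))


@dataclass(frozen=True)
class DybnStructure:
    """A stationary first-order transition structure.

    ``edges`` are (parent, child) pairs meaning parent at slice t ->
    child at slice t+1, identical for every consecutive slice pair;
    there are no within-slice edges, so temporal legality and
    within-slice acyclicity hold by construction.  ``cpds`` maps each
    child to a smoothed conditional probability table.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    cpds: dict = field(default_factory=dict, compare=False)
    scores: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for p, c in self.edges:
            if p not in known or c not in known:
                raise ValueError(f"edge ({p!r}, {c!r}) references unknown node")

    def parents_of(self, child: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.edges if c == child)

    def has_self_edge(self, mediator: str) -> bool:
        return (mediator, mediator) in self.edges

    def degree(self, mediator: str) -> int:
        return sum(1 for p, c in self.edges if p == mediator or c == mediator)


def bin_slices(cohort: MediatorCohort) -> SlicedPanel:
    """Average each patient's mediator samples within 24-h slices.

    The value for slice k is the mean of all samples with time in
    [24k, 24(k+1)); a slice with no samples is missing.
    """
    if not cohort.normalized:
        raise ValueError("cohort must be normalized before slicing")
    series = cohort.series.copy()
    series["slice"] = np.minimum(
        (series["time_h"] // SLICE_WIDTH_H).astype(int), N_SLICES - 1
    )
    cell = (
        series.groupby(["patient_id", "slice", "mediator"])["conc_pg_ml"]
        .mean()
        .unstack("mediator")
    )
    # ensure every patient has all five slice rows (missing -> NaN rows)
    full_index = pd.MultiIndex.from_product(
        [cohort.clinical["patient_id"], range(N_SLICES)],
        names=["patient_id", "slice"],
    )
    cols = [m for m in MEDIATOR_PANEL if m in cell.columns] + [
        m for m in cell.columns if m not in MEDIATOR_PANEL
    ]
    cell = cell.reindex(full_index)[cols]
    return SlicedPanel(values=cell, discrete=False)


def discretize(panel: SlicedPanel, n_levels: int = 3) -> SlicedPanel:
    """Quantile-code each mediator over all patients and slices.

    With the default three levels this is tertile coding
    (low/mid/high).  Missing cells stay missing.  A mediator with fewer
    distinct values than levels collapses to fewer levels with a
    warning.
    """
    if panel.discrete:
        raise ValueError("panel is already discrete")
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    coded = {}
    for mediator in panel.values.columns:
        col = panel.values[mediator]
        filled = col.dropna()
        if filled.nunique() < n_levels:
            warnings.warn(
                f"{mediator}: only {filled.nunique()} distinct values; "
                f"collapsing below {n_levels} levels",
                stacklevel=2,
            )
        if filled.nunique() <= 1:  # constant column collapses to one level
            codes = col.where(col.isna(), 0.0)
        else:
            codes = pd.qcut(col, q=n_levels, labels=False, duplicates="drop")
        coded[mediator] = codes
    values = pd.DataFrame(coded, index=panel.values.index)
    return SlicedPanel(values=values, discrete=True, n_levels=n_levels)


def _transition_frame(panel: SlicedPanel) -> pd.DataFrame:
    """Stack the four (t, t+1) slice pairs into one pooled table.

    Columns ``<m>__prev`` hold slice-t values and ``<m>__next`` slice
    t+1 values.  Complete-case deletion over the full mediator panel at
    both ends keeps scores for competing parent sets comparable.
    """
    v = panel.values
    frames = []
    for t in range(N_SLICES - 1):
        prev = v.xs(t, level="slice")
        nxt = v.xs(t + 1, level="slice")
        common = prev.index.intersection(nxt.index)
        f = pd.concat(
            [
                prev.loc[common].add_suffix("__prev"),
                nxt.loc[common].add_suffix("__next"),
            ],
            axis=1,
        )
        frames.append(f)
    pooled = pd.concat(frames, axis=0, ignore_index=True)
    return pooled.dropna()


#: Equivalent sample size of the BDeu structure score's Dirichlet prior.
BDEU_ESS = 1.0


def _family_counts(
    child_next: np.ndarray, parent_prev: np.ndarray, n_levels: int
) -> np.ndarray:
    """Contingency counts of one family, shape (parent configs, levels).

    ``parent_prev`` has one column per parent; an empty parent set is a
    marginal multinomial (one config row).
    """
    n = child_next.shape[0]
    keys = np.zeros(n, dtype=np.int64)
    for j in range(parent_prev.shape[1]):
        keys = keys * n_levels + parent_prev[:, j].astype(np.int64)
    n_configs = n_levels ** parent_prev.shape[1]
    flat = keys * n_levels + child_next.astype(np.int64)
    return np.bincount(flat, minlength=n_configs * n_levels).reshape(
        n_configs, n_levels
    )


def _family_score(
    child_next: np.ndarray, parent_prev: np.ndarray, n_levels: int
) -> float:
    """BDeu marginal-likelihood score of one child-parent family.

    The Bayesian Dirichlet equivalent uniform score with a small
    equivalent sample size: the integrated likelihood of the family
    under a uniform Dirichlet prior split evenly over parent
    configurations.  Larger parent sets dilute the prior over more
    configurations, which is the score's built-in parsimony penalty.
    """
    counts = _family_counts(child_next, parent_prev, n_levels)
    q = counts.shape[0]
    a_j = BDEU_ESS / q
    a_jk = BDEU_ESS / (q * n_levels)
    n_j = counts.sum(axis=1)
    return float(
        (gammaln(a_j) - gammaln(a_j + n_j)).sum()
        + (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
    )


def _cpd_table(
    child_next: np.ndarray, parent_prev: np.ndarray, n_levels: int
) -> np.ndarray:
    """Add-one-smoothed conditional probability table, shape (configs, levels)."""
    counts = _family_counts(child_next, parent_prev, n_levels)
    smoothed = counts + 1.0
    return smoothed / smoothed.sum(axis=1, keepdims=True)


def learn_structure(panel: SlicedPanel, seed: int = 0) -> DybnStructure:
    """Greedy BDeu hill-climbing over first-order transition parents.

    For each mediator at slice t+1 the candidate parents are all
    mediators at slice t (itself included).  Starting from the empty
    parent set, single-parent additions and removals are applied while
    they improve the BIC score (log-likelihood minus a parsimony
    penalty), with at most three parents per node.  Candidate moves are
    scanned in panel order and deterministically tie-broken, so the
    result depends only on the data; the ``seed`` argument is part of
    the determinism contract and reserved for randomized restarts.
    """
    if not panel.discrete or panel.n_levels is None:
        raise ValueError("structure learning needs a discretized panel")
    mediators = panel.mediators
    trans = _transition_frame(panel)
    n = len(trans)
    n_patients = len(panel.patient_ids())
    total_cells = panel.values.size
    missing_frac = float(panel.values.isna().sum().sum()) / max(total_cells, 1)
    if n_patients < 5 or missing_frac > 0.30 or n < 10:
        raise ValueError(
            "insufficient data for structure learning "
            f"(patients={n_patients}, missing fraction={missing_frac:.2f}, "
            f"complete transitions={n}); mediators: {mediators}"
        )
    L = int(panel.n_levels)
    prev_mat = {m: trans[f"{m}__prev"].to_numpy() for m in mediators}

    edges: list[tuple[str, str]] = []
    cpds: dict[str, dict] = {}
    scores: dict[str, float] = {}
    for child in mediators:
        y = trans[f"{child}__next"].to_numpy()
        parents: list[str] = []

        def score_of(parent_set: list[str]) -> float:
            x = (
                np.column_stack([prev_mat[p] for p in parent_set])
                if parent_set
                else np.empty((len(y), 0))
            )
            return _family_score(y, x, L)

        current = score_of(parents)
        improved = True
        while improved:
            improved = False
            best_move, best_score = None, current + 1e-9
            if len(parents) < MAX_PARENTS:
                for cand in mediators:
                    if cand in parents:
                        continue
                    s = score_of(parents + [cand])
                    if s > best_score:
                        best_move, best_score = ("add", cand), s
            for cand in list(parents):
                s = score_of([p for p in parents if p != cand])
                if s > best_score:
                    best_move, best_score = ("remove", cand), s
            if best_move is not None:
                op, cand = best_move
                if op == "add":
                    parents.append(cand)
                else:
                    parents.remove(cand)
                parents.sort(key=mediators.index)
                current = best_score
                improved = True
        scores[child] = current
        edges.extend((p, child) for p in parents)
        x = (
            np.column_stack([prev_mat[p] for p in parents])
            if parents
            else np.empty((len(y), 0))
        )
        cpds[child] = {
            "parents": tuple(parents),
            "table": _cpd_table(y, x, L),
        }
    return DybnStructure(
        nodes=tuple(mediators), edges=tuple(edges), cpds=cpds, scores=scores
    )


def central_nodes(structure: DybnStructure) -> list[str]:
    """Switch-motif central nodes, ranked by total degree.

    A mediator is central when it has a self-edge and at least one edge
    to or from another self-edged mediator.
    """
    selfed = {m for m in structure.nodes if structure.has_self_edge(m)}
    central = []
    for m in selfed:
        others = {
            p if c == m else c
            for p, c in structure.edges
            if (p == m or c == m) and p != c
        }
        if others & selfed:
            central.append(m)
    return sorted(
        central, key=lambda m: (-structure.degree(m), structure.nodes.index(m))
    )


def write_edge_list(structure: DybnStructure, path) -> None:
    """Text export: ``parent_mediator,parent_slice_offset,child_mediator``.

    All learned edges are inter-slice, so the parent offset is -1
    (parent lives one slice before the child).
    """
    lines = ["parent_mediator,parent_slice_offset,child_mediator"]
    lines += [f"{p},-1,{c}" for p, c in structure.edges]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def to_networkx(structure: DybnStructure):
    """Unrolled five-slice directed graph for visualization/export."""
    import networkx as nx

    g = nx.DiGraph()
    for t in range(N_SLICES):
        for m in structure.nodes:
            g.add_node(f"{m}@t{t}", mediator=m, slice=t)
    for t in range(N_SLICES - 1):
        for p, c in structure.edges:
            g.add_edge(f"{p}@t{t}", f"{c}@t{t + 1}")
    return g
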