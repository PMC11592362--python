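"""PLS feature construction from the connectivity tensor.

Two feature sets are built per network pairing:

* group-by-condition — baseline-normalised connectivity (the baseline
  condition's estimate subtracted from the semantic and pragmatic
  estimates), one observation row per subject per task condition, four
  design cells (group x condition);
* idiosyncrasy — the absolute semantic-pragmatic difference per edge, a
  direction-agnostic measure of how much a subject's connectivity shifts
  between the two speech-act conditions, one row per subject, two cells
  (group).  Because the baseline estimate cancels inside the difference,
  raw and baseline-normalised inputs give identical idiosyncrasy values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import NetworkPairing, ParcellationMap
from .connectivity import ConnectivityTensor

GROUPS = ("ASD", "TD")
TASK_CONDITIONS = ("semantic", "pragmatic")

__all__ = [
    "GROUPS",
    "TASK_CONDITIONS",
    "FeatureMatrix",
    "baseline_normalize",
    "idiosyncrasy_features",
    "assemble_feature_matrix",
]


@dataclass
class FeatureMatrix:
    """Observations x features matrix for one pairing, with design metadata.

    ``cells`` is the ordered list of design cells; ``row_cells`` assigns each
    row to a cell index and ``row_subjects`` names the subject behind each
    row (a subject contributes one row per task condition of its group in
    the group-by-condition analysis, one row total in the idiosyncrasy
    analysis).
    """

    X: np.ndarray
    cells: list[str]
    row_cells: np.ndarray  # cell index per row
    row_subjects: list[str]
    feature_edges: np.ndarray  # edge ids (into the tensor's edge list) per column

    def __post_init__(self) -> None:
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")
        if len(self.row_cells) != self.X.shape[0] or len(self.row_subjects) != self.X.shape[0]:
            raise ValueError("row metadata length mismatch")
        counts = np.bincount(self.row_cells, minlength=len(self.cells))
        if (counts == 0).any():
            empty = [self.cells[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"empty design cell(s): {empty}")


def baseline_normalize(t: ConnectivityTensor) -> ConnectivityTensor:
    """Subtract each subject's baseline estimate from the task conditions.

    Returns a tensor over (semantic, pragmatic) only, with values in
    [-1, 1]: positive means stronger coupling during the task condition
    than at baseline.
    """
    if "baseline" not in t.conditions:
        raise ValueError("tensor has no baseline condition")
    base = t.condition_slice("baseline")
    out = np.stack([t.condition_slice(c) - base for c in TASK_CONDITIONS], axis=1)
    return ConnectivityTensor(
        out, list(t.subjects), list(t.groups), list(TASK_CONDITIONS), t.edge_index
    )


def idiosyncrasy_features(t: ConnectivityTensor) -> np.ndarray:
    """|semantic - pragmatic| per subject and edge (subjects x edges).

    Absolute values equalise positive and negative shifts, so the statistic
    captures the magnitude of condition-dependent deviation regardless of
    direction — the idiosyncrasy construct.
    """
    for c in TASK_CONDITIONS:
        if c not in t.conditions:
            raise ValueError(f"tensor has no {c!r} condition")
    return np.abs(t.condition_slice("semantic") - t.condition_slice("pragmatic"))


def _group_order(t: ConnectivityTensor) -> list[str]:
    ordered = [g for g in GROUPS if g in t.groups]
    extra = sorted(set(t.groups) - set(ordered))
    return ordered + extra


def assemble_feature_matrix(
    t: ConnectivityTensor,
    pairing: NetworkPairing,
    pmap: ParcellationMap,
    analysis: str,
) -> FeatureMatrix:
    """Restrict the tensor to one pairing's edges and lay out the PLS design.

    ``analysis`` is ``"group_by_condition"`` (baseline-normalised features,
    cells ordered ASD-semantic, ASD-pragmatic, TD-semantic, TD-pragmatic)
    or ``"idiosyncrasy"`` (|semantic-pragmatic| features, cells ASD, TD).
    Rows are ordered by cell, subjects in tensor order within a cell.
    """
    edge_ids = pmap.edge_positions(pairing)
    if len(edge_ids) == 0:
        raise ValueError(f"pairing {pairing.label}: empty edge set")
    groups = np.asarray(t.groups)
    group_order = _group_order(t)

    if analysis == "group_by_condition":
        norm = t if set(t.conditions) == set(TASK_CONDITIONS) else baseline_normalize(t)
        cells = [f"{g}-{c}" for g in group_order for c in TASK_CONDITIONS]
        rows, row_cells, row_subjects = [], [], []
        for ci, (g, c) in enumerate((g, c) for g in group_order for c in TASK_CONDITIONS):
            sl = norm.condition_slice(c)[:, edge_ids]
            for s in np.flatnonzero(groups == g):
                rows.append(sl[s])
                row_cells.append(ci)
                row_subjects.append(t.subjects[s])
    elif analysis == "idiosyncrasy":
        idio = idiosyncrasy_features(t)[:, edge_ids]
        cells = list(group_order)
        rows, row_cells, row_subjects = [], [], []
        for ci, g in enumerate(group_order):
            for s in np.flatnonzero(groups == g):
                rows.append(idio[s])
                row_cells.append(ci)
                row_subjects.append(t.subjects[s])
    else:
        raise ValueError(f"unknown analysis {analysis!r}")

    return FeatureMatrix(
        np.asarray(rows), cells, np.asarray(row_cells), row_subjects, edge_ids
    )
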