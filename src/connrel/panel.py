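"""Edge-level observation panels.

The unit of analysis throughout the package is an *edge observation panel*:
connectivity values for every (subject, condition, session, edge) cell of a
repeated-measures design, together with a missingness mask.  Values may be
raw Pearson correlations (``units="r"``) or Fisher-z transformed
(``units="fisher_z"``); model fitting defaults to the z scale because its
unbounded support matches the Gaussian random-effects assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["EdgeObservationPanel", "inject_missing"]

_VALID_UNITS = ("r", "fisher_z")


@dataclass
class EdgeObservationPanel:
    """Connectivity values indexed (subject, condition, session, edge).

    Parameters
    ----------
    values : ndarray, shape (K, J, I, V)
        Edge-level connectivity values for K subjects, J conditions,
        I sessions and V edges.
    missing_mask : ndarray of bool, same shape
        True marks a missing observation.  Values under the mask are
        retained but ignored by every estimator.
    subject_ids, condition_labels, session_indices, edge_labels
        Index metadata; lengths must match the corresponding axes.
    units : {"r", "fisher_z"}
        Scale of ``values``.
    """

    values: np.ndarray
    missing_mask: np.ndarray = None
    subject_ids: list = None
    condition_labels: list = None
    session_indices: list = None
    edge_labels: list = None
    units: str = "fisher_z"
    edge_blocks: list = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(
                f"values must be 4-dimensional (subject, condition, session, "
                f"edge); got shape {self.values.shape}"
            )
        K, J, I, V = self.values.shape
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape must match values shape")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{k + 1:02d}" for k in range(K)]
        if self.condition_labels is None:
            self.condition_labels = [f"cond{j + 1}" for j in range(J)]
        if self.session_indices is None:
            self.session_indices = list(range(1, I + 1))
        if self.edge_labels is None:
            self.edge_labels = [f"edge{v}" for v in range(V)]
        for name, labels, n in [
            ("subject_ids", self.subject_ids, K),
            ("condition_labels", self.condition_labels, J),
            ("session_indices", self.session_indices, I),
            ("edge_labels", self.edge_labels, V),
        ]:
            if len(labels) != n:
                raise ValueError(f"{name} has length {len(labels)}, expected {n}")
        if self.units not in _VALID_UNITS:
            raise ValueError(f"units must be one of {_VALID_UNITS}")
        if self.units == "r":
            obs = self.values[~self.missing_mask]
            if obs.size and (np.nanmax(np.abs(obs)) > 1 + 1e-12):
                raise ValueError("r-unit values must lie in [-1, 1]")

    # -- shape accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[2]

    @property
    def n_edges(self) -> int:
        return self.values.shape[3]

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def copy(self) -> "EdgeObservationPanel":
        return replace(
            self,
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            subject_ids=list(self.subject_ids),
            condition_labels=list(self.condition_labels),
            session_indices=list(self.session_indices),
            edge_labels=list(self.edge_labels),
        )

    def select_condition(self, condition) -> "EdgeObservationPanel":
        """Return a single-condition sub-panel (J = 1)."""
        j = self.condition_labels.index(condition)
        return replace(
            self,
            values=self.values[:, j : j + 1],
            missing_mask=self.missing_mask[:, j : j + 1],
            condition_labels=[condition],
        )

    # -- serialization ---------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: subject, condition, session, edge, value, missing."""
        K, J, I, V = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.subject_ids, self.condition_labels, self.session_indices,
             self.edge_labels],
            names=["subject", "condition", "session", "edge"],
        )
        df = pd.DataFrame(
            {"value": self.values.ravel(), "missing": self.missing_mask.ravel()},
            index=idx,
        ).reset_index()
        return df

    def to_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, units: str = "fisher_z"
                        ) -> "EdgeObservationPanel":
        subjects = list(pd.unique(df["subject"]))
        conditions = list(pd.unique(df["condition"]))
        sessions = list(pd.unique(df["session"]))
        edges = list(pd.unique(df["edge"]))
        shape = (len(subjects), len(conditions), len(sessions), len(edges))
        values = np.full(shape, np.nan)
        mask = np.ones(shape, dtype=bool)
        ki = {s: i for i, s in enumerate(subjects)}
        ji = {c: i for i, c in enumerate(conditions)}
        ii = {s: i for i, s in enumerate(sessions)}
        vi = {e: i for i, e in enumerate(edges)}
        k = df["subject"].map(ki).to_numpy()
        j = df["condition"].map(ji).to_numpy()
        i = df["session"].map(ii).to_numpy()
        v = df["edge"].map(vi).to_numpy()
        values[k, j, i, v] = df["value"].to_numpy()
        miss = df["missing"].to_numpy(dtype=bool) if "missing" in df else \
            np.zeros(len(df), dtype=bool)
        mask[k, j, i, v] = miss
        mask |= np.isnan(values)
        values = np.nan_to_num(values)
        return cls(values, mask, subjects, conditions, sessions, edges,
                   units=units)

    @classmethod
    def from_tsv(cls, path, units: str = "fisher_z") -> "EdgeObservationPanel":
        return cls.from_long_frame(pd.read_csv(path, sep="\t"), units=units)


def inject_missing(panel: EdgeObservationPanel, cells) -> EdgeObservationPanel:
    """Mark (subject, condition, session) cells as missing for all edges.

    Cells may be given as integer index triples or as
    (subject_id, condition_label, session_index) label triples.  The input
    panel is not modified.  Masking is rejected when it would leave a
    subject with no observed data, or — in a single-condition panel —
    blank an entire subject-by-condition cell.
    """
    out = panel.copy()
    K, J, I, _ = out.values.shape
    for cell in cells:
        k, j, i = cell
        if not isinstance(k, (int, np.integer)):
            k = out.subject_ids.index(k)
        if not isinstance(j, (int, np.integer)):
            j = out.condition_labels.index(j)
        if not isinstance(i, (int, np.integer)):
            i = out.session_indices.index(i)
        if not (0 <= k < K and 0 <= j < J and 0 <= i < I):
            raise IndexError(f"missingness cell {cell} out of bounds for "
                             f"shape {(K, J, I)}")
        out.missing_mask[k, j, i, :] = True
    cell_gone = out.missing_mask.all(axis=2).all(axis=-1)  # (K, J)
    if J == 1 and cell_gone.any():
        bad = [out.subject_ids[k] for k in np.where(cell_gone[:, 0])[0]]
        raise ValueError(
            f"masking removes every session of subject(s) {bad} in a "
            "single-condition panel")
    subj_gone = cell_gone.all(axis=1)
    if subj_gone.any():
        bad = [out.subject_ids[k] for k in np.where(subj_gone)[0]]
        raise ValueError(f"masking removes all data for subject(s) {bad}")
    return out
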