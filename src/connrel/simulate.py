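"""Synthetic multi-subject, multi-condition, multi-session data.

Every generator realizes the three-level random-effects model that the
reliability estimators assume: for edge v,

    y_ijk(v) = mu(v) + delta_k(v) + gamma_jk(v) + eps_ijk(v)

with independent zero-mean Gaussian subject effects delta ~ N(0, sigma3^2),
subject-by-condition effects gamma ~ N(0, sigma2^2), and session residuals
eps ~ N(0, sigma0^2).  Edges are simulated independently, so the configured
variance components are the exact ground truth for every downstream
estimator.  A time-series mode embeds the same draws as Fisher-z offsets in
per-scan ROI correlation targets, so the full pipeline (time series ->
connectivity -> edge panel -> variance components) can be exercised against
known truth.

The defaults mirror a serial-scanning design: 10 subjects, 4 conditions
(rest, inscapes, movie, flanker), 12 sessions, and a missingness helper
that blanks one flanker session in each of three subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import (ConnectivityMatrix, NetworkPartition,
                           TimeSeriesPanel, vectorize_edges)
from .panel import EdgeObservationPanel, inject_missing

__all__ = [
    "SimulationConfig",
    "EffectDraws",
    "ScanCollection",
    "simulate_edge_panel",
    "simulate_timeseries_panel",
    "default_missing_cells",
    "nearest_correlation",
]

DEFAULT_CONDITIONS = ("rest", "inscapes", "movie", "flanker")


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the three-level simulation.

    sigma3_sq, sigma2_sq, sigma0_sq are the between-subject,
    between-condition-within-subject, and between-session (residual)
    variances, in Fisher-z units squared.
    """

    n_subjects: int = 10
    n_conditions: int = 4
    n_sessions: int = 12
    n_edges: int = 1000
    n_rois: int = None  # when set, n_edges = n_rois * (n_rois - 1) / 2
    mu: float = 0.3
    sigma3_sq: float = 0.04
    sigma2_sq: float = 0.01
    sigma0_sq: float = 0.10
    n_timepoints: int = 414  # ~10 min at TR 1.45 s
    seed: int = 0
    condition_labels: tuple = None
    missingness: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_subjects < 2 or self.n_sessions < 2 or self.n_conditions < 1:
            raise ValueError("need K >= 2 subjects, I >= 2 sessions, "
                             "J >= 1 conditions")
        for name in ("sigma3_sq", "sigma2_sq", "sigma0_sq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_rois is not None:
            if self.n_rois < 3:
                raise ValueError("need at least 3 ROIs")
            self.n_edges = self.n_rois * (self.n_rois - 1) // 2
        if self.condition_labels is None:
            if self.n_conditions == len(DEFAULT_CONDITIONS):
                self.condition_labels = DEFAULT_CONDITIONS
            else:
                self.condition_labels = tuple(
                    f"cond{j + 1}" for j in range(self.n_conditions))
        if len(self.condition_labels) != self.n_conditions:
            raise ValueError("condition_labels length mismatch")
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim not in (0, 1) or (mu.ndim == 1
                                     and mu.size != self.n_edges):
            raise ValueError("mu must be a scalar or a length-V array of "
                             "per-edge means")
        for (k, j, i) in self.missingness:
            if not (0 <= k < self.n_subjects and 0 <= j < self.n_conditions
                    and 0 <= i < self.n_sessions):
                raise ValueError(f"missingness cell {(k, j, i)} out of bounds")


@dataclass
class EffectDraws:
    """Ground-truth random-effect realizations behind a simulated panel."""

    mu: float
    delta: np.ndarray  # (K, V) subject effects
    gamma: np.ndarray  # (K, J, V) subject-by-condition effects
    eps: np.ndarray    # (K, J, I, V) session residuals


def _rng(seed: int, *tag) -> np.random.Generator:
    # stable per-purpose streams independent of iteration order
    return np.random.default_rng(np.random.SeedSequence([seed, *tag]))


def simulate_edge_panel(config: SimulationConfig
                        ) -> tuple[EdgeObservationPanel, EffectDraws]:
    """Draw an edge panel directly from the three-level model.

    Returns the panel (Fisher-z units) and the ground-truth effect draws.
    Deterministic given ``config.seed``; edges are mutually independent.
    """
    K, J, I, V = (config.n_subjects, config.n_conditions,
                  config.n_sessions, config.n_edges)
    delta = _rng(config.seed, 3).normal(
        0.0, np.sqrt(config.sigma3_sq), size=(K, V))
    gamma = _rng(config.seed, 2).normal(
        0.0, np.sqrt(config.sigma2_sq), size=(K, J, V))
    eps = _rng(config.seed, 0).normal(
        0.0, np.sqrt(config.sigma0_sq), size=(K, J, I, V))
    mu = np.broadcast_to(np.asarray(config.mu, dtype=float), (V,))
    values = (mu
              + delta[:, None, None, :]
              + gamma[:, :, None, :]
              + eps)
    panel = EdgeObservationPanel(
        values,
        condition_labels=list(config.condition_labels),
        units="fisher_z",
    )
    if config.missingness:
        panel = inject_missing(panel, config.missingness)
    return panel, EffectDraws(config.mu, delta, gamma, eps)


def default_missing_cells(config: SimulationConfig,
                          condition: str = "flanker",
                          n_affected: int = 3) -> list:
    """Dropout pattern: ``n_affected`` subjects each missing one session of
    one condition (default flanker), sessions chosen deterministically."""
    if condition in config.condition_labels:
        j = config.condition_labels.index(condition)
    else:
        j = config.n_conditions - 1
    rng = _rng(config.seed, 99)
    subjects = rng.choice(config.n_subjects, size=n_affected, replace=False)
    sessions = rng.integers(0, config.n_sessions, size=n_affected)
    return [(int(k), j, int(i)) for k, i in zip(subjects, sessions)]


# ---------------------------------------------------------------------------
# time-series mode


def nearest_correlation(m: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix
    by eigenvalue clipping followed by diagonal renormalization."""
    m = (m + m.T) / 2.0
    w, q = np.linalg.eigh(m)
    w = np.clip(w, eig_floor, None)
    m = (q * w) @ q.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return (m + m.T) / 2.0


def default_base_correlation(partition: NetworkPartition, roi_labels,
                             within_r: float = 0.35,
                             between_r: float = 0.10) -> np.ndarray:
    """Block-structured base matrix: moderate within-network, weak
    between-network correlation."""
    nets = [partition.roi_to_network[r] for r in roi_labels]
    same = np.equal.outer(np.array(nets, dtype=object),
                          np.array(nets, dtype=object)).astype(float)
    base = np.where(same > 0, within_r, between_r)
    np.fill_diagonal(base, 1.0)
    return nearest_correlation(base)


@dataclass
class ScanCollection:
    """Per-scan ROI time series keyed (subject_id, condition, session)."""

    scans: dict
    roi_labels: list
    partition: NetworkPartition
    subject_ids: list
    condition_labels: list
    session_indices: list

    def __iter__(self):
        return iter(self.scans.items())

    def __getitem__(self, key) -> TimeSeriesPanel:
        return self.scans[key]

    def write_tsvs(self, directory) -> list:
        """One TSV per scan: sub-<K>_ses-<I>_task-<cond>_run-1_timeseries.tsv."""
        import os
        paths = []
        for (sub, cond, ses), ts in self.scans.items():
            k = self.subject_ids.index(sub) + 1
            name = f"sub-{k:02d}_ses-{ses:02d}_task-{cond}_run-1_timeseries.tsv"
            path = os.path.join(directory, name)
            ts.to_tsv(path)
            paths.append(path)
        return paths


def simulate_timeseries_panel(config: SimulationConfig,
                              partition: NetworkPartition = None,
                              base_correlation: np.ndarray = None
                              ) -> tuple[ScanCollection,
                                         EdgeObservationPanel, EffectDraws]:
    """Generate per-scan ROI time series whose correlation structure carries
    the three-level effect draws.

    For each scan, the target correlation matrix is built by adding the
    scan's random-effect draw (in Fisher-z space) to the z-transformed
    base matrix edge-wise, mapping back through tanh, and repairing to the
    nearest positive-definite correlation matrix.  Sampling is Gaussian via
    Cholesky, with a stable per-scan random stream.

    Returns the scan collection, the panel of target edge offsets (the same
    object :func:`simulate_edge_panel` would produce), and the effect draws.
    """
    if config.n_rois is None:
        raise ValueError("time-series mode requires n_rois in the config")
    if config.n_timepoints < 50:
        raise ValueError("need at least 50 timepoints")
    R = config.n_rois
    roi_labels = [f"roi{r + 1:03d}" for r in range(R)]
    if partition is None:
        partition = NetworkPartition.default(roi_labels)
    if base_correlation is None:
        base_correlation = default_base_correlation(partition, roi_labels)
    base_z = np.arctanh(np.clip(base_correlation, -0.999999, 0.999999))
    np.fill_diagonal(base_z, 0.0)

    panel, truth = simulate_edge_panel(config)
    # edge ordering consistent with vectorize_edges
    dummy = ConnectivityMatrix(np.eye(R), roi_labels)
    order = vectorize_edges(dummy, partition)
    pairs = [tuple(lbl.split("--")) for lbl in order.edge_labels]
    ridx = {lab: r for r, lab in enumerate(roi_labels)}
    rows = np.array([ridx[a] for a, _ in pairs])
    cols = np.array([ridx[b] for _, b in pairs])
    panel.edge_labels = list(order.edge_labels)
    panel.edge_blocks = list(order.blocks)

    scans = {}
    subject_ids = panel.subject_ids
    for k, sub in enumerate(subject_ids):
        for j, cond in enumerate(panel.condition_labels):
            for i, ses in enumerate(panel.session_indices):
                z = base_z.copy()
                z[rows, cols] = z[cols, rows] = (
                    base_z[rows, cols] + panel.values[k, j, i, :])
                target = np.tanh(z)
                np.fill_diagonal(target, 1.0)
                target = nearest_correlation(target)
                try:
                    L = np.linalg.cholesky(target)
                except np.linalg.LinAlgError as exc:
                    raise ValueError(
                        f"target correlation for scan (sub={sub}, "
                        f"cond={cond}, ses={ses}) is not positive definite"
                    ) from exc
                g = _rng(config.seed, 7, k, j, i)
                x = g.standard_normal((config.n_timepoints, R)) @ L.T
                scans[(sub, cond, ses)] = TimeSeriesPanel(x, roi_labels)
    coll = ScanCollection(scans, roi_labels, partition, subject_ids,
                          list(panel.condition_labels),
                          list(panel.session_indices))
    return coll, panel, truth
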