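"""ROI time series to network-sorted edge vectors.

Covers the scan-level derivation steps: the 24-parameter motion regressor
expansion, polynomial-plus-confound nuisance regression, pairwise Pearson
connectivity, and vectorization of the upper triangle into a canonical,
network-block-sorted edge order shared by every scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesPanel",
    "ConnectivityMatrix",
    "NetworkPartition",
    "EdgeVector",
    "CANONICAL_NETWORKS",
    "build_motion_regressors",
    "nuisance_regress",
    "roi_connectivity",
    "vectorize_edges",
    "matrix_from_edges",
]

# Canonical Yeo-7-style network ordering plus a bucket for ROIs outside
# every network; edge blocks are sorted by this list.
CANONICAL_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
    "no_overlap",
)

DEFAULT_TR_SECONDS = 1.45


@dataclass
class TimeSeriesPanel:
    """T x R matrix of ROI time series for a single scan."""

    data: np.ndarray
    roi_labels: list = None
    tr_seconds: float = DEFAULT_TR_SECONDS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a T x R matrix")
        if self.data.shape[0] < 10:
            raise ValueError("need at least 10 timepoints")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite entries")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.roi_labels is None:
            self.roi_labels = [f"roi{r + 1:03d}" for r in
                               range(self.data.shape[1])]
        if len(self.roi_labels) != self.data.shape[1]:
            raise ValueError("roi_labels length must match column count")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, columns=self.roi_labels).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr_seconds: float = DEFAULT_TR_SECONDS
                 ) -> "TimeSeriesPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(), list(df.columns), tr_seconds)


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI correlation matrix with unit diagonal."""

    matrix: np.ndarray
    roi_labels: list = None
    units: str = "r"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        R = self.matrix.shape[0]
        if self.matrix.shape != (R, R):
            raise ValueError("matrix must be square")
        if np.abs(self.matrix - self.matrix.T).max() > 1e-12:
            raise ValueError("matrix must be symmetric to 1e-12")
        if self.units == "r" and np.abs(self.matrix).max() > 1 + 1e-12:
            raise ValueError("r-unit entries must lie in [-1, 1]")
        if self.roi_labels is None:
            self.roi_labels = [f"roi{r + 1:03d}" for r in range(R)]

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.roi_labels,
                     columns=self.roi_labels).to_csv(path, sep="\t")


@dataclass
class NetworkPartition:
    """ROI -> intrinsic-connectivity-network membership.

    Networks are ordered by :data:`CANONICAL_NETWORKS` first, then by first
    appearance for any non-canonical labels; edge blocks are unordered
    network pairs sorted accordingly.
    """

    roi_to_network: dict
    network_order: tuple = field(default=None)

    def __post_init__(self):
        seen = list(dict.fromkeys(self.roi_to_network.values()))
        if self.network_order is None:
            canon = [n for n in CANONICAL_NETWORKS if n in seen]
            extra = [n for n in seen if n not in CANONICAL_NETWORKS]
            self.network_order = tuple(canon + extra)
        missing = [n for n in seen if n not in self.network_order]
        if missing:
            raise ValueError(f"networks {missing} absent from network_order")

    def network_index(self, roi) -> int:
        return self.network_order.index(self.roi_to_network[roi])

    def block_of(self, roi_a, roi_b) -> tuple:
        """Unordered network pair, sorted by canonical network order."""
        na, nb = self.roi_to_network[roi_a], self.roi_to_network[roi_b]
        ia, ib = self.network_order.index(na), self.network_order.index(nb)
        return (na, nb) if ia <= ib else (nb, na)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"roi_label": list(self.roi_to_network),
             "network": list(self.roi_to_network.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NetworkPartition":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["roi_label"], df["network"])))

    @classmethod
    def default(cls, roi_labels, n_networks: int = 7,
                include_no_overlap: bool = True) -> "NetworkPartition":
        """Contiguous assignment of ROIs to the canonical networks; the last
        few ROIs fall in the no-overlap bucket when requested."""
        nets = list(CANONICAL_NETWORKS[:n_networks])
        if include_no_overlap:
            nets.append("no_overlap")
        R = len(roi_labels)
        bounds = np.linspace(0, R, len(nets) + 1).astype(int)
        mapping = {}
        for g, net in enumerate(nets):
            for r in range(bounds[g], bounds[g + 1]):
                mapping[roi_labels[r]] = net
        return cls(mapping)


@dataclass
class EdgeVector:
    """Network-sorted strict-upper-triangle edge values for one scan."""

    values: np.ndarray
    edge_labels: list
    blocks: list  # network pair per edge
    units: str = "r"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.values) == len(self.edge_labels) == len(self.blocks)):
            raise ValueError("values, edge_labels, blocks must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "edge_label": self.edge_labels,
            "block": ["--".join(b) for b in self.blocks],
            "value": self.values,
        })


def build_motion_regressors(params6: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body motion parameters into the 24-regressor model.

    Column order: the 6 parameters p, then p^2, then the backward
    difference dp (first row zero), then dp^2.
    """
    p = np.asarray(params6, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError(f"expected a T x 6 matrix, got shape {p.shape}")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    dp = np.zeros_like(p)
    dp[1:] = np.diff(p, axis=0)
    return np.hstack([p, p ** 2, dp, dp ** 2])


def _orthogonal_polynomials(T: int, order: int) -> np.ndarray:
    """Legendre polynomials on [-1, 1] evaluated at T points, degrees 1..order."""
    if order < 1:
        return np.empty((T, 0))
    x = np.linspace(-1, 1, T)
    cols = [np.polynomial.legendre.Legendre.basis(d)(x)
            for d in range(1, order + 1)]
    return np.column_stack(cols)


def nuisance_regress(ts: TimeSeriesPanel,
                     confounds: np.ndarray = None,
                     poly_order: int = 2) -> TimeSeriesPanel:
    """OLS residuals of each ROI on intercept + polynomial trends + confounds.

    Exactly collinear design columns are dropped (reported in the error if
    the pruned design is still rank deficient); residuals are orthogonal to
    every retained column.
    """
    T = ts.n_timepoints
    design = [np.ones((T, 1)), _orthogonal_polynomials(T, poly_order)]
    names = ["intercept"] + [f"poly{d}" for d in range(1, poly_order + 1)]
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.shape[0] != T:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows, expected {T}")
        design.append(confounds)
        names += [f"confound{c + 1}" for c in range(confounds.shape[1])]
    X = np.hstack(design)

    # prune exactly collinear columns via rank-revealing QR
    keep, dropped = [], []
    for c in range(X.shape[1]):
        cand = X[:, keep + [c]]
        if np.linalg.matrix_rank(cand, tol=1e-10 * max(1.0, np.abs(cand).max())
                                 ) == len(keep) + 1:
            keep.append(c)
        else:
            dropped.append(names[c])
    X = X[:, keep]
    if X.shape[1] == 0 or np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design rank deficient after dropping {dropped}")

    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return TimeSeriesPanel(resid, list(ts.roi_labels), ts.tr_seconds)


def roi_connectivity(ts: TimeSeriesPanel) -> ConnectivityMatrix:
    """All pairwise Pearson correlations among ROI time series."""
    sd = ts.data.std(axis=0)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance ROI column(s): {[ts.roi_labels[z] for z in zero]}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, list(ts.roi_labels))


def _edge_order(roi_labels, partition: NetworkPartition):
    """Canonical edge ordering: by network block, then ascending (row, col)."""
    missing = [r for r in roi_labels if r not in partition.roi_to_network]
    if missing:
        raise ValueError(f"partition does not cover ROIs {missing}")
    R = len(roi_labels)
    entries = []
    for a in range(R):
        for b in range(a + 1, R):
            block = partition.block_of(roi_labels[a], roi_labels[b])
            key = (partition.network_order.index(block[0]),
                   partition.network_order.index(block[1]))
            entries.append((key, a, b, block))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    return entries


def vectorize_edges(cm: ConnectivityMatrix,
                    partition: NetworkPartition,
                    to_fisher_z: bool = False,
                    clip: float = None) -> EdgeVector:
    """Extract the strict upper triangle in canonical network-sorted order.

    The ordering depends only on the partition and ROI labels, so edge
    vectors from different scans of the same parcellation align
    element-wise.  With ``to_fisher_z``, values are atanh-transformed;
    |r| = 1 raises unless ``clip`` (e.g. 0.999999) is given.
    """
    entries = _edge_order(cm.roi_labels, partition)
    vals, labels, blocks = [], [], []
    for _, a, b, block in entries:
        v = cm.matrix[a, b]
        if to_fisher_z:
            if clip is not None:
                v = np.clip(v, -clip, clip)
            elif abs(v) >= 1:
                raise ValueError(
                    f"|r| = 1 at edge ({cm.roi_labels[a]}, {cm.roi_labels[b]}); "
                    "Fisher z is infinite (enable clipping)")
            v = np.arctanh(v)
        vals.append(v)
        # canonical label, independent of the input ROI ordering
        la, lb = sorted((cm.roi_labels[a], cm.roi_labels[b]))
        labels.append(f"{la}--{lb}")
        blocks.append(block)
    return EdgeVector(np.array(vals), labels, blocks,
                      units="fisher_z" if to_fisher_z else "r")


def matrix_from_edges(ev: EdgeVector, roi_labels) -> ConnectivityMatrix:
    """Reassemble the symmetric matrix from an edge vector (r units)."""
    if ev.units != "r":
        raise ValueError("reassembly expects r-unit edges")
    R = len(roi_labels)
    idx = {lab: i for i, lab in enumerate(roi_labels)}
    m = np.eye(R)
    for lab, v in zip(ev.edge_labels, ev.values):
        a, b = lab.split("--")
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = v
    return ConnectivityMatrix(m, list(roi_labels))
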