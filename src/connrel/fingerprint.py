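"""Connectome fingerprinting.

Whole-connectome edge vectors act as individual "fingerprints": scans from
the same person correlate more strongly with each other than with scans
from other people.  This module builds the scan-by-scan similarity matrix
(Pearson correlation of edge vectors), summarizes the same-subject and
different-subject pair distributions, and optionally scores nearest-
neighbour subject identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FingerprintModel",
    "FingerprintResults",
    "similarity_matrix",
    "within_between_stats",
    "identify",
]


def similarity_matrix(edge_vectors: np.ndarray) -> np.ndarray:
    """S x S Pearson correlations between scans' edge vectors.

    ``edge_vectors``: (S, V) with a shared edge order.  A constant vector
    has no defined correlation and raises, naming the scan.
    """
    X = np.asarray(edge_vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("edge_vectors must be (scans, edges)")
    sd = X.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant edge vector for scan index {bad.tolist()}")
    r = np.corrcoef(X)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def _pair_stats(values: np.ndarray) -> dict:
    n = values.size
    m = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    half = 1.96 * sd / np.sqrt(n)
    return {"mean": m, "sd": sd, "ci_low": m - half, "ci_high": m + half,
            "n_pairs": int(n)}


def within_between_stats(similarity: np.ndarray, subjects,
                         conditions=None, sessions=None,
                         stratum: str = "all") -> tuple:
    """Same-subject vs different-subject pair summaries.

    Unordered scan pairs are split by subject identity; each set is
    summarized by mean, SD and a normal-approximation 95% CI of the mean
    (mean +/- 1.96 sd / sqrt(n_pairs)).  ``stratum`` restricts which pairs
    enter: 'all' pools everything, 'same_condition' or 'same_session'
    keep only pairs matched on that factor.
    """
    S = similarity.shape[0]
    subjects = np.asarray(subjects)
    if subjects.size != S:
        raise ValueError("one subject label per scan required")
    iu = np.triu_indices(S, k=1)
    keep = np.ones(iu[0].size, dtype=bool)
    if stratum == "same_condition":
        conditions = np.asarray(conditions)
        keep &= conditions[iu[0]] == conditions[iu[1]]
    elif stratum == "same_session":
        sessions = np.asarray(sessions)
        keep &= sessions[iu[0]] == sessions[iu[1]]
    elif stratum != "all":
        raise ValueError("stratum must be 'all', 'same_condition' or "
                         "'same_session'")
    same = subjects[iu[0]] == subjects[iu[1]]
    vals = similarity[iu]
    w = vals[keep & same]
    b = vals[keep & ~same]
    if w.size == 0:
        raise ValueError("no same-subject scan pairs in the chosen stratum")
    if b.size == 0:
        raise ValueError("no different-subject scan pairs in the chosen "
                         "stratum")
    return _pair_stats(w), _pair_stats(b)


def identify(similarity: np.ndarray, subjects) -> float:
    """Nearest-neighbour identification accuracy.

    Each scan is assigned the subject of its most similar *other* scan;
    ties break toward the lowest scan index.  Every subject must have at
    least two scans.
    """
    subjects = np.asarray(subjects)
    S = similarity.shape[0]
    uniq, counts = np.unique(subjects, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every subject needs >= 2 scans for identification")
    correct = 0
    for s in range(S):
        row = similarity[s].copy()
        row[s] = -np.inf
        best = int(np.argmax(row))  # argmax returns the first (lowest) index
        correct += subjects[best] == subjects[s]
    return correct / S


class FingerprintModel:
    """Similarity-based fingerprinting over a stack of scan edge vectors.

    Parameters
    ----------
    edge_vectors : (S, V) array
        One row per scan; identical edge order across rows (raw r units
        by convention for matrix similarity).
    scan_meta : DataFrame with columns subject, condition, session
        One row per scan, aligned with ``edge_vectors``.
    """

    def __init__(self, edge_vectors: np.ndarray, scan_meta: pd.DataFrame):
        self.edge_vectors = np.asarray(edge_vectors, dtype=float)
        if len(scan_meta) != self.edge_vectors.shape[0]:
            raise ValueError("scan_meta rows must match edge_vectors rows")
        for col in ("subject", "condition", "session"):
            if col not in scan_meta.columns:
                raise ValueError(f"scan_meta missing column {col!r}")
        self.scan_meta = scan_meta.reset_index(drop=True)

    @classmethod
    def from_panel(cls, panel) -> "FingerprintModel":
        """Stack an EdgeObservationPanel's complete scans into a model."""
        rows, meta = [], []
        K, J, I, _ = panel.values.shape
        for k in range(K):
            for j in range(J):
                for i in range(I):
                    if panel.missing_mask[k, j, i].any():
                        continue
                    rows.append(panel.values[k, j, i])
                    meta.append((panel.subject_ids[k],
                                 panel.condition_labels[j],
                                 panel.session_indices[i]))
        meta = pd.DataFrame(meta, columns=["subject", "condition", "session"])
        return cls(np.array(rows), meta)

    def fit(self, stratum: str = "all",
            compute_identification: bool = True) -> "FingerprintResults":
        sim = similarity_matrix(self.edge_vectors)
        subjects = self.scan_meta["subject"].to_numpy()
        within, between = within_between_stats(
            sim, subjects,
            conditions=self.scan_meta["condition"].to_numpy(),
            sessions=self.scan_meta["session"].to_numpy(),
            stratum=stratum)
        acc = None
        if compute_identification:
            counts = self.scan_meta["subject"].value_counts()
            if (counts >= 2).all():
                acc = identify(sim, subjects)
        return FingerprintResults(self, sim, within, between, acc, stratum)


@dataclass
class FingerprintResults:
    """Similarity matrix plus pair-distribution summaries."""

    model: FingerprintModel
    similarity: np.ndarray
    within_stats: dict
    between_stats: dict
    id_accuracy: float = None
    stratum: str = "all"
    _pairs: pd.DataFrame = field(default=None, repr=False)

    @property
    def gap(self) -> float:
        """Same-subject minus different-subject mean similarity."""
        return self.within_stats["mean"] - self.between_stats["mean"]

    def pairs_frame(self) -> pd.DataFrame:
        """Long table of scan pairs for plotting: scan_a, scan_b, r, class."""
        if self._pairs is None:
            meta = self.model.scan_meta
            iu = np.triu_indices(self.similarity.shape[0], k=1)
            subj = meta["subject"].to_numpy()
            self._pairs = pd.DataFrame({
                "scan_a": iu[0],
                "scan_b": iu[1],
                "r": self.similarity[iu],
                "pair_class": np.where(subj[iu[0]] == subj[iu[1]],
                                       "within_subject", "between_subject"),
            })
        return self._pairs

    def summary(self) -> str:
        w, b = self.within_stats, self.between_stats
        lines = [
            "Connectome fingerprinting",
            "=" * 58,
            f"Scans: {self.similarity.shape[0]}   Pair stratum: "
            f"{self.stratum}",
            (f"Same subject:      mean {w['mean']:.3f}  SD {w['sd']:.3f}  "
             f"95% CI {w['ci_low']:.3f}-{w['ci_high']:.3f}  "
             f"(n={w['n_pairs']})"),
            (f"Different subject: mean {b['mean']:.3f}  SD {b['sd']:.3f}  "
             f"95% CI {b['ci_low']:.3f}-{b['ci_high']:.3f}  "
             f"(n={b['n_pairs']})"),
            f"Gap (same - different): {self.gap:.3f}",
        ]
        if self.id_accuracy is not None:
            lines.append(f"Identification accuracy: {self.id_accuracy:.3f}")
        return "\n".join(lines)
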