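"""Variance components and reliability of connectome edges.

The statistical core of the package.  Each edge's connectivity values over
a subjects x conditions x sessions design are modeled as

    y_ijk = mu + delta_k + gamma_jk + eps_ijk,

with independent Gaussian random effects: delta_k ~ N(0, sigma3^2) between
subjects, gamma_jk ~ N(0, sigma2^2) between conditions within subject, and
eps_ijk ~ N(0, sigma0^2) between sessions.  Two reliability coefficients
follow:

    ICC(between conditions) = sigma3^2 / (sigma3^2 + sigma2^2)
    ICC(between sessions)   = (sigma3^2 + sigma2^2)
                              / (sigma3^2 + sigma2^2 + sigma0^2)

Note the between-condition ICC deliberately excludes the session residual
from its denominator: it asks how stable the subject ordering is across
conditions, relative to condition-induced variation only.  A
``include_residual`` flag provides the total-variance-normalized variant.

Components are estimated by balanced-ANOVA method of moments when the
design is complete, and by an EM algorithm for the REML criterion when
sessions are missing; the two agree on complete data with interior
estimates.  The module also provides the multivariate image intraclass
correlation (I2C2) trace estimator for network blocks, distribution
summaries, scalar quality-measure reliability with a one-way condition
ANOVA, and the pseudo-session scan-duration analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import roi_connectivity, vectorize_edges, TimeSeriesPanel
from .panel import EdgeObservationPanel

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "ReliabilitySummary",
    "ScalarMeasurePanel",
    "EdgeReliabilityModel",
    "EdgeReliabilityResults",
    "anova_moments",
    "fit_em_reml",
    "icc_between_condition",
    "icc_between_session",
    "per_condition_icc",
    "i2c2",
    "i2c2_by_network",
    "summarize",
    "scalar_measure_reliability",
    "duration_pseudosessions",
]


@dataclass
class VarianceComponents:
    """Estimates of (mu, sigma3^2, sigma2^2, sigma0^2) for one edge."""

    mu: float
    sigma3_sq: float
    sigma2_sq: float
    sigma0_sq: float
    estimator: str = "mom"  # {"mom", "em_reml"}
    converged: bool = True
    n_used: int = 0

    @property
    def total_variance(self) -> float:
        return self.sigma3_sq + self.sigma2_sq + self.sigma0_sq


# ---------------------------------------------------------------------------
# method of moments (balanced ANOVA)


def _mom_arrays(values: np.ndarray):
    """Vectorized balanced-ANOVA moment estimators over the last axis.

    values: (K, J, I, V) complete data.  Returns dict of per-edge arrays
    including the three mean squares and the clamped component estimates.
    """
    K, J, I, V = values.shape
    gbar = values.mean(axis=(0, 1, 2))               # (V,)
    sbar = values.mean(axis=(1, 2))                  # (K, V)
    cbar = values.mean(axis=2)                       # (K, J, V)
    ms_subject = J * I * ((sbar - gbar) ** 2).sum(axis=0) / (K - 1)
    if J > 1:
        ms_cell = I * ((cbar - sbar[:, None, :]) ** 2).sum(axis=(0, 1)) \
            / (K * (J - 1))
    else:
        ms_cell = np.full(V, np.nan)
    if I > 1:
        ms_error = ((values - cbar[:, :, None, :]) ** 2).sum(axis=(0, 1, 2)) \
            / (K * J * (I - 1))
    else:
        ms_error = np.full(V, np.nan)
    sigma0 = ms_error
    if J > 1:
        sigma2 = (ms_cell - ms_error) / I
        sigma3 = (ms_subject - ms_cell) / (I * J)
    else:
        sigma2 = np.zeros(V)
        sigma3 = (ms_subject - ms_error) / I
    n_clamped = int((sigma2 < 0).sum() + (sigma3 < 0).sum()
                    + (sigma0 < 0).sum())
    if n_clamped:
        logger.info("method of moments: clamped %d negative component "
                    "estimates to zero", n_clamped)
    return {
        "mu": gbar,
        "sigma3_sq": np.clip(sigma3, 0, None),
        "sigma2_sq": np.clip(sigma2, 0, None),
        "sigma0_sq": np.clip(sigma0, 0, None),
        "ms_subject": ms_subject,
        "ms_cell": ms_cell,
        "ms_error": ms_error,
        "n_clamped": n_clamped,
    }


def anova_moments(panel: EdgeObservationPanel, edge: int):
    """Balanced-ANOVA mean squares and moment estimates for one edge.

    Requires complete data for the edge.  Returns
    (MS_subject, MS_cell, MS_error, VarianceComponents); negative moment
    estimates are clamped at zero.
    """
    if panel.missing_mask[..., edge].any():
        raise ValueError(
            "edge has missing observations; balanced ANOVA moments are "
            "undefined — use fit_em_reml instead")
    y = panel.values[..., edge : edge + 1]
    K, J, I, _ = y.shape
    if K < 2 or I < 2:
        raise ValueError("need K >= 2 subjects and I >= 2 sessions")
    out = _mom_arrays(y)
    vc = VarianceComponents(
        mu=float(out["mu"][0]),
        sigma3_sq=float(out["sigma3_sq"][0]),
        sigma2_sq=float(out["sigma2_sq"][0]),
        sigma0_sq=float(out["sigma0_sq"][0]),
        estimator="mom",
        converged=True,
        n_used=K * J * I,
    )
    return (float(out["ms_subject"][0]), float(out["ms_cell"][0]),
            float(out["ms_error"][0]), vc)


# ---------------------------------------------------------------------------
# EM algorithm for the REML criterion


def _em_reml_engine(ys, cells, subj_slices, include_cell,
                    tol=1e-10, max_iter=500, accel_every=4):
    """EM for the REML criterion of the nested model, batched over edges.

    Parameters
    ----------
    ys : (E, N) observations, concatenated over subjects
    cells : (N,) integer subject-by-condition cell label per observation
    subj_slices : list of slices, one per subject, into the N axis
    include_cell : fit the subject-by-condition component (three-level) or
        not (two-level subject/residual model)

    The basic iteration is the standard EM update for Gaussian variance
    components under the restricted likelihood, which keeps every
    component nonnegative by construction.  Because plain EM converges
    only linearly — painfully so when a component is small relative to the
    residual — every ``accel_every`` iterations an Aitken extrapolation of
    the parameter trajectory is attempted and accepted only where it does
    not decrease the restricted log-likelihood.  Convergence is declared
    when the Aitken-estimated distance to the fixed point drops below
    ``tol`` (relative to the edge's data variance).

    Returns dict of (E,) arrays: mu, sigma3_sq, sigma2_sq, sigma0_sq,
    converged, n_iter.
    """
    E, N = ys.shape
    K = len(subj_slices)
    n_cells = len(np.unique(cells))

    # per-subject fixed structure
    structs = []
    for sl in subj_slices:
        c = cells[sl]
        n_k = c.size
        C = (c[:, None] == c[None, :]).astype(float)
        M = np.stack([(c == u).astype(float) for u in np.unique(c)], axis=1)
        structs.append((sl, n_k, C, M))

    def evaluate(idx, s3a, s2a, s0a):
        """One restricted E-step at (s3a, s2a, s0a) for edges ``idx``:
        returns (loglik, beta, em-updated parameters)."""
        Ws, wys, us = [], [], []
        S = np.zeros(idx.size)
        Q = np.zeros(idx.size)
        logdet = np.zeros(idx.size)
        for sl, n_k, C, M in structs:
            y_k = ys[idx][:, sl]
            V = (s0a[:, None, None] * np.eye(n_k)
                 + s3a[:, None, None] * np.ones((n_k, n_k)))
            if include_cell:
                V += s2a[:, None, None] * C
            sign, ld = np.linalg.slogdet(V)
            logdet += ld
            W = np.linalg.inv(V)
            wy = np.einsum("enm,em->en", W, y_k)
            u = W.sum(axis=2)
            Ws.append(W)
            wys.append(wy)
            us.append(u)
            S += u.sum(axis=1)
            Q += (u * y_k).sum(axis=1)
        beta = Q / S

        quad3 = np.zeros(idx.size)
        tr3 = np.zeros(idx.size)
        quad2 = np.zeros(idx.size)
        tr2 = np.zeros(idx.size)
        quad0 = np.zeros(idx.size)
        tr0 = np.zeros(idx.size)
        ypy = np.zeros(idx.size)
        for (sl, n_k, C, M), W, wy, u in zip(structs, Ws, wys, us):
            y_k = ys[idx][:, sl]
            p = wy - u * beta[:, None]          # (P y) restricted to block
            s_k = u.sum(axis=1)
            ypy += (p * y_k).sum(axis=1)
            quad3 += p.sum(axis=1) ** 2
            tr3 += s_k - s_k ** 2 / S
            if include_cell:
                pc = p @ M                       # per-cell sums of Py
                quad2 += (pc ** 2).sum(axis=1)
                cw = np.einsum("enm,nc,mc->ec", W, M, M)  # 1_c' W 1_c
                cu = u @ M                       # 1_c' V^-1 1
                tr2 += (cw - cu ** 2 / S[:, None]).sum(axis=1)
            quad0 += (p ** 2).sum(axis=1)
            tr0 += np.einsum("enn->e", W) - (u ** 2).sum(axis=1) / S

        loglik = -0.5 * (logdet + np.log(S) + ypy)
        # keep V invertible: residual floored at a tiny scale-relative
        # value even when the within variance is genuinely zero
        floor0 = 1e-10 * np.maximum(var_y[idx], 1e-12)
        s3_new = np.maximum(s3a + s3a ** 2 * (quad3 - tr3) / K, 0.0)
        s0_new = np.maximum(s0a + s0a ** 2 * (quad0 - tr0) / N, floor0)
        if include_cell:
            s2_new = np.maximum(s2a + s2a ** 2 * (quad2 - tr2) / n_cells,
                                0.0)
        else:
            s2_new = s2a
        return loglik, beta, s3_new, s2_new, s0_new

    var_y = ys.var(axis=1, ddof=1) if N > 1 else np.zeros(E)
    var_y = np.maximum(var_y, 0.0)
    degenerate = var_y <= 1e-300
    init = np.maximum(var_y, 1e-12) / 3.0
    s3 = init.copy()
    s2 = init.copy() if include_cell else np.zeros(E)
    s0 = init.copy()
    mu = ys.mean(axis=1)
    converged = degenerate.copy()
    n_iter = np.zeros(E, dtype=int)
    active = ~degenerate
    s3[degenerate] = s2[degenerate] = s0[degenerate] = 0.0

    params = np.stack([s3, s2, s0], axis=0)      # (3, E)
    prev = None  # parameter iterate from the previous iteration

    for it in range(max_iter):
        if not active.any():
            break
        a = np.where(active)[0]
        ll, beta, s3n, s2n, s0n = evaluate(a, params[0, a], params[1, a],
                                           params[2, a])
        new = np.stack([s3n, s2n, s0n], axis=0)   # (3, |a|)

        # Aitken extrapolation, safeguarded by the restricted likelihood
        if prev is not None and it % accel_every == accel_every - 1:
            d1 = params[:, a] - prev[:, a]
            d2 = new - params[:, a]
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(np.abs(d1) > 0, d2 / d1, 0.0)
            rate = np.clip(rate, 0.0, 0.99)
            cand = np.maximum(new + d2 * rate / (1.0 - rate), 0.0)
            cand[2] = np.maximum(cand[2],
                                 1e-10 * np.maximum(var_y[a], 1e-12))
            ll_c, beta_c, s3c, s2c, s0c = evaluate(
                a, cand[0], cand[1], cand[2])
            accept = ll_c >= ll
            new = np.where(accept, np.stack([s3c, s2c, s0c]), new)
            beta = np.where(accept, beta_c, beta)

        # estimated distance to the fixed point
        step = np.abs(new - params[:, a])
        if prev is not None:
            d1 = np.abs(params[:, a] - prev[:, a])
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(d1 > 0, step / d1, 0.0)
            rate = np.clip(rate, 0.0, 0.99)
            err = step / (1.0 - rate)
        else:
            err = step
        done = err.max(axis=0) < tol * np.maximum(1.0, var_y[a])

        prev = params.copy()
        params[:, a] = new
        mu[a] = beta
        n_iter[a] += 1
        newly = a[done]
        converged[newly] = True
        active[newly] = False

    s3, s2, s0 = params
    # tidy exact boundaries
    s3[s3 < 1e-14] = 0.0
    s2[s2 < 1e-14] = 0.0
    s0[s0 < 1e-14] = 0.0
    return {
        "mu": mu,
        "sigma3_sq": s3,
        "sigma2_sq": s2 if include_cell else np.zeros(E),
        "sigma0_sq": s0,
        "converged": converged,
        "n_iter": n_iter,
    }


def _panel_to_obs(values: np.ndarray, mask: np.ndarray):
    """Flatten a (K, J, I, V) panel with a shared (K, J, I) missing pattern
    into per-subject observation blocks for the EM engine."""
    K, J, I, V = values.shape
    ys_parts, cell_parts, subj_slices = [], [], []
    start = 0
    for k in range(K):
        obs = ~mask[k]                       # (J, I)
        jj, ii = np.nonzero(obs)
        if jj.size == 0:
            raise ValueError(f"subject index {k} has no observed data")
        ys_parts.append(values[k, jj, ii, :].T)     # (V, n_k)
        cell_parts.append(k * J + jj)
        subj_slices.append(slice(start, start + jj.size))
        start += jj.size
    ys = np.concatenate(ys_parts, axis=1)
    cells = np.concatenate(cell_parts)
    return ys, cells, subj_slices


def _check_identifiable(mask: np.ndarray, include_cell: bool):
    """mask: (K, J, I) True = missing."""
    K, J, I = mask.shape
    obs = ~mask
    n_per_cell = obs.sum(axis=2)                     # (K, J)
    if not (n_per_cell >= 2).any():
        raise ValueError(
            "residual variance not identifiable: no subject-by-condition "
            "cell has two or more observed sessions")
    if include_cell:
        n_cond = (n_per_cell > 0).sum(axis=1)        # per subject
        if not (n_cond >= 2).any():
            raise ValueError(
                "between-condition variance not identifiable: no subject "
                "has two or more observed conditions")
    if K < 2:
        raise ValueError(
            "between-subject variance not identifiable: need >= 2 subjects")


def fit_em_reml(panel: EdgeObservationPanel, edge: int,
                tol: float = 1e-10, max_iter: int = 500
                ) -> VarianceComponents:
    """EM-REML estimates of (mu, sigma3^2, sigma2^2, sigma0^2) for one edge.

    Handles missing sessions; on complete balanced data with interior
    estimates it agrees with :func:`anova_moments`.  Nonnegativity is
    maintained by construction of the EM updates.
    """
    mask = panel.missing_mask[..., edge]
    include_cell = panel.n_conditions > 1
    _check_identifiable(mask, include_cell)
    ys, cells, subj_slices = _panel_to_obs(
        panel.values[..., edge : edge + 1], mask)
    out = _em_reml_engine(ys, cells, subj_slices, include_cell,
                          tol=tol, max_iter=max_iter)
    if not out["converged"][0]:
        logger.warning("EM-REML did not converge for edge %d after %d "
                       "iterations", edge, max_iter)
    return VarianceComponents(
        mu=float(out["mu"][0]),
        sigma3_sq=float(out["sigma3_sq"][0]),
        sigma2_sq=float(out["sigma2_sq"][0]),
        sigma0_sq=float(out["sigma0_sq"][0]),
        estimator="em_reml",
        converged=bool(out["converged"][0]),
        n_used=int(ys.shape[1]),
    )


# ---------------------------------------------------------------------------
# intraclass correlation coefficients


def _unpack(vc_or_s3, s2):
    if isinstance(vc_or_s3, VarianceComponents):
        return vc_or_s3.sigma3_sq, vc_or_s3.sigma2_sq, vc_or_s3.sigma0_sq
    return vc_or_s3, s2, None


def icc_between_condition(vc_or_sigma3_sq, sigma2_sq=None, sigma0_sq=None,
                          include_residual: bool = False):
    """Between-condition ICC: sigma3^2 / (sigma3^2 + sigma2^2).

    The session residual is excluded from the denominator by definition;
    pass ``include_residual=True`` (with sigma0^2 available) for the
    total-variance-normalized variant.  Returns NaN where the denominator
    is zero.
    """
    s3, s2, s0 = _unpack(vc_or_sigma3_sq, sigma2_sq)
    if sigma0_sq is not None:
        s0 = sigma0_sq
    s3 = np.asarray(s3, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    denom = s3 + s2
    if include_residual:
        if s0 is None:
            raise ValueError("include_residual requires sigma0_sq")
        denom = denom + np.asarray(s0, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, s3 / np.where(denom > 0, denom, 1.0),
                       np.nan)
    return float(out) if out.ndim == 0 else out


def icc_between_session(vc_or_sigma3_sq, sigma2_sq=None, sigma0_sq=None):
    """Between-session (test-retest) ICC:
    (sigma3^2 + sigma2^2) / (sigma3^2 + sigma2^2 + sigma0^2)."""
    s3, s2, s0 = _unpack(vc_or_sigma3_sq, sigma2_sq)
    if sigma0_sq is not None:
        s0 = sigma0_sq
    s3 = np.asarray(s3, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    denom = s3 + s2 + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (s3 + s2) / np.where(denom > 0, denom, 1.0),
                       np.nan)
    return float(out) if out.ndim == 0 else out


def per_condition_icc(panel: EdgeObservationPanel, edge: int = None,
                      tol: float = 1e-10, max_iter: int = 500):
    """Test-retest ICC within a single condition.

    Fits the two-level model y_ik = mu + b_k + e_ik by EM-REML and returns
    sigma_b^2 / (sigma_b^2 + sigma_w^2).  ``panel`` must hold exactly one
    condition (use :meth:`EdgeObservationPanel.select_condition`).  When
    ``edge`` is None, all edges are fitted and an array is returned.
    """
    if panel.n_conditions != 1:
        raise ValueError("per-condition ICC expects a single-condition panel")
    mask = panel.missing_mask.any(axis=-1)  # (K, 1, I)
    _check_identifiable(mask, include_cell=False)
    values = panel.values if edge is None else \
        panel.values[..., edge : edge + 1]
    ys, cells, subj_slices = _panel_to_obs(values, mask)
    out = _em_reml_engine(ys, cells, subj_slices, include_cell=False,
                          tol=tol, max_iter=max_iter)
    icc = icc_between_session(out["sigma3_sq"], np.zeros_like(out["sigma3_sq"]),
                              out["sigma0_sq"])
    return float(icc[0]) if edge is not None else icc


# ---------------------------------------------------------------------------
# I2C2: multivariate (image-level) intraclass correlation


def i2c2(W: np.ndarray, subjects) -> float:
    """Trace-based image intraclass correlation for replicate images.

    W : (S, p) matrix of S replicate observations of p-dimensional images
    (edge vectors); ``subjects`` labels each row.  Returns
    1 - tr_within / tr_total clamped to [0, 1], where tr_within pools
    squared deviations from subject means and tr_total from the grand
    mean.  NaN when total variation is zero.
    """
    W = np.asarray(W, dtype=float)
    subjects = np.asarray(subjects)
    S = W.shape[0]
    if S != subjects.size:
        raise ValueError("one subject label per row required")
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("need at least 2 subjects")
    ss_within = 0.0
    df_within = 0
    for s in uniq:
        rows = W[subjects == s]
        if rows.shape[0] < 2:
            continue
        ss_within += ((rows - rows.mean(axis=0)) ** 2).sum()
        df_within += rows.shape[0] - 1
    if df_within == 0:
        raise ValueError("need at least one subject with >= 2 replicates")
    tr_within = ss_within / df_within
    tr_total = ((W - W.mean(axis=0)) ** 2).sum() / (S - 1)
    if tr_total == 0:
        return float("nan")
    return float(np.clip(1.0 - tr_within / tr_total, 0.0, 1.0))


def panel_to_replicates(panel: EdgeObservationPanel,
                        pool_conditions: bool = True):
    """Stack a panel into an (S, p) replicate matrix for I2C2.

    With ``pool_conditions`` (the default), the replicate unit is the
    *session*: each replicate is the length J*V concatenation of all
    condition edge vectors from one (subject, session), so within-subject
    variation across replicates is purely between-session and the I2C2
    population target is (sigma3^2 + sigma2^2) / total variance.
    Otherwise every scan is its own replicate (within-subject variation
    then also includes the condition component).  Replicates containing
    missing data are dropped.

    Returns (W, subjects, blocks) where blocks extends the panel's edge
    blocks to the image coordinates (None when the panel carries none).
    """
    K, J, I, V = panel.values.shape
    rows, subs = [], []
    if pool_conditions:
        for k in range(K):
            for i in range(I):
                if panel.missing_mask[k, :, i].any():
                    continue
                rows.append(panel.values[k, :, i, :].reshape(J * V))
                subs.append(panel.subject_ids[k])
        blocks = (list(panel.edge_blocks) * J if panel.edge_blocks
                  else None)
    else:
        for k in range(K):
            for j in range(J):
                for i in range(I):
                    if panel.missing_mask[k, j, i].any():
                        continue
                    rows.append(panel.values[k, j, i, :])
                    subs.append(panel.subject_ids[k])
        blocks = list(panel.edge_blocks) if panel.edge_blocks else None
    return np.array(rows), np.array(subs), blocks


def i2c2_by_network(edge_matrix: np.ndarray, subjects, blocks,
                    networks=None, mode: str = "incident") -> dict:
    """I2C2 per network block of the edge vector, plus the full vector.

    ``blocks`` gives each edge's unordered network pair.  In ``incident``
    mode a network's block is every edge whose pair involves that network
    (matching a network-wise display of reliabilities); ``within`` mode
    keeps only edges internal to the network.
    """
    if mode not in ("incident", "within"):
        raise ValueError("mode must be 'incident' or 'within'")
    blocks = list(blocks)
    if networks is None:
        networks = list(dict.fromkeys(n for b in blocks for n in b))
    out = {"all": i2c2(edge_matrix, subjects)}
    for net in networks:
        if mode == "incident":
            cols = [v for v, b in enumerate(blocks) if net in b]
        else:
            cols = [v for v, b in enumerate(blocks)
                    if b[0] == net and b[1] == net]
        if cols:
            out[net] = i2c2(edge_matrix[:, cols], subjects)
    return out


# ---------------------------------------------------------------------------
# summaries


@dataclass
class ReliabilitySummary:
    """Distribution summary of per-edge ICCs, with network breakdown."""

    condition: str
    percentiles: dict                 # {50: ..., 75: ..., 95: ...}
    within_network: dict              # mean, sd, ci_low, ci_high, n
    between_network: dict
    per_block: pd.DataFrame = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "percentiles": self.percentiles,
            "within_network": self.within_network,
            "between_network": self.between_network,
        }


def _mean_stats(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n == 0:
        return {"mean": np.nan, "sd": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "n": 0}
    m = float(x.mean())
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    half = 1.96 * sd / np.sqrt(n)
    return {"mean": m, "sd": sd, "ci_low": m - half, "ci_high": m + half,
            "n": int(n)}


def summarize(icc: np.ndarray, blocks, condition: str = "all",
              percentiles=(50, 75, 95)) -> ReliabilitySummary:
    """Percentiles (linear interpolation) and within/between-network stats.

    ``blocks``: per-edge unordered network pair; an edge is within-network
    when both ROIs share a network.
    """
    icc = np.asarray(icc, dtype=float)
    blocks = list(blocks)
    if len(blocks) != icc.size:
        raise ValueError("one block label per edge required")
    finite = icc[np.isfinite(icc)]
    pct = {int(p): float(np.percentile(finite, p, method="linear"))
           for p in percentiles} if finite.size else \
        {int(p): np.nan for p in percentiles}
    within = np.array([b[0] == b[1] for b in blocks])
    rows = []
    for blk in dict.fromkeys(blocks):
        sel = np.array([b == blk for b in blocks])
        st = _mean_stats(icc[sel])
        rows.append({"block": "--".join(blk), **st})
    return ReliabilitySummary(
        condition=condition,
        percentiles=pct,
        within_network=_mean_stats(icc[within]),
        between_network=_mean_stats(icc[~within]),
        per_block=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# scalar quality measures


@dataclass
class ScalarMeasurePanel:
    """Per-scan scalar measures indexed (subject, condition, session, measure)."""

    values: np.ndarray
    missing_mask: np.ndarray = None
    subject_ids: list = None
    condition_labels: list = None
    session_indices: list = None
    measure_names: list = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be (subject, condition, session, "
                             "measure)")
        K, J, I, M = self.values.shape
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{k + 1:02d}" for k in range(K)]
        if self.condition_labels is None:
            self.condition_labels = [f"cond{j + 1}" for j in range(J)]
        if self.session_indices is None:
            self.session_indices = list(range(1, I + 1))
        if self.measure_names is None:
            self.measure_names = [f"measure{m + 1}" for m in range(M)]


def scalar_measure_reliability(panel: ScalarMeasurePanel,
                               anova_unit: str = "scan",
                               compute_icc: bool = True):
    """Reliability and condition effects for scalar per-scan measures.

    Returns (icc_table, anova_table):

    * icc_table — per (measure, condition) two-level test-retest ICC, as
      estimated by :func:`per_condition_icc` (empty when ``compute_icc``
      is off, e.g. for large condition-effect simulations);
    * anova_table — per measure, a one-way ANOVA of condition on the
      values (scan-level by default; ``anova_unit='subject'`` averages
      sessions within subject first), reporting F, df, and p.
    """
    K, J, I, M = panel.values.shape
    icc_rows = []
    for m, name in enumerate(panel.measure_names if compute_icc else []):
        for j, cond in enumerate(panel.condition_labels):
            vals = panel.values[:, j : j + 1, :, m : m + 1]
            mask = panel.missing_mask[:, j : j + 1, :, m : m + 1]
            sub = EdgeObservationPanel(
                vals, mask, subject_ids=list(panel.subject_ids),
                condition_labels=[cond],
                session_indices=list(panel.session_indices),
                edge_labels=[name])
            if np.ptp(vals[~mask]) == 0:
                icc = np.nan
                flag = "degenerate"
            else:
                icc = float(per_condition_icc(sub)[0])
                flag = "ok"
            icc_rows.append({"measure": name, "condition": cond,
                             "icc": icc, "flag": flag})
    icc_table = pd.DataFrame(icc_rows,
                             columns=["measure", "condition", "icc", "flag"])

    if J < 2:
        return icc_table, pd.DataFrame(
            columns=["measure", "F", "df_between", "df_within", "p"])
    anova_rows = []
    for m, name in enumerate(panel.measure_names):
        groups = []
        for j in range(J):
            v = panel.values[:, j, :, m]
            msk = panel.missing_mask[:, j, :, m]
            if anova_unit == "subject":
                with np.errstate(invalid="ignore"):
                    g = np.where(msk, np.nan, v)
                    g = np.nanmean(g, axis=1)
                g = g[np.isfinite(g)]
            else:
                g = v[~msk]
            groups.append(g)
        if any(g.size < 2 for g in groups) or \
                np.ptp(np.concatenate(groups)) == 0:
            anova_rows.append({"measure": name, "F": np.nan,
                               "df_between": J - 1,
                               "df_within": np.nan, "p": np.nan})
            continue
        F, p = sps.f_oneway(*groups)
        n_tot = sum(g.size for g in groups)
        anova_rows.append({"measure": name, "F": float(F),
                           "df_between": J - 1,
                           "df_within": n_tot - J, "p": float(p)})
    return icc_table, pd.DataFrame(anova_rows)


# ---------------------------------------------------------------------------
# scan-duration pseudo-sessions


def duration_pseudosessions(collection, minutes: int,
                            n_pseudosessions: int = 4,
                            seed: int = 0,
                            minutes_per_session: int = 10,
                            fisher_z: bool = True) -> EdgeObservationPanel:
    """Edge panel from temporally concatenated pseudo-sessions.

    Per subject and condition, sessions are sampled without replacement
    into ``n_pseudosessions`` disjoint groups of ``minutes /
    minutes_per_session`` sessions each; the group's time series are
    concatenated and correlated as a single longer scan.  The returned
    panel's session axis indexes pseudo-sessions.  Deterministic given
    ``seed``.
    """
    if minutes % minutes_per_session:
        raise ValueError("minutes must be a multiple of the per-session "
                         "duration")
    group = minutes // minutes_per_session
    need = n_pseudosessions * group
    subs = collection.subject_ids
    conds = collection.condition_labels
    partition = collection.partition

    values = None
    edge_labels = blocks = None
    for k, sub in enumerate(subs):
        for j, cond in enumerate(conds):
            sessions = sorted(ses for (s, c, ses) in collection.scans
                              if s == sub and c == cond)
            if len(sessions) < need:
                raise ValueError(
                    f"subject {sub}, condition {cond}: {len(sessions)} "
                    f"sessions available but {need} required for "
                    f"{n_pseudosessions} pseudo-sessions of {minutes} min")
            rng = np.random.default_rng(np.random.SeedSequence(
                [seed, minutes, k, j]))
            chosen = rng.permutation(sessions)[:need]
            for ps in range(n_pseudosessions):
                members = chosen[ps * group : (ps + 1) * group]
                data = np.vstack([collection[(sub, cond, int(s))].data
                                  for s in members])
                ts = TimeSeriesPanel(data, list(collection.roi_labels))
                ev = vectorize_edges(roi_connectivity(ts), partition,
                                     to_fisher_z=fisher_z,
                                     clip=0.999999 if fisher_z else None)
                if values is None:
                    V = len(ev.values)
                    values = np.zeros((len(subs), len(conds),
                                       n_pseudosessions, V))
                    edge_labels = list(ev.edge_labels)
                    blocks = list(ev.blocks)
                values[k, j, ps, :] = ev.values
    panel = EdgeObservationPanel(
        values, subject_ids=list(subs), condition_labels=list(conds),
        session_indices=list(range(1, n_pseudosessions + 1)),
        edge_labels=edge_labels,
        units="fisher_z" if fisher_z else "r")
    panel.edge_blocks = blocks
    return panel


# ---------------------------------------------------------------------------
# model / results interface


class EdgeReliabilityModel:
    """Three-level random-effects model for every edge of a panel.

    Parameters
    ----------
    panel : EdgeObservationPanel
        Edge-level observations; Fisher-z units recommended for fitting.

    ``fit`` dispatches to balanced-ANOVA method of moments on complete
    panels and to EM-REML whenever any observation is missing (or when
    forced with ``method='reml'``).
    """

    def __init__(self, panel: EdgeObservationPanel):
        self.panel = panel

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, units: str = "fisher_z"):
        return cls(EdgeObservationPanel.from_long_frame(df, units=units))

    @classmethod
    def from_tsv(cls, path, units: str = "fisher_z"):
        return cls(EdgeObservationPanel.from_tsv(path, units=units))

    def fit(self, method: str = "auto", tol: float = 1e-10,
            max_iter: int = 500) -> "EdgeReliabilityResults":
        panel = self.panel
        if method not in ("auto", "mom", "reml"):
            raise ValueError("method must be 'auto', 'mom' or 'reml'")
        use_reml = method == "reml" or (
            method == "auto" and not panel.is_complete)
        if method == "mom" and not panel.is_complete:
            raise ValueError("method-of-moments requires complete data; "
                             "use method='reml'")
        if use_reml:
            mask = panel.missing_mask.any(axis=-1)  # (K, J, I)
            per_edge_masks = not np.array_equal(
                panel.missing_mask,
                np.broadcast_to(mask[..., None], panel.missing_mask.shape))
            include_cell = panel.n_conditions > 1
            _check_identifiable(mask, include_cell)
            if per_edge_masks:
                raise ValueError("missingness must be shared across edges "
                                 "(scan-level dropout)")
            ys, cells, subj_slices = _panel_to_obs(panel.values, mask)
            out = _em_reml_engine(ys, cells, subj_slices, include_cell,
                                  tol=tol, max_iter=max_iter)
            estimator = "em_reml"
            n_used = ys.shape[1]
            n_clamped = 0
        else:
            out = _mom_arrays(panel.values)
            out["converged"] = np.ones(panel.n_edges, dtype=bool)
            estimator = "mom"
            n_used = panel.n_subjects * panel.n_conditions * panel.n_sessions
            n_clamped = out["n_clamped"]
        return EdgeReliabilityResults(
            model=self,
            mu=np.asarray(out["mu"], dtype=float),
            sigma3_sq=np.asarray(out["sigma3_sq"], dtype=float),
            sigma2_sq=np.asarray(out["sigma2_sq"], dtype=float),
            sigma0_sq=np.asarray(out["sigma0_sq"], dtype=float),
            converged=np.asarray(out["converged"], dtype=bool),
            estimator=estimator,
            n_used=n_used,
            n_clamped=n_clamped,
        )


@dataclass
class EdgeReliabilityResults:
    """Per-edge variance components, ICCs and summaries."""

    model: EdgeReliabilityModel
    mu: np.ndarray
    sigma3_sq: np.ndarray
    sigma2_sq: np.ndarray
    sigma0_sq: np.ndarray
    converged: np.ndarray
    estimator: str
    n_used: int
    n_clamped: int = 0

    @property
    def panel(self) -> EdgeObservationPanel:
        return self.model.panel

    def components(self, edge: int) -> VarianceComponents:
        return VarianceComponents(
            mu=float(self.mu[edge]),
            sigma3_sq=float(self.sigma3_sq[edge]),
            sigma2_sq=float(self.sigma2_sq[edge]),
            sigma0_sq=float(self.sigma0_sq[edge]),
            estimator=self.estimator,
            converged=bool(self.converged[edge]),
            n_used=self.n_used,
        )

    def icc_between_condition(self, include_residual: bool = False):
        return icc_between_condition(self.sigma3_sq, self.sigma2_sq,
                                     self.sigma0_sq,
                                     include_residual=include_residual)

    def icc_between_session(self):
        return icc_between_session(self.sigma3_sq, self.sigma2_sq,
                                   self.sigma0_sq)

    def per_condition_icc(self, condition) -> np.ndarray:
        """Two-level test-retest ICC within one condition, all edges."""
        sub = self.panel.select_condition(condition)
        return per_condition_icc(sub)

    def to_frame(self) -> pd.DataFrame:
        panel = self.panel
        blocks = panel.edge_blocks
        df = pd.DataFrame({
            "edge": panel.edge_labels,
            "block": ["--".join(b) for b in blocks] if blocks else "",
            "mu": self.mu,
            "sigma3_sq": self.sigma3_sq,
            "sigma2_sq": self.sigma2_sq,
            "sigma0_sq": self.sigma0_sq,
            "icc_between_condition": self.icc_between_condition(),
            "icc_between_session": self.icc_between_session(),
            "estimator": self.estimator,
            "converged": self.converged,
        })
        return df

    def summarize(self, blocks=None, which: str = "between_session",
                  condition: str = "all") -> ReliabilitySummary:
        if blocks is None:
            blocks = self.panel.edge_blocks
        if blocks is None:
            blocks = [("all", "all")] * self.panel.n_edges
        icc = (self.icc_between_session() if which == "between_session"
               else self.icc_between_condition())
        return summarize(icc, blocks, condition=condition)

    def summary(self) -> str:
        """Plain-text overview in the style of a fitted-model report."""
        panel = self.panel
        bc = self.icc_between_condition()
        bs = self.icc_between_session()
        lines = [
            "Edge reliability: three-level random-effects model",
            "=" * 58,
            f"Subjects: {panel.n_subjects}   Conditions: "
            f"{panel.n_conditions}   Sessions: {panel.n_sessions}   "
            f"Edges: {panel.n_edges}",
            f"Estimator: {self.estimator}   Units: {panel.units}   "
            f"Observations used: {self.n_used}",
            f"Converged: {int(self.converged.sum())}/{self.converged.size}"
            + (f"   Clamped moments: {self.n_clamped}"
               if self.estimator == "mom" else ""),
            "-" * 58,
            "Component        mean      median",
        ]
        for name, arr in [("sigma3^2", self.sigma3_sq),
                          ("sigma2^2", self.sigma2_sq),
                          ("sigma0^2", self.sigma0_sq)]:
            lines.append(f"{name:<12} {np.nanmean(arr):>9.4f} "
                         f"{np.nanmedian(arr):>10.4f}")
        lines.append("-" * 58)
        for name, arr in [("ICC between-condition", bc),
                          ("ICC between-session", bs)]:
            with np.errstate(all="ignore"):
                pct = np.nanpercentile(arr, [50, 75, 95])
            lines.append(f"{name}: 50th {pct[0]:.3f}  75th {pct[1]:.3f}  "
                         f"95th {pct[2]:.3f}")
        return "\n".join(lines)
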