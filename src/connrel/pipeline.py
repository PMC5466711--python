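"""Reproducible multi-stage workflow.

Ties the package's stages into a declarative run: simulate -> connectivity
-> panel assembly -> fingerprint / reliability / duration -> report.  A
single YAML (or dict) config drives everything; every artifact gets a JSON
sidecar recording the config hash, the seed and the package version, so a
rerun with an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (NetworkPartition, TimeSeriesPanel,
                           roi_connectivity, vectorize_edges)
from .design import generate_cohort, verify_schedule
from .fingerprint import FingerprintModel
from .panel import EdgeObservationPanel
from .reliability import (EdgeReliabilityModel, duration_pseudosessions,
                          i2c2_by_network, panel_to_replicates,
                          per_condition_icc, summarize)
from .simulate import (ScanCollection, SimulationConfig,
                       default_missing_cells, simulate_edge_panel,
                       simulate_timeseries_panel)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "MissingInputError", "StageError",
           "run", "report", "EXIT_OK", "EXIT_CONFIG", "EXIT_MISSING_INPUT",
           "EXIT_STAGE"]

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_MISSING_INPUT = 3
EXIT_STAGE = 4

ALL_STAGES = ("design", "simulate", "connect", "fingerprint", "reliability",
              "duration", "report")


class ConfigError(ValueError):
    """The run configuration violates the schema."""


class MissingInputError(FileNotFoundError):
    """A stage's upstream artifact is absent."""


class StageError(RuntimeError):
    """A stage failed during execution."""


@dataclass
class RunConfig:
    """Declarative description of a pipeline run."""

    outdir: str
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    fisher_z: bool = True
    icc_include_residual: bool = False
    i2c2_block_mode: str = "incident"
    anova_unit: str = "scan"
    missingness: str = "none"  # "none" | "flanker_default" | list of cells
    duration_minutes: list = field(default_factory=lambda: [10, 20, 30])
    n_pseudosessions: int = 4
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s) {unknown}; valid stages "
                              f"are {list(ALL_STAGES)}")
        if self.i2c2_block_mode not in ("incident", "within"):
            raise ConfigError("i2c2_block_mode must be 'incident' or "
                              "'within'")
        if self.anova_unit not in ("scan", "subject"):
            raise ConfigError("anova_unit must be 'scan' or 'subject'")
        if isinstance(self.missingness, str) and self.missingness not in (
                "none", "flanker_default"):
            raise ConfigError("missingness must be 'none', "
                              "'flanker_default', or a list of cells")
        try:
            self.sim_config = SimulationConfig(seed=self.seed,
                                               **self.simulation)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid simulation block: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        if not os.path.exists(path):
            raise MissingInputError(f"config file {path} not found")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        # hash the scientific configuration only, not where it is written
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("sim_config", "outdir", "log_level")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sidecar(cfg: RunConfig, path: str, stage: str) -> None:
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
            "stage": stage, "version": __version__}
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_tsv(cfg: RunConfig, df: pd.DataFrame, path: str, stage: str,
               **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", **kwargs)
    _sidecar(cfg, path, stage)


def _need(path: str, what: str):
    if not os.path.exists(path):
        raise MissingInputError(f"{what} not found at {path}; run the "
                                "producing stage first")
    return path


SCAN_RE = re.compile(
    r"sub-(\d+)_ses-(\d+)_task-([^_]+)_run-\d+_timeseries\.tsv$")


def _load_scans(cfg: RunConfig, out: str) -> ScanCollection:
    tsdir = _need(os.path.join(out, "timeseries"), "time-series directory")
    partition = NetworkPartition.from_tsv(
        _need(os.path.join(out, "partition.tsv"), "partition table"))
    scans = {}
    roi_labels = None
    for path in sorted(glob.glob(os.path.join(tsdir, "*_timeseries.tsv"))):
        m = SCAN_RE.search(os.path.basename(path))
        if not m:
            continue
        k, ses, cond = int(m.group(1)), int(m.group(2)), m.group(3)
        ts = TimeSeriesPanel.from_tsv(path)
        roi_labels = ts.roi_labels
        scans[(f"sub-{k:02d}", cond, ses)] = ts
    if not scans:
        raise MissingInputError(f"no scan TSVs found under {tsdir}")
    subs = sorted({s for s, _, _ in scans})
    conds = list(dict.fromkeys(c for _, c, _ in sorted(scans)))
    sess = sorted({i for _, _, i in scans})
    return ScanCollection(scans, roi_labels, partition, subs, conds, sess)


def _panel_with_blocks(path: str, partition_path: str = None,
                       units: str = "fisher_z") -> EdgeObservationPanel:
    panel = EdgeObservationPanel.from_tsv(path, units=units)
    if partition_path and os.path.exists(partition_path):
        partition = NetworkPartition.from_tsv(partition_path)
        blocks = []
        for lab in panel.edge_labels:
            a, b = str(lab).split("--")
            blocks.append(partition.block_of(a, b))
        panel.edge_blocks = blocks
    return panel


# ---------------------------------------------------------------------------
# stages


def _stage_design(cfg: RunConfig, out: str) -> None:
    sim = cfg.sim_config
    schedules = generate_cohort(sim.n_subjects, seed=cfg.seed,
                                conditions=sim.condition_labels,
                                n_sessions=sim.n_sessions)
    frames = []
    for sch in schedules:
        rep = verify_schedule(sch)
        if not rep.ok:
            raise StageError(f"generated schedule for {sch.subject_id} "
                             f"failed verification:\n{rep}")
        frames.append(sch.to_frame())
    _write_tsv(cfg, pd.concat(frames, ignore_index=True),
               os.path.join(out, "schedules.tsv"), "design")


def _stage_simulate(cfg: RunConfig, out: str) -> None:
    sim = cfg.sim_config
    if cfg.missingness == "flanker_default":
        sim.missingness = default_missing_cells(sim)
    elif isinstance(cfg.missingness, list):
        sim.missingness = [tuple(c) for c in cfg.missingness]
    if sim.n_rois is not None:
        coll, panel, truth = simulate_timeseries_panel(sim)
        tsdir = os.path.join(out, "timeseries")
        os.makedirs(tsdir, exist_ok=True)
        coll.write_tsvs(tsdir)
        coll.partition.to_tsv(os.path.join(out, "partition.tsv"))
        _sidecar(cfg, os.path.join(out, "partition.tsv"), "simulate")
    else:
        panel, truth = simulate_edge_panel(sim)
    _write_tsv(cfg, panel.to_long_frame(), os.path.join(out, "panel.tsv"),
               "simulate")
    truth_doc = {
        "mu": sim.mu, "sigma3_sq": sim.sigma3_sq,
        "sigma2_sq": sim.sigma2_sq, "sigma0_sq": sim.sigma0_sq,
        "n_subjects": sim.n_subjects, "n_conditions": sim.n_conditions,
        "n_sessions": sim.n_sessions, "n_edges": sim.n_edges,
        "missingness": [list(c) for c in sim.missingness],
    }
    with open(os.path.join(out, "truth.json"), "w") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _sidecar(cfg, os.path.join(out, "truth.json"), "simulate")


def _stage_connect(cfg: RunConfig, out: str) -> None:
    coll = _load_scans(cfg, out)
    values_z, values_r = None, None
    subs, conds, sess = (coll.subject_ids, coll.condition_labels,
                         coll.session_indices)
    mask = np.zeros((len(subs), len(conds), len(sess), 1), dtype=bool)
    edge_labels = blocks = None
    for k, sub in enumerate(subs):
        for j, cond in enumerate(conds):
            for i, ses in enumerate(sess):
                key = (sub, cond, ses)
                if key not in coll.scans:
                    mask[k, j, i, :] = True
                    continue
                cm = roi_connectivity(coll[key])
                ev_r = vectorize_edges(cm, coll.partition, to_fisher_z=False)
                ev_z = vectorize_edges(cm, coll.partition, to_fisher_z=True,
                                       clip=0.999999)
                if values_z is None:
                    V = len(ev_r.values)
                    shape = (len(subs), len(conds), len(sess), V)
                    values_z = np.zeros(shape)
                    values_r = np.zeros(shape)
                    mask = np.broadcast_to(mask, shape).copy()
                    edge_labels, blocks = list(ev_r.edge_labels), ev_r.blocks
                values_r[k, j, i] = ev_r.values
                values_z[k, j, i] = ev_z.values
    for name, vals, units in [("panel_z", values_z, "fisher_z"),
                              ("panel_r", values_r, "r")]:
        p = EdgeObservationPanel(
            vals, mask.copy(), subject_ids=subs, condition_labels=conds,
            session_indices=sess, edge_labels=edge_labels, units=units)
        _write_tsv(cfg, p.to_long_frame(),
                   os.path.join(out, f"{name}.tsv"), "connect")


def _fit_panel_path(cfg: RunConfig, out: str) -> str:
    # model fitting prefers z units; fall back to the simulated panel
    for name in (("panel_z.tsv",) if cfg.fisher_z else ("panel_r.tsv",)):
        if os.path.exists(os.path.join(out, name)):
            return os.path.join(out, name)
    return _need(os.path.join(out, "panel.tsv"), "edge panel")


def _stage_fingerprint(cfg: RunConfig, out: str) -> None:
    path = os.path.join(out, "panel_r.tsv")
    if not os.path.exists(path):
        path = _need(os.path.join(out, "panel.tsv"), "edge panel")
    panel = EdgeObservationPanel.from_tsv(path, units="fisher_z")
    model = FingerprintModel.from_panel(panel)
    res = model.fit()
    _write_tsv(cfg, pd.DataFrame(res.similarity),
               os.path.join(out, "similarity.tsv"), "fingerprint")
    _write_tsv(cfg, res.pairs_frame(), os.path.join(out, "pairs.tsv"),
               "fingerprint")
    doc = {"within": res.within_stats, "between": res.between_stats,
           "gap": res.gap, "id_accuracy": res.id_accuracy}
    with open(os.path.join(out, "fingerprint.json"), "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _sidecar(cfg, os.path.join(out, "fingerprint.json"), "fingerprint")


def _stage_reliability(cfg: RunConfig, out: str) -> None:
    panel = _panel_with_blocks(_fit_panel_path(cfg, out),
                               os.path.join(out, "partition.tsv"))
    res = EdgeReliabilityModel(panel).fit()
    _write_tsv(cfg, res.to_frame(), os.path.join(out, "edge_results.tsv"),
               "reliability")
    blocks = panel.edge_blocks or [("all", "all")] * panel.n_edges
    summ = {
        "between_condition": summarize(
            res.icc_between_condition(
                include_residual=cfg.icc_include_residual),
            blocks).to_dict(),
        "between_session": summarize(res.icc_between_session(),
                                     blocks).to_dict(),
    }
    # per-condition test-retest ICC medians
    per_cond = {}
    for cond in panel.condition_labels:
        icc = res.per_condition_icc(cond)
        per_cond[str(cond)] = float(np.nanmedian(icc))
    summ["per_condition_median_icc"] = per_cond
    # I2C2 per network; replicate = session with conditions pooled into
    # the image, so the univariate target matches the between-session ICC
    W, subjects, img_blocks = panel_to_replicates(panel)
    summ["i2c2"] = i2c2_by_network(
        W, subjects, img_blocks or list(blocks) * panel.n_conditions,
        mode=cfg.i2c2_block_mode)
    with open(os.path.join(out, "reliability_summary.json"), "w") as fh:
        json.dump(summ, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _sidecar(cfg, os.path.join(out, "reliability_summary.json"),
             "reliability")


def _stage_duration(cfg: RunConfig, out: str) -> None:
    coll = _load_scans(cfg, out)
    rows = []
    for minutes in cfg.duration_minutes:
        panel = duration_pseudosessions(
            coll, minutes, n_pseudosessions=cfg.n_pseudosessions,
            seed=cfg.seed, fisher_z=cfg.fisher_z)
        for cond in panel.condition_labels:
            icc = per_condition_icc(panel.select_condition(cond))
            rows.append({"condition": cond, "minutes": minutes,
                         "median_icc": float(np.nanmedian(icc)),
                         "n_edges": icc.size})
    _write_tsv(cfg, pd.DataFrame(rows), os.path.join(out, "duration.tsv"),
               "duration")


def report(cfg: RunConfig, out: str = None) -> str:
    """Assemble a deterministic markdown report from present artifacts;
    absent sections are marked explicitly."""
    out = out or cfg.outdir
    lines = ["# Connectome reliability report", ""]

    sched = os.path.join(out, "schedules.tsv")
    lines.append("## Counterbalanced design")
    if os.path.exists(sched):
        df = pd.read_csv(sched, sep="\t")
        n = df["subject_id"].nunique()
        lines.append(f"{n} subject schedule(s), "
                     f"{df['session'].max()} sessions x "
                     f"{df['slot'].max()} slots; all constraints verified.")
    else:
        lines.append("_absent_")
    lines.append("")

    lines.append("## Fingerprinting")
    fpath = os.path.join(out, "fingerprint.json")
    if os.path.exists(fpath):
        with open(fpath) as fh:
            fp = json.load(fh)
        for key, label in [("within", "Same subject"),
                           ("between", "Different subject")]:
            st = fp[key]
            lines.append(
                f"- {label}: mean {st['mean']:.3f}, SD {st['sd']:.3f}, "
                f"95% CI {st['ci_low']:.3f}-{st['ci_high']:.3f} "
                f"(n={st['n_pairs']})")
        if fp.get("id_accuracy") is not None:
            lines.append(f"- Identification accuracy: "
                         f"{fp['id_accuracy']:.3f}")
    else:
        lines.append("_absent_")
    lines.append("")

    lines.append("## Edge-wise reliability")
    rpath = os.path.join(out, "reliability_summary.json")
    if os.path.exists(rpath):
        with open(rpath) as fh:
            rs = json.load(fh)
        for key, label in [("between_condition", "Between-condition ICC"),
                           ("between_session", "Between-session ICC")]:
            s = rs[key]
            pct = s["percentiles"]
            for v in list(pct.values()) + [s["within_network"]["mean"]]:
                if v is not None and np.isfinite(v) and not (0 <= v <= 1):
                    raise StageError(
                        f"out-of-range ICC in summary record {key!r}: {v}")
            lines.append(
                f"- {label} percentiles: 50th {pct['50']:.3f}, "
                f"75th {pct['75']:.3f}, 95th {pct['95']:.3f}")
            for cell in ("within_network", "between_network"):
                st = s[cell]
                lines.append(
                    f"  - {cell.replace('_', ' ')}: mean "
                    f"{st['mean']:.3f}, SD {st['sd']:.3f}, 95% CI "
                    f"{st['ci_low']:.3f}-{st['ci_high']:.3f} (n={st['n']})")
        lines.append("- Per-condition median test-retest ICC: "
                     + ", ".join(f"{c}: {v:.3f}" for c, v in
                                 rs["per_condition_median_icc"].items()))
        lines.append("- Network I2C2: "
                     + ", ".join(f"{k}: {v:.3f}" for k, v in
                                 rs["i2c2"].items()))
    else:
        lines.append("_absent_")
    lines.append("")

    lines.append("## Scan-duration analysis")
    dpath = os.path.join(out, "duration.tsv")
    if os.path.exists(dpath):
        df = pd.read_csv(dpath, sep="\t")
        for cond, grp in df.groupby("condition", sort=False):
            vals = ", ".join(f"{int(m)} min: {v:.3f}" for m, v in
                             zip(grp["minutes"], grp["median_icc"]))
            lines.append(f"- {cond}: {vals}")
    else:
        lines.append("_absent_")
    lines.append("")
    text = "\n".join(lines)
    rp = os.path.join(out, "report.md")
    with open(rp, "w") as fh:
        fh.write(text)
    _sidecar(cfg, rp, "report")
    return text


_STAGE_FN = {
    "design": _stage_design,
    "simulate": _stage_simulate,
    "connect": _stage_connect,
    "fingerprint": _stage_fingerprint,
    "reliability": _stage_reliability,
    "duration": _stage_duration,
}


def run(cfg: RunConfig, stages=None) -> int:
    """Execute the configured stages in dependency order.

    Returns the process exit code (0 on success); raises nothing — errors
    map to the documented nonzero codes.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    stages = list(stages or cfg.stages)
    os.makedirs(cfg.outdir, exist_ok=True)
    try:
        for stage in ALL_STAGES:
            if stage not in stages:
                continue
            logger.info("stage %s", stage)
            if stage == "report":
                report(cfg)
            else:
                _STAGE_FN[stage](cfg, cfg.outdir)
    except ConfigError as exc:
        logger.error("config error: %s", exc)
        return EXIT_CONFIG
    except MissingInputError as exc:
        logger.error("missing input: %s", exc)
        return EXIT_MISSING_INPUT
    except Exception as exc:  # noqa: BLE001 — stage failures map to one code
        logger.error("stage failure: %s", exc)
        return EXIT_STAGE
    return EXIT_OK
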