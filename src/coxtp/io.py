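"""Delimited-text readers/writers and run manifests.

Expression matrices and survival tables are plain TSV/CSV (delimiter
auto-detected from the extension) with one header row and one identifier
column.  Missing expression cells (empty or NA-like tokens) are replaced
by 0.0 and counted; fits, traces and reports are serialized as JSON at
full precision, tables as TSV with six significant digits.
"""
from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SurvivalDataset

__all__ = ["read_expression", "read_survival", "build_dataset", "read_split",
           "write_path_outputs", "write_trace_outputs", "write_manifest",
           "load_sim_config"]

log = logging.getLogger("coxtp")

MISSING_TOKENS = {"", "na", "n/a", "nan", "null", "none", "?", "."}
FLOAT_FMT = "%.6g"


def _sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path, orientation: str = "samples-by-genes"):
    """Read an expression matrix; returns (matrix, gene_ids, sample_ids, n_imputed).

    ``orientation`` states how the file is laid out; the returned matrix
    is always samples x genes.  Missing cells become 0.0 (logged); a
    non-numeric cell that is not a recognized missing token is an error
    naming its row and column.
    """
    if orientation not in ("samples-by-genes", "genes-by-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(path))[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise ValueError(f"duplicate column ids in {path}: {dupes}")
    df = pd.read_csv(path, sep=_sep(path), index_col=0, dtype=str,
                     keep_default_na=False)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column ids in {path}: {dupes}")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=np.float64)
    n_imputed = 0
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell.lower() in MISSING_TOKENS:
                values[i, j] = 0.0
                n_imputed += 1
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r} of {path}") from exc
    if orientation == "genes-by-samples":
        values = np.ascontiguousarray(values.T)
        gene_ids = tuple(df.index.astype(str))
        sample_ids = tuple(df.columns.astype(str))
    else:
        gene_ids = tuple(df.columns.astype(str))
        sample_ids = tuple(df.index.astype(str))
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError(f"duplicate gene ids in {path}")
    if n_imputed:
        log.info("imputed %d missing expression cells with 0.0", n_imputed)
    return values, gene_ids, sample_ids, n_imputed


def read_survival(path):
    """Read a survival table with columns id, time, event."""
    df = pd.read_csv(path, sep=_sep(path))
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("id", "time", "event") if c not in cols]
    if missing:
        raise ValueError(f"{path} lacks required column(s): {missing}")
    ids = df[cols["id"]].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate patient ids in {path}: "
                         f"{ids[ids.duplicated()].tolist()}")
    times = pd.to_numeric(df[cols["time"]], errors="coerce").to_numpy()
    events = pd.to_numeric(df[cols["event"]], errors="coerce").to_numpy()
    for i, (t, e) in enumerate(zip(times, events)):
        if not np.isfinite(t) or t <= 0:
            raise ValueError(f"nonpositive or invalid time at row {i + 2} "
                             f"(id {ids.iloc[i]!r}) of {path}")
        if e not in (0, 1):
            raise ValueError(f"event not in {{0,1}} at row {i + 2} "
                             f"(id {ids.iloc[i]!r}) of {path}")
    return times, events.astype(np.int8), tuple(ids)


def build_dataset(expression_path, survival_path,
                  orientation: str = "samples-by-genes") -> SurvivalDataset:
    """Load and align expression and survival files into a dataset."""
    X, gene_ids, sample_ids, _ = read_expression(expression_path, orientation)
    times, events, surv_ids = read_survival(survival_path)
    pos = {s: i for i, s in enumerate(surv_ids)}
    unmatched = [s for s in sample_ids if s not in pos]
    if unmatched:
        raise ValueError(f"expression samples missing from survival table: "
                         f"{unmatched}")
    extra = sorted(set(surv_ids) - set(sample_ids))
    if extra:
        raise ValueError(f"survival ids not present in expression data: "
                         f"{extra}")
    order = np.array([pos[s] for s in sample_ids])
    return SurvivalDataset(times=times[order], events=events[order],
                           expression=X, gene_ids=gene_ids,
                           patient_ids=sample_ids)


def read_split(path):
    """Read a train/validation assignment file with columns id, role."""
    df = pd.read_csv(path, sep=_sep(path))
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "role" not in cols:
        raise ValueError(f"{path} needs columns id and role")
    roles = df[cols["role"]].astype(str).str.lower()
    bad = sorted(set(roles) - {"train", "validation"})
    if bad:
        raise ValueError(f"unknown roles in {path}: {bad}")
    ids = df[cols["id"]].astype(str)
    return (tuple(ids[roles == "train"]), tuple(ids[roles == "validation"]))


def write_path_outputs(path_obj, data: SurvivalDataset, outdir) -> None:
    """Long-format TSV of the path plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for step in path_obj.steps:
        for j in np.flatnonzero(np.abs(step.beta) > path_obj.zero_tol):
            rows.append({"k": step.index, "lambda": step.lam,
                         "gene_id": data.gene_ids[j],
                         "beta": step.beta[j]})
    pd.DataFrame(rows, columns=["k", "lambda", "gene_id", "beta"]).to_csv(
        outdir / "path.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    summary = {
        "lambda0": path_obj.lambda0,
        "lambda_z": path_obj.lambda_z,
        "n_steps": len(path_obj.steps) - 1,
        "steps": [{"k": s.index, "lambda": s.lam, "m": s.m,
                   "change_gene": None if s.change_gene is None
                   else data.gene_ids[s.change_gene],
                   "change_direction": s.change_direction,
                   "kkt_violation": s.kkt_violation,
                   "pseudo": s.pseudo}
                  for s in path_obj.steps],
        "diagnostics": path_obj.diagnostics,
    }
    (outdir / "path_summary.json").write_text(json.dumps(summary, indent=1))


def write_trace_outputs(trace, path_obj, data, outdir, optimum=None,
                        tp_selection=None, mixture_report=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = trace.to_frame()
    frame.to_csv(outdir / "trace.tsv", sep="\t", index=False,
                 float_format=FLOAT_FMT)
    report: dict = {"C": trace.C}
    if optimum is not None:
        report["optimum"] = {
            "lambda": optimum.lam_star, "k": optimum.k_star,
            "TP_hat": optimum.tp_hat, "FP_hat": optimum.fp_hat,
            "false_positive_rate": optimum.false_positive_rate,
        }
    if tp_selection is not None:
        report["tp_genes"] = {
            "genes": list(tp_selection.genes),
            "zeta": tp_selection.zeta,
            "TP_hat_raw": tp_selection.tp_hat_raw,
            "n_selected": tp_selection.n_selected,
        }
    if mixture_report is not None:
        report["mixture"] = mixture_report
    (outdir / "tracking_report.json").write_text(json.dumps(report, indent=1))


def write_manifest(outdir, command: str, config: dict) -> None:
    """Machine-readable record sufficient to rerun the command."""
    import coxtp

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "argv": sys.argv,
        "config": config,
        "versions": {
            "coxtp": coxtp.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))


def load_sim_config(path):
    """Simulation config from a YAML or JSON mapping."""
    import yaml

    from .simulate import SimConfig
    from .tracking import TrackingConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path} must contain a mapping of SimConfig fields")
    tracking = raw.pop("tracking", None)
    if "report_ks" in raw:
        raw["report_ks"] = tuple(raw["report_ks"])
    cfg = SimConfig(**raw)
    if tracking:
        cfg.tracking = TrackingConfig(**tracking)
    return cfg


def sim_config_dict(cfg) -> dict:
    d = asdict(cfg)
    d["report_ks"] = list(d["report_ks"])
    return d
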