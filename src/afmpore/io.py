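"""Measurement file I/O, run configuration and report writing.

Measurement files are strict comma-delimited UTF-8 text with a header and
columns ``pore_radius_nm, mwco_kda, mode, location_id, acquisition_index``
(radius strictly positive, '.' decimal separator).  One file may carry
several datasets; rows are grouped into one measurement set per
(MWCO, mode) pair on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .classify import ROCCurve, auc_category
from .datasets import PoreMeasurementSet
from .pipeline import SweepResult

REQUIRED_COLUMNS = ("pore_radius_nm", "mwco_kda", "mode", "location_id", "acquisition_index")


class MeasurementParseError(ValueError):
    """Raised when a measurement file violates the format contract."""


@dataclass
class RunConfig:
    """Thresholds and settings for a pipeline run, loadable from YAML."""

    eval_fraction: float = 0.8
    n_datasets: int = 10
    fractions: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
    seed: int = 0
    auc_floor: float = 0.7
    slope_tol: float = 0.01
    drift_threshold: float = 0.8
    jb_alpha: float = 0.05
    agreement_k: float = 2.0
    output_dir: str = "results"

    def __post_init__(self):
        if not 0.0 < self.eval_fraction < 1.0:
            raise ValueError("eval_fraction must be in (0, 1)")
        if not 0.0 <= self.auc_floor <= 1.0:
            raise ValueError("auc_floor must be in [0, 1]")
        if self.slope_tol < 0 or self.agreement_k < 0:
            raise ValueError("slope_tol and agreement_k must be >= 0")
        if not 0.0 < self.jb_alpha < 1.0:
            raise ValueError("jb_alpha must be in (0, 1)")
        if not 0.0 <= self.drift_threshold <= 1.0:
            raise ValueError("drift_threshold must be in [0, 1]")
        if any(not 0.0 < f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(**raw)


def read_measurements(path) -> Dict[Tuple[int, str], PoreMeasurementSet]:
    """Read a measurement file into one set per (MWCO kDa, mode) group.

    Errors name the offending 1-based file line (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementParseError(f"{path}: missing required column(s): {', '.join(missing)}")

    def numeric(col, kind=float):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            raise MeasurementParseError(
                f"{path}: line {bad[0] + 2}: non-numeric value in column {col!r}: "
                f"{df[col].iloc[bad[0]]!r}"
            )
        return converted.astype(kind)

    radius = numeric("pore_radius_nm")
    nonpos = radius.index[radius <= 0]
    if len(nonpos):
        raise MeasurementParseError(
            f"{path}: line {nonpos[0] + 2}: non-positive pore radius {radius.iloc[nonpos[0]]}"
        )
    mwco = numeric("mwco_kda", int)
    acq = numeric("acquisition_index", int)

    dup = pd.DataFrame({"mwco": mwco, "mode": df["mode"], "acq": acq}).duplicated()
    if dup.any():
        raise MeasurementParseError(
            f"{path}: line {dup.idxmax() + 2}: duplicate (mwco_kda, mode, acquisition_index)"
        )

    out: Dict[Tuple[int, str], PoreMeasurementSet] = {}
    keys = pd.DataFrame({"mwco": mwco, "mode": df["mode"]})
    for (m, mode), idx in keys.groupby(["mwco", "mode"], sort=True).groups.items():
        sub = np.argsort(acq.loc[idx].to_numpy(), kind="stable")
        idx = np.asarray(idx)[sub]
        try:
            out[(int(m), str(mode))] = PoreMeasurementSet(
                values=radius.loc[idx].to_numpy(),
                mwco_kda=int(m),
                mode=str(mode),
                location_ids=df["location_id"].loc[idx].to_numpy(),
                acquisition_index=acq.loc[idx].to_numpy(),
            )
        except ValueError as exc:
            raise MeasurementParseError(f"{path}: group ({m}, {mode}): {exc}") from exc
    return out


def write_measurements(sets: Sequence[PoreMeasurementSet], path) -> None:
    """Write measurement sets to the delimited format read_measurements expects."""
    frames = [
        pd.DataFrame(
            {
                "pore_radius_nm": ds.values,
                "mwco_kda": ds.mwco_kda,
                "mode": ds.mode,
                "location_id": ds.location_ids,
                "acquisition_index": ds.acquisition_index,
            }
        )
        for ds in sets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_roc_coordinates(roc: ROCCurve, path) -> None:
    """Export per-cutoff (cutoff, sensitivity, specificity) as delimited text."""
    pd.DataFrame(
        {"cutoff": roc.cutoffs, "sensitivity": roc.sensitivity, "specificity": roc.specificity}
    ).to_csv(path, index=False, float_format="%.6g")


@dataclass
class ReportBundle:
    """Completed pipeline outputs handed to the report writer.

    Every table is written as computed — the formatter never recomputes a
    statistic.  Sections left as None are omitted.
    """

    qc_table: pd.DataFrame | None = None
    discrimination_table: pd.DataFrame | None = None
    replicate_auc_table: pd.DataFrame | None = None
    sweep: Sequence[SweepResult] | None = None
    optimal_fraction: float | None = None
    scan_time_reduction_pct: float | None = None
    roc_curves: Mapping[str, ROCCurve] = field(default_factory=dict)


def sweep_table(sweep: Sequence[SweepResult]) -> pd.DataFrame:
    rows = []
    for s in sweep:
        if s.valid:
            m = s.summary
            rows.append(
                dict(
                    fraction=s.fraction, valid=True,
                    auc_mean=m.auc_mean, auc_sd=m.auc_sd,
                    acc_mean=m.acc_mean, acc_sd=m.acc_sd,
                    youden_mean=m.youden_mean, youden_sd=m.youden_sd,
                    beta0_mean=m.beta0_mean, beta1_mean=m.beta1_mean,
                )
            )
        else:
            rows.append(dict(fraction=s.fraction, valid=False))
    return pd.DataFrame(rows)


def run_report(bundle: ReportBundle, output_dir) -> Dict[str, Path]:
    """Write the report files for one pipeline run; returns section -> path.

    Emits, when present: the QC table (normality / drift / location-shift
    screen), the pairwise discrimination table, the replicate AUC table
    (with categorical strength per mean AUC), the test-size sweep table
    with the selected fraction and projected scan-time saving, and ROC
    coordinate files.  Output is deterministic for fixed inputs.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    notices: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> Path:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.6g")
        return p

    if bundle.qc_table is not None:
        written["qc"] = emit(bundle.qc_table, "qc_summary.csv")
    if bundle.discrimination_table is not None:
        written["discrimination"] = emit(bundle.discrimination_table, "discrimination.csv")
    if bundle.replicate_auc_table is not None:
        table = bundle.replicate_auc_table.copy()
        if "auc_mean" in table.columns and "auc_category" not in table.columns:
            table["auc_category"] = [auc_category(v) for v in table["auc_mean"]]
        written["replicate_auc"] = emit(table, "replicate_auc.csv")
    if bundle.sweep:
        df = sweep_table(bundle.sweep)
        written["sweep"] = emit(df, "sweep.csv")
        summary_lines = []
        if bundle.optimal_fraction is not None:
            summary_lines.append(f"optimal_fraction: {bundle.optimal_fraction:g}")
        if bundle.scan_time_reduction_pct is not None:
            summary_lines.append(
                f"scan_time_reduction_percent: {bundle.scan_time_reduction_pct:g}"
            )
        if summary_lines:
            p = outdir / "sweep_summary.txt"
            p.write_text("\n".join(summary_lines) + "\n", encoding="utf-8")
            written["sweep_summary"] = p
    elif bundle.sweep is not None:
        notices.append("sweep section omitted: sweep result list was empty")
    for name, roc in bundle.roc_curves.items():
        p = outdir / f"roc_{name}.csv"
        write_roc_coordinates(roc, p)
        written[f"roc_{name}"] = p
    if notices:
        p = outdir / "report_notices.txt"
        p.write_text("\n".join(notices) + "\n", encoding="utf-8")
        written["notices"] = p
    return written
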