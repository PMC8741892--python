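"""Readers, writers and report formatting.

Survival CSV dialect: header ``id,time_years,event,<covariate...>``; one
row per patient, no missing values in model columns.  Expression TSV:
first column ``gene_id``, remaining columns sample ids.  Reports are
deterministic byte-for-byte given identical inputs: a Table-1-style
coefficient CSV (3-decimal formatting) plus a full-precision JSON summary.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cutoff import CutoffScanResult
from .km import KMCurve, curve_table
from .model import (
    MixtureFit,
    SurvivalRecord,
    Z_975,
    confidence_interval,
    wald_test,
)

__all__ = [
    "read_survival_csv",
    "write_survival_csv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_csv",
    "fit_report_frame",
    "write_fit_report",
    "write_scan_report",
    "write_curves_csv",
    "write_manifest",
]

SURVIVAL_COLUMNS = ("id", "time_years", "event")


def read_survival_csv(path) -> tuple[list[str], list[SurvivalRecord]]:
    """Read the survival CSV dialect; fail fast with the offending row.

    Returns (ids, records).  Row numbers in error messages count data rows
    from 1 (the header is row 0).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    covariate_cols = [c for c in df.columns if c not in SURVIVAL_COLUMNS]
    ids, records = [], []
    for i, rowd in enumerate(df.to_dict(orient="records"), start=1):
        time = rowd["time_years"]
        event = rowd["event"]
        if not (isinstance(time, (int, float)) and math.isfinite(time) and time > 0):
            raise ValueError(f"{path}: row {i}: time_years must be > 0, got {time}")
        if event not in (0, 1):
            raise ValueError(f"{path}: row {i}: event must be 0 or 1, got {event}")
        covs = {}
        for c in covariate_cols:
            v = rowd[c]
            if v is None or (isinstance(v, float) and not math.isfinite(v)):
                raise ValueError(f"{path}: row {i}: missing value in column {c!r}")
            covs[c] = float(v)
        ids.append(str(rowd["id"]))
        records.append(SurvivalRecord(time=float(time), event=int(event), covariates=covs))
    return ids, records


def write_survival_csv(
    ids: Sequence[str], records: Sequence[SurvivalRecord], path
) -> None:
    covariates = sorted({k for r in records for k in r.covariates})
    rows = []
    for sid, r in zip(ids, records):
        row = {"id": sid, "time_years": repr(float(r.time)), "event": r.event}
        row.update({c: repr(float(r.covariates[c])) for c in covariates})
        rows.append(row)
    pd.DataFrame(rows, columns=list(SURVIVAL_COLUMNS) + covariates).to_csv(
        path, index=False
    )


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes-by-samples log2 expression matrix with labels."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.name != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.index.name!r}")
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene ids {dupes}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise ValueError(f"{path}: non-finite expression values")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_annotation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=False)
    if "sample_id" not in df.columns or "subtype" not in df.columns:
        raise ValueError(f"{path}: need columns sample_id and subtype")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def fit_report_frame(fit_result: MixtureFit) -> pd.DataFrame:
    """Coefficient table mirroring the published layout: one row per
    (part, term) with estimate, 95% CI and Wald p."""
    rows = []
    have_se = fit_result.standard_errors is not None
    for part, term in fit_result.design.labels():
        est = fit_result.estimate(part, term)
        if have_se:
            lo, hi = confidence_interval(fit_result, part, term)
            _, p = wald_test(fit_result, part, term)
        else:
            lo = hi = p = np.nan
        rows.append({
            "part": part, "term": term, "estimate": est,
            "ci_low": lo, "ci_high": hi, "wald_p": p,
        })
    return pd.DataFrame(rows)


def write_fit_report(
    fit_result: MixtureFit,
    outdir,
    stem: str = "fit",
    lrt_p: Optional[float] = None,
) -> tuple[Path, Path]:
    """Write the Table-1-style CSV (3 decimals) and a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}_coefficients.csv"
    frame = fit_report_frame(fit_result)
    frame.to_csv(csv_path, index=False, float_format="%.3f")

    summary = {
        "design": fit_result.design.describe(),
        "loglik": fit_result.loglik,
        "aic": fit_result.aic,
        "n": fit_result.n,
        "n_events": fit_result.n_events,
        "converged": fit_result.converged,
        "lrt_p": lrt_p,
        "coefficients": {
            f"{part}:{term}": fit_result.estimate(part, term)
            for part, term in fit_result.design.labels()
        },
        "z_975": Z_975,
    }
    json_path = outdir / f"{stem}_summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path


def write_scan_report(result: CutoffScanResult, path) -> Path:
    """Per-decile scan report CSV (plus metadata as # comments)."""
    path = Path(path)
    table = result.table()
    with open(path, "w") as fh:
        for key in sorted(result.metadata):
            fh.write(f"# {key}: {result.metadata[key]}\n")
        fh.write("# conditional_weights: one-pass from final fit\n")
        table.to_csv(fh, index=False, float_format="%.6g")
    return path


def write_curves_csv(
    curves: Mapping[object, KMCurve], path, log_time: bool = False
) -> Path:
    """Export step curves as ``group,time_years,survival`` rows."""
    path = Path(path)
    frames = []
    for group in curves:
        tab = curve_table(curves[group], log_time=log_time)
        tab.insert(0, "group", group)
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out.columns = ["group", "time_years", "survival"]
    out.to_csv(path, index=False)
    return path


def write_manifest(outdir, **info) -> Path:
    """Reproducibility manifest written beside outputs."""
    import cureaft

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "cureaft",
        "version": cureaft.__version__,
        "quantile_convention": "linear interpolation (type 7)",
        "tie_rules": {
            "dichotomization": "value > cutoff is high; ties to low",
            "kaplan_meier": "events before censorings at tied times",
        },
        **info,
    }
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
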