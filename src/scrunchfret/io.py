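"""Delimited-text readers and writers.

All on-disk formats are diff-able delimited text with ``#`` comment headers:

* trace sets — one file per trace with columns ``frame, I_D, I_A,
  is_check_frame`` plus a YAML manifest holding truth parameters and seeds;
* titrations / time courses — ``x, y[, y_err]`` with the units and
  generating model named in the header;
* fit results and rate matrices — key-value or matrix tables.

Floats are written with 17 significant digits so write -> read round-trips
are lossless.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import yaml

from .errors import EmptyTraceError, SchemaError
from .models import TitrationDataset, Trace, TraceSet

__all__ = [
    "write_trace",
    "read_trace",
    "write_trace_set",
    "read_trace_set",
    "write_titration",
    "read_titration",
    "write_table",
]

FLOAT_FMT = "%.17g"
TRACE_COLUMNS = ["frame", "I_D", "I_A", "is_check_frame"]


def _fmt(v: float) -> str:
    return FLOAT_FMT % v


def write_trace(trace: Trace, path, header_lines=()) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        for f, d, a, c in zip(
            trace.frame, trace.I_D, trace.I_A, trace.is_check_frame
        ):
            fh.write(f"{f}\t{_fmt(d)}\t{_fmt(a)}\t{int(c)}\n")


def read_trace(path) -> Trace:
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")]
    if not body:
        raise EmptyTraceError(f"trace file {path} contains no data rows")
    header_no, header = body[0]
    cols = header.split("\t")
    missing = [c for c in TRACE_COLUMNS if c not in cols]
    if missing:
        raise SchemaError(
            f"missing column(s) {missing}", path=str(path), line=header_no
        )
    try:
        df = pd.read_csv(_io.StringIO(text), sep="\t", comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed body
        raise SchemaError(f"unparseable trace file: {exc}", path=str(path)) from exc
    if len(df) == 0:
        raise EmptyTraceError(f"trace file {path} contains no data rows")
    for no, ln in body[1:]:
        if len(ln.split("\t")) != len(cols):
            raise SchemaError("wrong number of fields", path=str(path), line=no)
    return Trace(
        frame=df["frame"].to_numpy(),
        I_D=df["I_D"].to_numpy(float),
        I_A=df["I_A"].to_numpy(float),
        is_check_frame=df["is_check_frame"].to_numpy().astype(bool),
        meta={"source": str(path)},
    )


def write_trace_set(ts: TraceSet, directory) -> None:
    """One delimited file per trace plus ``manifest.yaml``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, tr in enumerate(ts):
        write_trace(tr, directory / f"trace_{i:04d}.txt")
    with (directory / "manifest.yaml").open("w") as fh:
        yaml.safe_dump(ts.manifest, fh, sort_keys=True)


def read_trace_set(directory) -> TraceSet:
    directory = Path(directory)
    files = sorted(directory.glob("trace_*.txt"))
    if not files:
        raise EmptyTraceError(f"no trace files found in {directory}")
    traces = []
    for i, f in enumerate(files):
        tr = read_trace(f)
        tr.meta["trace_id"] = i
        traces.append(tr)
    manifest = {}
    mf = directory / "manifest.yaml"
    if mf.exists():
        manifest = yaml.safe_load(mf.read_text()) or {}
    return TraceSet(traces=traces, manifest=manifest)


def write_titration(data: TitrationDataset, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# x_unit: {data.x_unit}\n")
        fh.write(f"# y_kind: {data.y_kind}\n")
        if data.meta.get("model"):
            fh.write(f"# model: {data.meta['model']}\n")
        cols = ["x", "y"] + (["y_err"] if data.y_err is not None else [])
        fh.write("\t".join(cols) + "\n")
        for i in range(len(data)):
            row = [_fmt(data.x[i]), _fmt(data.y[i])]
            if data.y_err is not None:
                row.append(_fmt(data.y_err[i]))
            fh.write("\t".join(row) + "\n")


def read_titration(path) -> TitrationDataset:
    path = Path(path)
    text = path.read_text()
    meta = {}
    x_unit, y_kind = "uM", "fluorescence"
    for ln in text.splitlines():
        if ln.startswith("#") and ":" in ln:
            key, _, val = ln.lstrip("# ").partition(":")
            key, val = key.strip(), val.strip()
            if key == "x_unit":
                x_unit = val
            elif key == "y_kind":
                y_kind = val
            else:
                meta[key] = val
    try:
        df = pd.read_csv(_io.StringIO(text), sep="\t", comment="#", float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"unparseable titration file: {exc}", path=str(path)) from exc
    for col in ("x", "y"):
        if col not in df.columns:
            raise SchemaError(f"missing column '{col}'", path=str(path))
    if len(df) == 0:
        raise EmptyTraceError(f"titration file {path} contains no data rows")
    return TitrationDataset(
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        y_err=df["y_err"].to_numpy(float) if "y_err" in df.columns else None,
        x_unit=x_unit,
        y_kind=y_kind,
        meta=meta,
    )


def write_table(df: pd.DataFrame, path, header_lines=()) -> None:
    """Delimited table with provenance header comments."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)
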