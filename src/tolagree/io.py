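"""Reading paired measurements and writing analysis reports.

Input is wide-format delimited text: one row per subject, one or more
replicate columns per measurement method (delimiter sniffed among comma,
tab and semicolon).  Reports round-trip through JSON at full floating-point
precision.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .intervals import DifferenceSummary, StatInterval
from .pipeline import AcceptanceSpec, MDData, MDResult, PairedSample

__all__ = ["read_paired_csv", "ReportBundle", "write_report", "read_report"]

logger = logging.getLogger(__name__)

ColumnSel = Sequence[Union[str, int]]


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()[0]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _resolve_columns(df: pd.DataFrame, cols: ColumnSel, which: str) -> List[str]:
    resolved = []
    for c in cols:
        if isinstance(c, int):
            if not (0 <= c < df.shape[1]):
                raise ValueError(f"{which} column index {c} out of range "
                                 f"(file has {df.shape[1]} columns)")
            resolved.append(df.columns[c])
        else:
            if c not in df.columns:
                raise ValueError(f"{which} column {c!r} not found; available: "
                                 f"{list(df.columns)}")
            resolved.append(c)
    return resolved


def read_paired_csv(
    path,
    x_cols: ColumnSel,
    y_cols: ColumnSel,
    id_col: Optional[Union[str, int]] = None,
    method_names: Optional[tuple] = None,
) -> PairedSample:
    """Read a wide-format paired-measurement file.

    ``x_cols``/``y_cols`` are column names or 0-based positions; several
    columns per method are treated as replicates.  Subjects with any
    missing or non-numeric replicate on either method are dropped (the
    count is logged): the paired design requires complete pairs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    xs = _resolve_columns(df, x_cols, "x")
    ys = _resolve_columns(df, y_cols, "y")

    for col in xs + ys:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"row {row + 2} (1-based, counting the header)"
            )
        df[col] = coerced

    complete = df[xs + ys].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d subject(s) with incomplete pairs", n_dropped)
    df = df[complete]
    if df.empty:
        raise ValueError("no complete subject remains after dropping missing pairs")

    if id_col is not None:
        ids = tuple(df[_resolve_columns(df, [id_col], "id")[0]])
    else:
        ids = tuple(df.index)
    names = method_names or ("+".join(xs), "+".join(ys))
    return PairedSample(
        subject_ids=ids,
        x_values=df[xs].to_numpy(float),
        y_values=df[ys].to_numpy(float),
        method_names=names,
    )


# ---------------------------------------------------------------------------
# JSON report

@dataclass(frozen=True)
class ReportBundle:
    """Everything needed to audit one analysis run."""

    result: MDResult
    input_file: Optional[str] = None
    x_cols: Optional[list] = None
    y_cols: Optional[list] = None
    transform: str = "none"
    seed: Optional[int] = None
    plot_paths: tuple = ()


def _interval_to_dict(iv: StatInterval) -> dict:
    d = asdict(iv)
    for key in ("ci_lower_bound", "ci_upper_bound"):
        if d[key] is not None:
            d[key] = list(d[key])
    return d


def bundle_to_dict(bundle: ReportBundle) -> dict:
    r = bundle.result
    return {
        "software": {"name": "tolagree", "version": __version__},
        "input": {
            "file": bundle.input_file,
            "x_cols": bundle.x_cols,
            "y_cols": bundle.y_cols,
            "transform": bundle.transform,
            "seed": bundle.seed,
        },
        "plots": list(bundle.plot_paths),
        "result": {
            "summary": {"n": r.summary.n, "mean_diff": r.summary.mean_diff,
                        "sd_diff": r.summary.sd_diff},
            "method_names": list(r.method_names),
            "scale": r.md.scale,
            "back_transformed": r.back_transformed,
            "base": r.base,
            "normality_p": r.normality_p,
            "decision": r.decision,
            "acceptance": None if r.acceptance is None else asdict(r.acceptance),
            "intervals": {k: _interval_to_dict(iv) for k, iv in r.intervals.items()},
            "means": [float(v) for v in r.md.means],
            "diffs": [float(v) for v in r.md.diffs],
        },
    }


def write_report(bundle: ReportBundle, path) -> None:
    """Serialise an analysis to JSON; floats survive round-trip exactly."""
    Path(path).write_text(json.dumps(bundle_to_dict(bundle), indent=2))


def read_report(path) -> dict:
    """Load a report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
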