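"""File ingestion, report assembly and fixture generation.

Input is delimited text (comma, or tab autodetected) with a header row.
Rows with missing values in any of the three analysis columns are dropped
with a logged count; the outcome (and a binary mediator) must be strictly
0/1.  Reports serialize to JSON at full precision and to delimited text at
6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import BINARY, MIN_N, MediationDataset
from .effects import EffectTable, estimate_all
from .exceptions import InputError
from .simulation import generate_dataset
from .truth import Condition, condition_by_label, true_effects

log = logging.getLogger("medlogit")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep)


def median_split(values: pd.Series) -> pd.Series:
    """Dichotomize at the median; ties at the median go to the upper group."""
    med = values.median()
    return (values >= med).astype(float)


def read_dataset(
    path: str | Path,
    x_col: str,
    m_col: str,
    y_col: str,
    mediator_type: str,
    median_split_cols: tuple[str, ...] = (),
) -> MediationDataset:
    """Load a delimited file into a validated :class:`MediationDataset`.

    Raises :class:`InputError` on unknown columns, non-0/1 outcome values or
    fewer than 10 usable rows.
    """
    frame = _read_table(path)
    for col in {x_col, m_col, y_col, *median_split_cols}:
        if col not in frame.columns:
            raise InputError(
                f"column {col!r} not found in {path}; available: {list(frame.columns)}"
            )
    for col in median_split_cols:
        frame[col] = median_split(frame[col])
    sub = frame[[x_col, m_col, y_col]].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        log.warning("dropped %d row(s) with missing values in %s/%s/%s",
                    dropped, x_col, m_col, y_col)
    if len(complete) < MIN_N:
        raise InputError(f"only {len(complete)} usable rows after dropping missing; need {MIN_N}")
    y_values = np.unique(complete[y_col].to_numpy())
    bad = y_values[~np.isin(y_values, (0.0, 1.0))]
    if bad.size:
        raise InputError(f"outcome column {y_col!r} contains non-0/1 value(s): {bad.tolist()}")
    return MediationDataset(
        x=complete[x_col].to_numpy(dtype=float),
        m=complete[m_col].to_numpy(dtype=float),
        y=complete[y_col].to_numpy(dtype=float),
        mediator_type=mediator_type,
    )


@dataclass(frozen=True)
class AnalysisReport:
    """An effect table plus provenance for one analyzed file."""

    table: EffectTable
    input_path: str
    input_sha256: str
    columns: dict[str, str]
    mediator_type: str
    version: str
    timestamp: str

    def to_dict(self) -> dict:
        frame = self.table.to_frame()
        rows = []
        for rec in frame.to_dict(orient="records"):
            rec = {k: (None if pd.isna(v) else v) for k, v in rec.items()}
            for key in ("ie_product", "direct", "total"):
                rec[f"{key}_or"] = None if rec[key] is None else float(np.exp(rec[key]))
            rows.append(rec)
        return {
            "input_path": self.input_path,
            "input_sha256": self.input_sha256,
            "columns": self.columns,
            "mediator_type": self.mediator_type,
            "n": self.table.n,
            "package_version": self.version,
            "timestamp": self.timestamp,
            "scale": "log_odds (…_or columns exponentiated)",
            "effects": rows,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        frame = self.table.to_frame()
        numeric = frame.select_dtypes(include=[float]).columns
        frame[numeric] = frame[numeric].map(
            lambda v: v if pd.isna(v) else float(f"{v:.6g}")
        )
        return frame.to_csv(index=False)


def analyze(
    path: str | Path,
    x_col: str,
    m_col: str,
    y_col: str,
    mediator_type: str,
    median_split_cols: tuple[str, ...] = (),
) -> AnalysisReport:
    """End-to-end analysis of one delimited file."""
    data = read_dataset(path, x_col, m_col, y_col, mediator_type, median_split_cols)
    table = estimate_all(data)
    digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return AnalysisReport(
        table=table,
        input_path=str(path),
        input_sha256=digest,
        columns={"x": x_col, "m": m_col, "y": y_col},
        mediator_type=mediator_type,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


def make_fixtures(
    condition: str | Condition, n: int, seed: int, out_path: str | Path
) -> Path:
    """Write one simulated dataset as CSV with a JSON truth sidecar.

    The sidecar records the generating parameters and true effect values so
    end-to-end tests can compare recovered estimates against known truth.
    Returns the CSV path; the sidecar sits next to it with suffix
    ``.truth.json``.
    """
    cond = condition if isinstance(condition, Condition) else condition_by_label(condition)
    if n != cond.n:
        cond = Condition(
            mediator_type=cond.mediator_type,
            y_prevalence=cond.y_prevalence,
            m_prevalence=cond.m_prevalence,
            a=cond.a, b=cond.b, c_prime=cond.c_prime,
            var_x=cond.var_x, m_residual_sd=cond.m_residual_sd,
            n=n, reps=cond.reps,
        )
    truth = true_effects(cond)
    data = generate_dataset(cond, truth, seed)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"x": data.x, "m": data.m, "y": data.y}).to_csv(
        out_path, index=False, float_format="%.10g"
    )
    sidecar = {
        "condition": cond.label,
        "mediator_type": cond.mediator_type,
        "n": n,
        "seed": seed,
        "a_true": cond.a,
        "b_true": cond.b,
        "c_prime_true": cond.c_prime,
        "i2_true": truth.i2_true,
        "i3_true": truth.i3_true,
        "ie_true": truth.ie_true,
        "pm_true": truth.pm_true,
    }
    out_path.with_suffix(".truth.json").write_text(json.dumps(sidecar, indent=2))
    return out_path
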