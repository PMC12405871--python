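"""Readers and writers for the pipeline's tabular formats.

All tables are RFC-4180 CSV with a header row, UTF-8, locale-independent
decimal points. Unicode minus signs (U+2212) in numeric fields are
normalized to ASCII on input. Errors cite the 1-based data row and the
column name. See docs/formats.md for the column-by-column schemas.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genetic_design import DigenicGenotype
from .metrics import GerminationRecord, ImbibitionSeries
from .model_fitting import EffectEstimate, FitResult

__all__ = [
    "TableSchema",
    "SCHEMAS",
    "read_germination",
    "write_germination",
    "read_phenotypes",
    "read_imbibition",
    "write_fit_report",
    "read_fit_report",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class TableSchema:
    """Declared columns of one tabular format."""

    name: str
    required_columns: tuple[str, ...]
    optional_columns: tuple[str, ...] = ()
    version: int = SCHEMA_VERSION

    def __post_init__(self):
        if len(set(self.required_columns)) != len(self.required_columns):
            raise ValidationError(f"schema {self.name!r}: duplicate required columns")


SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in (
        TableSchema(
            "germination",
            ("sample_id", "rc_dosage", "pb_dosage", "n_total"),
            optional_columns=("d*",),
        ),
        TableSchema(
            "flavonoid",
            ("rc_dosage", "pb_dosage", "dpa", "chemical", "replicate", "value"),
            optional_columns=("detected",),
        ),
        TableSchema(
            "imbibition",
            ("sample_id", "rc_dosage", "pb_dosage", "time_h"),
            optional_columns=("weight", "wc", "w0"),
        ),
        TableSchema(
            "f2_phenotype",
            ("rc_dosage", "pb_dosage"),
            optional_columns=("sample_id", "dpa", "gp", "gi"),
        ),
        TableSchema(
            "fit_report",
            ("term", "effect", "se", "p_value", "r2", "entry_order"),
        ),
    )
}

_MINUS = str.maketrans({"−": "-"})


def _num(raw, row: int, column: str, kind=float):
    if isinstance(raw, str):
        raw = raw.strip().translate(_MINUS)
    try:
        return kind(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"cannot parse {raw!r} as {kind.__name__}", row=row, column=column
        ) from None


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise ValidationError(f"no such file: {path}")
    except Exception as exc:
        raise ValidationError(f"cannot parse {path} as CSV: {exc}")
    df.columns = [c.strip() for c in df.columns]
    return df


def _require(df: pd.DataFrame, schema: TableSchema, path):
    missing = [c for c in schema.required_columns if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {', '.join(missing)} "
            f"for schema {schema.name!r}"
        )


def _dosage(raw, row: int, column: str) -> int:
    v = _num(raw, row, column, int)
    if v not in (0, 1, 2):
        raise ValidationError(f"dosage must be 0, 1 or 2, got {v}", row=row, column=column)
    return v


def read_germination(path, counts: str = "incremental", horizon: int | None = None) -> list[GerminationRecord]:
    """Read a germination table into validated records.

    Day columns are named ``d<day>`` (e.g. ``d2..d7`` or ``d3,d5,d7``).
    ``counts="cumulative"`` differences the day columns at ingestion and
    rejects any decreasing cumulative sequence.
    """
    if counts not in ("incremental", "cumulative"):
        raise ValidationError(f"counts must be 'incremental' or 'cumulative', got {counts!r}")
    df = _read_csv(path)
    schema = SCHEMAS["germination"]
    _require(df, schema, path)
    day_cols = sorted(
        (c for c in df.columns if c.startswith("d") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not day_cols:
        raise ValidationError(f"{path}: no day columns (d2, d3, ...) found")
    schedule = tuple(int(c[1:]) for c in day_cols)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        vals = [_num(row[c], i, c, int) for c in day_cols]
        for c, v in zip(day_cols, vals):
            if v < 0:
                raise ValidationError("negative count", row=i, column=c)
        if counts == "cumulative":
            incr = np.diff([0] + vals)
            bad = np.flatnonzero(incr < 0)
            if bad.size:
                raise ValidationError(
                    "cumulative counts decrease", row=i, column=day_cols[int(bad[0])]
                )
            vals = [int(v) for v in incr]
        records.append(
            GerminationRecord(
                sample_id=str(row["sample_id"]),
                genotype=DigenicGenotype(
                    _dosage(row["rc_dosage"], i, "rc_dosage"),
                    _dosage(row["pb_dosage"], i, "pb_dosage"),
                ),
                n_total=_num(row["n_total"], i, "n_total", int),
                schedule=schedule,
                counts=tuple(vals),
                horizon=horizon if horizon is not None else max(schedule),
            )
        )
    return records


def write_germination(records: list[GerminationRecord], path) -> None:
    schedules = {r.schedule for r in records}
    if len(schedules) > 1:
        raise ValidationError("records mix counting schedules; write them separately")
    schedule = next(iter(schedules))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "rc_dosage", "pb_dosage", "n_total"] + [f"d{d}" for d in schedule])
        for r in records:
            w.writerow(
                [r.sample_id, r.genotype.rc_dosage, r.genotype.pb_dosage, r.n_total]
                + list(r.counts)
            )


def read_phenotypes(path, response: str, dpa_column: str | None = None) -> list[tuple]:
    """Read ``(genotype, time, y)`` model records from a phenotype table."""
    df = _read_csv(path)
    _require(df, SCHEMAS["f2_phenotype"], path)
    if response not in df.columns:
        raise ValidationError(f"{path}: response column {response!r} not present")
    if dpa_column is not None and dpa_column not in df.columns:
        raise ValidationError(f"{path}: time column {dpa_column!r} not present")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        gt = DigenicGenotype(
            _dosage(row["rc_dosage"], i, "rc_dosage"),
            _dosage(row["pb_dosage"], i, "pb_dosage"),
        )
        t = _num(row[dpa_column], i, dpa_column) if dpa_column else None
        records.append((gt, t, _num(row[response], i, response)))
    return records


def read_imbibition(path, kind: str = "weight") -> list[ImbibitionSeries]:
    """Read a long-format imbibition table into per-sample series.

    ``kind="weight"`` expects ``weight`` and ``w0`` columns; ``kind="wc"``
    expects a ``wc`` column (stored in the series' ``weights`` slot with a
    unit ``w0``, for use with ``fit_per_timepoint(values="wc")``).
    """
    if kind not in ("weight", "wc"):
        raise ValidationError(f"kind must be 'weight' or 'wc', got {kind!r}")
    df = _read_csv(path)
    _require(df, SCHEMAS["imbibition"], path)
    value_col = "weight" if kind == "weight" else "wc"
    if value_col not in df.columns:
        raise ValidationError(f"{path}: column {value_col!r} required for kind={kind!r}")
    if kind == "weight" and "w0" not in df.columns:
        raise ValidationError(f"{path}: column 'w0' required for kind='weight'")

    groups: dict[str, list] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        sid = str(row["sample_id"])
        groups.setdefault(sid, []).append((i, row))
    series = []
    for sid, rows in groups.items():
        rows.sort(key=lambda ir: _num(ir[1]["time_h"], ir[0], "time_h"))
        first = rows[0][1]
        i0 = rows[0][0]
        gt = DigenicGenotype(
            _dosage(first["rc_dosage"], i0, "rc_dosage"),
            _dosage(first["pb_dosage"], i0, "pb_dosage"),
        )
        times = [_num(r["time_h"], i, "time_h") for i, r in rows]
        values = [_num(r[value_col], i, value_col) for i, r in rows]
        w0 = _num(first["w0"], i0, "w0") if kind == "weight" else 1.0
        series.append(
            ImbibitionSeries(sample_id=sid, genotype=gt, w0=w0, times=times, weights=values)
        )
    return series


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float) and math.isnan(x):
        return ""
    return repr(float(x))


def _parse_opt(raw: str) -> float:
    if raw == "":
        return float("nan")
    return float(raw.translate(_MINUS))


def write_fit_report(fit: FitResult, path) -> None:
    """Write a fit as a term-per-row CSV (mu row, term rows, Total row).

    Numbers are written with full precision so a read-back reproduces the fit
    bit-exactly.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SCHEMAS["fit_report"].required_columns)
        w.writerow(["mu", _fmt(fit.mu), "", _fmt(fit.mu_p_value), "", ""])
        for e in fit.estimates:
            w.writerow(
                [
                    e.term,
                    _fmt(e.coefficient),
                    _fmt(e.standard_error),
                    _fmt(e.p_value),
                    _fmt(e.r2_increment),
                    e.entry_order,
                ]
            )
        w.writerow(
            ["Total", "", "", "", _fmt(fit.total_r2), ""]
        )
        w.writerow(["_meta", _fmt(fit.residual_variance), "", "", "", fit.n_obs])
        w.writerow(["_model", fit.model_kind, "", "", "", ""])


def read_fit_report(path) -> FitResult:
    """Read back a report written by :func:`write_fit_report`."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    header, *body = rows
    if tuple(header) != SCHEMAS["fit_report"].required_columns:
        raise ValidationError(f"{path}: not a fit report (unexpected header)")
    mu = mu_p = total_r2 = residual_variance = float("nan")
    n_obs = 0
    model_kind = ""
    estimates: list[EffectEstimate] = []
    for row in body:
        term = row[0]
        if term == "mu":
            mu, mu_p = _parse_opt(row[1]), _parse_opt(row[3])
        elif term == "Total":
            total_r2 = _parse_opt(row[4])
        elif term == "_meta":
            residual_variance = _parse_opt(row[1])
            n_obs = int(row[5])
        elif term == "_model":
            model_kind = row[1]
        else:
            estimates.append(
                EffectEstimate(
                    term=term,
                    coefficient=_parse_opt(row[1]),
                    standard_error=_parse_opt(row[2]),
                    p_value=_parse_opt(row[3]),
                    r2_increment=_parse_opt(row[4]),
                    entry_order=int(row[5]),
                )
            )
    return FitResult(
        mu=mu,
        estimates=estimates,
        total_r2=total_r2,
        residual_variance=residual_variance,
        n_obs=n_obs,
        model_kind=model_kind,
        mu_p_value=mu_p,
    )
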