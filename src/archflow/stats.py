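"""Cohort summary arithmetic: means, ranges, percent changes, Pearson r.

Published clinical tables round half away from zero on decimal values, so
column means are recomputed in exact decimal arithmetic (``decimal.Decimal``)
rather than binary floating point, which would misround values like 4.095
or 44.85. Percent changes are computed from the printed (rounded) column
means, matching the published workflow; computing them from unrounded means
is available as an option.

The correlation test is the standard Pearson r with a two-sided p-value
from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as _sps

from .cohort import PRINTED_MEANS, PatientRecord

__all__ = [
    "CorrelationResult",
    "CohortSummary",
    "ColumnSummary",
    "DegenerateInputError",
    "column_mean",
    "percent_change",
    "conservation_residual",
    "pearson_with_p",
    "cohort_report",
]


class DegenerateInputError(ValueError):
    """Raised for inputs with no variance or too few samples."""


def _dec(x: float | str) -> Decimal:
    return Decimal(str(x))


def column_mean(values: list[float], decimals: int) -> float:
    """Arithmetic mean in exact decimal arithmetic, half away from zero."""
    if not values:
        raise ValueError("cannot average an empty column")
    total = sum((_dec(v) for v in values), Decimal(0))
    mean = total / len(values)
    quantum = Decimal(1).scaleb(-decimals)
    return float(mean.quantize(quantum, rounding=ROUND_HALF_UP))


def percent_change(pre_mean: float, post_mean: float) -> int:
    """Signed integer percent change, half away from zero."""
    pre = _dec(pre_mean)
    if pre == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    change = 100 * (_dec(post_mean) - pre) / pre
    return int(change.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def conservation_residual(record: PatientRecord, phase: str) -> float:
    """|inlet - sum of outlet flows| for one patient phase, L/min."""
    flows = record.flows(phase)
    try:
        inlet = _dec(flows.pop("AAo"))
    except KeyError:
        raise KeyError(f"record {record.patient_id} has no AAo flow for phase {phase!r}")
    outlets = sum((_dec(v) for v in flows.values()), Decimal(0))
    return float(abs(inlet - outlets))


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided small-sample p-value."""

    r: float
    p: float
    n: int


def pearson_with_p(x: list[float], y: list[float]) -> CorrelationResult:
    """Pearson r and two-sided p from the t-distribution with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise DegenerateInputError(f"need matched samples with n >= 3, got {len(x)}/{len(y)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input has no defined correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if 1.0 - r * r < 1e-15:
        return CorrelationResult(r, 0.0, n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r, p, n)


@dataclass(frozen=True)
class ColumnSummary:
    """One table column: recomputed mean, range, and the printed mean."""

    mean: float
    low: float
    high: float
    printed_mean: float | None = None

    @property
    def matches_printed(self) -> bool | None:
        if self.printed_mean is None:
            return None
        return self.mean == self.printed_mean


@dataclass(frozen=True)
class CohortSummary:
    """Every published column mean/range plus the headline percent changes.

    ``columns`` maps ``<table>.<phase>.<vessel>`` (e.g. ``flow.pre.LCCA``)
    to a :class:`ColumnSummary`; ``percent_changes`` maps
    ``<table>.<vessel>`` to the integer percent change computed from the
    printed column means. ``discrepancies`` lists every column whose exactly
    recomputed mean differs from print.
    """

    columns: dict[str, ColumnSummary]
    percent_changes: dict[str, int]
    conservation_residuals: dict[str, float]
    discrepancies: list[str]


_DECIMALS = {"flow": 2, "area": 2, "velocity": 1, "pressure": 0}


def cohort_report(
    records: list[PatientRecord],
    from_printed_means: bool = True,
) -> CohortSummary:
    """Recompute the published cohort arithmetic from the patient records.

    Column means use exact decimal rounding; ranges are column extrema.
    Percent changes compare post to pre column means — printed means by
    default, unrounded decimal means when ``from_printed_means`` is False.
    """
    if len(records) != 4:
        raise ValueError(f"expected the 4-patient cohort, got {len(records)} records")

    columns: dict[str, ColumnSummary] = {}
    discrepancies: list[str] = []
    raw_means: dict[str, float] = {}

    for table in ("flow", "area", "velocity", "pressure"):
        dec = _DECIMALS[table]
        for phase in ("pre", "post"):
            printed = PRINTED_MEANS[f"{table}_{phase}"]
            for vessel in printed:
                vals = [getattr(r, f"{table}_{phase}")[vessel] for r in records]
                mean = column_mean(vals, dec)
                key = f"{table}.{phase}.{vessel}"
                columns[key] = ColumnSummary(mean, min(vals), max(vals), printed[vessel])
                raw_means[key] = float(
                    sum((_dec(v) for v in vals), Decimal(0)) / len(vals)
                )
                if mean != printed[vessel]:
                    discrepancies.append(key)

    def _basis(key: str) -> float:
        return columns[key].printed_mean if from_printed_means else raw_means[key]

    percent_changes: dict[str, int] = {}
    for table, vessels in (
        ("flow", ("AAo", "BCT", "LCCA", "DAo")),
        ("area", ("BCT", "LCCA")),
        ("velocity", ("BCT", "LCCA")),
    ):
        for vessel in vessels:
            percent_changes[f"{table}.{vessel}"] = percent_change(
                _basis(f"{table}.pre.{vessel}"), _basis(f"{table}.post.{vessel}")
            )

    residuals = {
        f"patient{r.patient_id}.{phase}": conservation_residual(r, phase)
        for r in records
        for phase in ("pre", "post")
    }
    return CohortSummary(columns, percent_changes, residuals, discrepancies)
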