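"""Bland–Altman within-subject repeatability statistics.

For a matrix of n subjects × m repeated measurements of one metric:
the within-subject standard deviation Sw (the measurement error, ME)
is the square root of the mean per-subject variance; the coefficient
of repeatability is CR = 2.77·Sw (the expected bound on the absolute
difference between two repeat measurements at 95% confidence); and the
95% confidence interval of CR is CR ± 1.96·Sw/√(2·n·(m−1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "RepeatedMeasures",
    "RepeatabilityResult",
    "within_subject_sd",
    "coefficient_of_repeatability",
    "cr_confidence_interval",
    "repeatability_result",
    "repeatability_table",
]

CR_FACTOR = 2.77
CI_Z = 1.96


@dataclass
class RepeatedMeasures:
    """n subjects × m repeats of one metric; rows with missing repeats
    are dropped with a warning."""

    values: np.ndarray
    metric_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ParameterError("repeated measures must be a 2-D matrix (subjects x repeats)")
        keep = ~np.isnan(v).any(axis=1)
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} subject(s) with missing repeats",
                          stacklevel=2)
            v = v[keep]
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ParameterError(f"need >= 2 subjects and >= 2 repeats, got {v.shape}")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class RepeatabilityResult:
    metric_name: str
    units: str
    n: int
    m: int
    mean_all: float
    sw: float
    cr: float
    ci_low: float
    ci_high: float


def within_subject_sd(data: RepeatedMeasures) -> float:
    """Sw: square root of the average per-subject sample variance."""
    var = data.values.var(axis=1, ddof=1)
    return float(np.sqrt(var.mean()))


def coefficient_of_repeatability(sw: float) -> float:
    """CR = 2.77·Sw."""
    if sw < 0:
        raise ParameterError("Sw must be nonnegative")
    return CR_FACTOR * sw


def cr_confidence_interval(sw: float, n: int, m: int) -> tuple[float, float]:
    """95% CI of CR: CR ± 1.96·Sw/√(2·n·(m−1))."""
    if n < 2 or m < 2:
        raise ParameterError(f"need n >= 2 and m >= 2, got n={n}, m={m}")
    if sw < 0:
        raise ParameterError("Sw must be nonnegative")
    cr = coefficient_of_repeatability(sw)
    half = CI_Z * sw / np.sqrt(2.0 * n * (m - 1))
    return float(cr - half), float(cr + half)


def repeatability_result(data: RepeatedMeasures) -> RepeatabilityResult:
    sw = within_subject_sd(data)
    cr = coefficient_of_repeatability(sw)
    lo, hi = cr_confidence_interval(sw, data.n, data.m)
    return RepeatabilityResult(
        metric_name=data.metric_name, units=data.units, n=data.n, m=data.m,
        mean_all=float(data.values.mean()), sw=sw, cr=cr, ci_low=lo, ci_high=hi,
    )


def repeatability_table(df: pd.DataFrame, subject_col: str = "subject",
                        metric_cols: list[str] | None = None) -> pd.DataFrame:
    """Per-metric repeatability from a long table of repeated scans.

    ``df`` has one row per scan; rows sharing ``subject_col`` are
    repeats.  Every numeric column (or ``metric_cols``) yields one row
    with Mean, ME (= Sw), CR and the 95% CI bounds.
    """
    if subject_col not in df.columns:
        raise ParameterError(f"missing subject column {subject_col!r}")
    if metric_cols is None:
        metric_cols = [c for c in df.columns
                       if c != subject_col and pd.api.types.is_numeric_dtype(df[c])]
    rows = []
    for col in metric_cols:
        wide = df.pivot_table(index=subject_col, values=col, aggfunc=list)
        m = min(len(v) for v in wide[col])
        mat = np.array([v[:m] for v in wide[col]], dtype=float)
        res = repeatability_result(RepeatedMeasures(mat, metric_name=col))
        rows.append({"metric": col, "n": res.n, "m": res.m, "mean": res.mean_all,
                     "me": res.sw, "cr": res.cr, "ci_low": res.ci_low,
                     "ci_high": res.ci_high})
    return pd.DataFrame(rows)
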