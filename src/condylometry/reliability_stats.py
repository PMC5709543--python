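"""Agreement and study-design statistics.

Covers the intraclass correlation coefficient in its two-way mixed,
single-measures, consistency form — the convention for comparing raters
who are the only raters of interest — plus the paired-design sample-size
computation from the noncentral t distribution, and the layout of
absolute-discrepancy tables (volume / VOI / segmentation, intra- and
inter-observer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (e.g. zero variance)."""


@dataclass
class RatingTable:
    """Subjects × raters/occasions measurement matrix (no missing cells)."""

    values: np.ndarray
    units: str = "mm3"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("rating table must be 2D (subjects × raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if not np.isfinite(self.values).all():
            raise ValueError("rating table must be complete (no missing cells)")

    @classmethod
    def from_csv(cls, path: str, units: str = "mm3") -> "RatingTable":
        return cls(pd.read_csv(path).to_numpy(dtype=float), units=units)


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of the subjects × raters ANOVA, no replication."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_consistency(table: RatingTable) -> float:
    """Two-way mixed, single-measures, consistency ICC — ICC(3,1).

    ``(MS_subjects − MS_error) / (MS_subjects + (k−1)·MS_error)``.
    Fixed column offsets do not lower it: consistency ignores rater bias.
    """
    x = table.values
    if np.allclose(x, x.flat[0]):
        raise UndefinedStatisticError("zero total variance: ICC is undefined")
    ms_rows, _, ms_err = _two_way_mean_squares(x)
    k = x.shape[1]
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0:
        raise UndefinedStatisticError("degenerate variance decomposition: ICC is undefined")
    return float((ms_rows - ms_err) / denom)


def icc_absolute_agreement(table: RatingTable) -> float:
    """Two-way single-measures absolute-agreement ICC — ICC(2,1), for comparison."""
    x = table.values
    if np.allclose(x, x.flat[0]):
        raise UndefinedStatisticError("zero total variance: ICC is undefined")
    n, k = x.shape
    ms_rows, ms_cols, ms_err = _two_way_mean_squares(x)
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom <= 0:
        raise UndefinedStatisticError("degenerate variance decomposition: ICC is undefined")
    return float((ms_rows - ms_err) / denom)


def icc_label(value: float) -> str:
    """Qualitative label: 'good to excellent' above 0.6."""
    if value > 0.9:
        return "excellent"
    if value > 0.6:
        return "good"
    if value > 0.4:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a paired-design power analysis (difference scale, mm^3)."""

    mean_diff: float
    sd_diff: float
    alpha: float = 0.05
    power: float = 0.95
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.sd_diff <= 0:
            raise ValueError("sd_diff must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")

    @property
    def effect_size(self) -> float:
        return self.mean_diff / self.sd_diff


def paired_t_power(n: int, d: float, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Exact power of the paired t test from the noncentral t distribution.

    ``n`` pairs, effect size ``d`` on the difference scale, noncentrality
    ``d·sqrt(n)``, ``n−1`` degrees of freedom.
    """
    if n < 2:
        return 0.0
    df = n - 1
    ncp = abs(d) * np.sqrt(n)
    if two_sided:
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    tcrit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(tcrit, df, ncp))


def paired_sample_size(spec: PowerSpec, n_max: int = 100000) -> int:
    """Smallest n ≥ 2 whose paired t test attains the target power.

    Exact integer iteration over the noncentral-t power function — no
    normal approximation.
    """
    d = spec.effect_size
    if d == 0:
        raise UndefinedStatisticError("zero effect size: no finite sample size attains the power")
    for n in range(2, n_max + 1):
        if paired_t_power(n, d, spec.alpha, spec.two_sided) >= spec.power:
            return n
    raise UndefinedStatisticError(f"no n ≤ {n_max} attains power {spec.power}")


def discrepancy_cell(pairs: list[tuple[float, float]] | np.ndarray) -> tuple[float, float]:
    """Mean and sample SD of absolute paired differences |x1 − x2|."""
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if len(arr) == 0:
        raise ValueError("empty pair list")
    d = np.abs(arr[:, 0] - arr[:, 1])
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return float(d.mean()), sd


def discrepancy_table(cells: dict[tuple[str, str], dict[str, object]]) -> pd.DataFrame:
    """Absolute-discrepancy table: rows (scanner, relation), columns
    volume (mm^3) / VOI (mm) / segmentation (mm), each mean±SD.

    ``cells`` maps ``(scanner, relation)`` — e.g. ``("CBCT", "intra")`` —
    to a dict with any of the keys ``volume_pairs`` (paired volumes,
    mm^3), ``voi_means`` (distance-to-curve means, mm) and ``seg_means``
    (post-subtraction part-comparison means, mm); the latter two are
    summarized directly (mean ± sample SD of the per-case means).
    """
    rows = []
    for (scanner, relation), data in cells.items():
        row: dict[str, object] = {"scanner": scanner, "relation": relation}
        if "volume_pairs" in data:
            m, s = discrepancy_cell(data["volume_pairs"])
            row["volume_mean_mm3"], row["volume_sd_mm3"] = m, s
        for key, prefix in (("voi_means", "voi"), ("seg_means", "seg")):
            if key in data:
                vals = np.asarray(data[key], dtype=float)
                row[f"{prefix}_mean_mm"] = float(vals.mean())
                row[f"{prefix}_sd_mm"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
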