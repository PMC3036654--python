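"""Reproducibility statistics: paired t-tests, 95% CIs, Pearson correlations.

Repeated superimpositions of the same scan pair yield one regional mean
distance per repeat per case; reproducibility is assessed by paired-sample
t-tests on the per-case differences between repeats (within a registration
zone) or between zones, with 95% confidence intervals, and by the Pearson
correlation of the regional means across repeats.  Sample SD uses n-1, so
SE = SD/sqrt(n); p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateVarianceError(ValueError):
    """All paired differences identical and zero: t and p are undefined."""


@dataclass
class PairedDifferenceRow:
    """One comparison row: mean difference with CI and two-sided p."""

    label: str
    mean: float
    sd: float
    se: float
    ci95_lower: float
    ci95_upper: float
    t_statistic: float
    df: int
    p_value: float
    n: int
    degenerate: bool = False  # sd == 0: p is a floor/undefined flag, not an estimate

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "mean": self.mean,
            "sd": self.sd,
            "se": self.se,
            "ci95_lower": self.ci95_lower,
            "ci95_upper": self.ci95_upper,
            "t": self.t_statistic,
            "df": self.df,
            "p": self.p_value,
            "n": self.n,
        }


def paired_t_from_summary(mean: float, sd: float, n: int, label: str = "") -> PairedDifferenceRow:
    """Paired t-test row from the summary statistics of the differences.

    SE = sd/sqrt(n), t = mean/SE with n-1 df, two-sided p, and the 95% CI
    mean ± t(0.975, n-1)·SE.  With sd = 0 the test is degenerate: p is
    reported as NaN when the mean is also 0, else as 0 (below machine floor),
    and the row is flagged.
    """
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    se = sd / np.sqrt(n)
    df = n - 1
    tcrit = float(sps.t.ppf(0.975, df))
    if sd == 0:
        if mean == 0:
            raise DegenerateVarianceError("all differences are exactly zero; p undefined")
        return PairedDifferenceRow(label, mean, 0.0, 0.0, mean, mean, np.inf, df, 0.0, n, True)
    t = mean / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PairedDifferenceRow(
        label, float(mean), float(sd), float(se),
        float(mean - tcrit * se), float(mean + tcrit * se), float(t), df, p, n,
    )


def paired_t_from_values(x: np.ndarray, y: np.ndarray, label: str = "") -> PairedDifferenceRow:
    """Paired t-test on d = x - y; agrees exactly with the summary form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    return paired_t_from_summary(float(d.mean()), float(np.std(d, ddof=1)), len(d), label)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; requires n >= 3 and non-constant inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateVarianceError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Study tables
# ---------------------------------------------------------------------------

#: default comparison plan: (table name, repeat A, repeat B) — first vs second
#: cranial-base repeat, fourth vs fifth (arch) repeat, and arch vs cranial base
DEFAULT_COMPARISONS = (
    ("table2_cb_repeat", "S1", "S2"),
    ("table3_zl_repeat", "S4", "S5"),
    ("table4_zone_contrast", "S4", "S1"),
)


@dataclass
class StudyTable:
    """Table-1..4 analogues plus Pearson correlations across repeats."""

    distances: pd.DataFrame  # per case × repeat × region mean abs distance
    table1: pd.DataFrame  # mean/sd/se of regional means per repeat
    comparisons: dict[str, pd.DataFrame]
    correlations: pd.DataFrame

    def write_csvs(self, out_dir) -> list[str]:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        self.table1.to_csv(out / "table1_distances.csv", index=False)
        written.append("table1_distances.csv")
        for name, frame in self.comparisons.items():
            frame.to_csv(out / f"{name}.csv", index=False)
            written.append(f"{name}.csv")
        self.correlations.to_csv(out / "correlations.csv", index=False)
        written.append("correlations.csv")
        return written


def build_study_table(
    distances: pd.DataFrame,
    comparisons: tuple[tuple[str, str, str], ...] = DEFAULT_COMPARISONS,
) -> StudyTable:
    """Aggregate per-case regional distances into study tables.

    ``distances`` has columns (case, repeat, region, mean) with one row per
    case × repeat × region: the per-case mean absolute surface distance.
    Repeats are labels like S1..S5.  Full precision is kept internally;
    rounding is presentation-only.
    """
    required = {"case", "repeat", "region", "mean"}
    if not required <= set(distances.columns):
        raise ValueError(f"distances frame needs columns {sorted(required)}")

    table1_rows = []
    for (rep, region), grp in distances.groupby(["repeat", "region"], sort=True):
        vals = grp["mean"].to_numpy()
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        table1_rows.append(
            {
                "repeat": rep,
                "region": region,
                "mean": float(vals.mean()),
                "sd": sd,
                "se": sd / np.sqrt(len(vals)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            }
        )
    table1 = pd.DataFrame(table1_rows)

    pivot = distances.pivot_table(index=["case", "region"], columns="repeat", values="mean")
    repeats = set(distances["repeat"])
    regions = [r for r in ("CB", "FH", "ZL", "ZR") if r in set(distances["region"])]

    tables: dict[str, pd.DataFrame] = {}
    for name, rep_a, rep_b in comparisons:
        if rep_a not in repeats or rep_b not in repeats:
            continue
        rows = []
        for region in regions:
            sub = pivot.xs(region, level="region")[[rep_a, rep_b]].dropna()
            if sub.shape[0] < 2:
                continue
            if set(sub.index) != set(pivot.xs(region, level="region").index):
                raise ValueError(f"mismatched case sets for {rep_a} vs {rep_b} in region {region}")
            label = f"{region}.{rep_a[1:]} - {region}.{rep_b[1:]}"
            try:
                row = paired_t_from_values(
                    sub[rep_a].to_numpy(), sub[rep_b].to_numpy(), label=label
                )
                rows.append(row.as_dict())
            except DegenerateVarianceError:
                # identical repeats: difference is exactly zero, test undefined
                rows.append(
                    {"label": label, "mean": 0.0, "sd": 0.0, "se": 0.0,
                     "ci95_lower": 0.0, "ci95_upper": 0.0, "t": np.nan,
                     "df": sub.shape[0] - 1, "p": np.nan, "n": sub.shape[0]}
                )
        tables[name] = pd.DataFrame(rows)

    corr_rows = []
    for name, rep_a, rep_b in comparisons:
        if rep_a not in repeats or rep_b not in repeats:
            continue
        for region in regions:
            sub = pivot.xs(region, level="region")[[rep_a, rep_b]].dropna()
            if sub.shape[0] < 3:
                continue
            try:
                r = pearson_r(sub[rep_a].to_numpy(), sub[rep_b].to_numpy())
            except DegenerateVarianceError:
                r = np.nan
            corr_rows.append({"comparison": f"{rep_a} vs {rep_b}", "region": region, "r": r})
    correlations = pd.DataFrame(corr_rows, columns=["comparison", "region", "r"])

    return StudyTable(distances, table1, tables, correlations)
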