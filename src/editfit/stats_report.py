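"""Test-retest statistics: within-subject CV, variance-ratio (F) tests
with confidence intervals, Bland-Altman agreement, unit-mean
normalization, and cohort report tables.

The within-subject CV uses the root-mean-square of paired scan
differences, ``s_w = sqrt(sum_i d_i^2 / (2n))``, expressed as a
percentage of the grand mean; it is invariant to global rescaling of the
estimates.  The method comparison is the classic two-sample
variance-ratio test (R's ``var.test``) applied to unit-mean-normalized
subject-level estimates, with the 95% CI ``(F/q_{0.975}, F/q_{0.025})``
from the F(df1, df2) quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "FTestResult",
    "BlandAltmanResult",
    "within_subject_cv",
    "variance_ratio_test",
    "f_ci",
    "bland_altman",
    "normalize_unit_mean",
    "cohort_stats",
]


@dataclass
class FTestResult:
    F: float
    df1: int
    df2: int
    p_two_sided: float
    ci95: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("F must be positive")
        if not self.ci95[0] < self.ci95[1]:
            raise ValueError("invalid confidence interval")


@dataclass
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def _as_pairs(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array-like")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    return arr


def within_subject_cv(pairs) -> float:
    """Within-subject coefficient of variation (percent) of test-retest
    pairs: ``100 * sqrt(sum d_i^2 / (2n)) / grand_mean``."""
    arr = _as_pairs(pairs)
    d = arr[:, 0] - arr[:, 1]
    s_w = np.sqrt(np.sum(d**2) / (2.0 * len(d)))
    gm = arr.mean()
    if gm == 0:
        raise ZeroDivisionError("grand mean is zero")
    return float(100.0 * s_w / gm)


def f_ci(F: float, df1: int, df2: int, level: float = 0.95) -> Tuple[float, float]:
    """Confidence interval for a variance ratio:
    ``(F / q_{(1+level)/2}, F / q_{(1-level)/2})`` with q from F(df1, df2)."""
    if F <= 0:
        raise ValueError("F must be positive")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a = (1.0 - level) / 2.0
    q_hi = scipy.stats.f.ppf(1.0 - a, df1, df2)
    q_lo = scipy.stats.f.ppf(a, df1, df2)
    return (float(F / q_hi), float(F / q_lo))


def variance_ratio_test(x: Sequence[float], y: Sequence[float]) -> FTestResult:
    """Two-sample variance-ratio test, ``F = s_x^2 / s_y^2`` with
    df (n_x - 1, n_y - 1); two-sided p by doubling the smaller tail."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs size >= 2")
    vy = np.var(y, ddof=1)
    if vy == 0:
        raise ZeroDivisionError("zero variance in second sample")
    F = float(np.var(x, ddof=1) / vy)
    df1, df2 = len(x) - 1, len(y) - 1
    cdf = scipy.stats.f.cdf(F, df1, df2)
    sf = scipy.stats.f.sf(F, df1, df2)
    p = float(min(1.0, 2.0 * min(cdf, sf)))
    return FTestResult(F=F, df1=df1, df2=df2, p_two_sided=p, ci95=f_ci(F, df1, df2))


def bland_altman(pairs) -> BlandAltmanResult:
    """Agreement between two scans: mean difference and 95% limits of
    agreement ``mean_diff +- 1.96 SD(diffs)``."""
    arr = _as_pairs(pairs)
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    md = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(md, md - 1.96 * sd, md + 1.96 * sd, means, diffs)


def normalize_unit_mean(values: Sequence[float]) -> np.ndarray:
    """Divide by the mean so the normalized values average exactly 1."""
    v = np.asarray(values, float)
    m = v.mean()
    if m == 0:
        raise ZeroDivisionError("zero mean")
    return v / m


_KEY = ["sequence", "metabolite", "method"]


def _pairs_by_subject(g: pd.DataFrame) -> np.ndarray:
    """(n_subjects, 2) array of scan-1/scan-2 estimates (complete pairs)."""
    wide = g.pivot_table(
        index="subject", columns="scan", values="estimate_iu", aggfunc="mean"
    )
    wide = wide.dropna()
    if wide.shape[1] < 2:
        return np.zeros((0, 2))
    return wide.iloc[:, :2].to_numpy()


def cohort_stats(table: pd.DataFrame) -> Dict[str, object]:
    """Full report from a tidy estimates table.

    ``table`` columns: subject, scan, sequence, method, metabolite,
    estimate_iu.  Returns scan-wise and pooled means/SDs, within-subject
    CVs, method-vs-method variance-ratio tests on unit-mean-normalized
    subject means, and Bland-Altman summaries.  Missing cells are reported
    in ``issues`` rather than raised.
    """
    required = {"subject", "scan", "sequence", "method", "metabolite", "estimate_iu"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")
    issues: List[str] = []

    rows1 = []
    rows2 = []
    ba_rows = []
    for key, g in table.groupby(_KEY, sort=True):
        seq, met, method = key
        rec = {"sequence": seq, "metabolite": met, "method": method}
        for scan, gs in g.groupby("scan"):
            rec[f"scan{scan}_mean"] = gs["estimate_iu"].mean()
            rec[f"scan{scan}_sd"] = gs["estimate_iu"].std(ddof=1)
        rec["total_mean"] = g["estimate_iu"].mean()
        rec["total_sd"] = g["estimate_iu"].std(ddof=1)
        rec["n_subjects"] = g["subject"].nunique()
        rows1.append(rec)

        pairs = _pairs_by_subject(g)
        if len(pairs) >= 2:
            cv = within_subject_cv(pairs)
            norm = pairs / pairs.mean()
            ba = bland_altman(norm)
            ba_rows.append(
                {
                    "sequence": seq,
                    "metabolite": met,
                    "method": method,
                    "mean_diff": ba.mean_diff,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                }
            )
        else:
            cv = np.nan
            issues.append(f"incomplete pairs for {key}")
        rows2.append(
            {"sequence": seq, "metabolite": met, "method": method, "cv_percent": cv}
        )

    ftests = []
    for (seq, met), g in table.groupby(["sequence", "metabolite"], sort=True):
        methods = sorted(g["method"].unique())
        if len(methods) != 2:
            continue
        # subject means across scans, one value per subject per method
        sub = {
            m: g[g["method"] == m]
            .groupby("subject")["estimate_iu"]
            .mean()
            .sort_index()
            for m in methods
        }
        common = sub[methods[0]].index.intersection(sub[methods[1]].index)
        if len(common) < 2:
            issues.append(f"too few subjects for F test {seq}/{met}")
            continue
        # peak-fit variance in the numerator (PEAK sorts after LCM)
        num, den = methods[1], methods[0]
        if num != "PEAK" and "PEAK" in methods:
            num, den = "PEAK", [m for m in methods if m != "PEAK"][0]
        xv = normalize_unit_mean(sub[num].loc[common].to_numpy())
        yv = normalize_unit_mean(sub[den].loc[common].to_numpy())
        try:
            ft = variance_ratio_test(xv, yv)
        except ZeroDivisionError:
            issues.append(f"zero variance in F test {seq}/{met}")
            continue
        ftests.append(
            {
                "sequence": seq,
                "metabolite": met,
                "numerator": num,
                "denominator": den,
                "F": ft.F,
                "df1": ft.df1,
                "df2": ft.df2,
                "p": ft.p_two_sided,
                "ci95_low": ft.ci95[0],
                "ci95_high": ft.ci95[1],
                "n": int(len(common)),
            }
        )

    return {
        "table1": pd.DataFrame(rows1),
        "table2": pd.DataFrame(rows2),
        "ftests": ftests,
        "bland_altman": pd.DataFrame(ba_rows),
        "issues": issues,
    }
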