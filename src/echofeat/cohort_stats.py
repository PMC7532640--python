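"""Group descriptive statistics, two-sample comparison, cohort composition.

The comparison table mirrors the conventional clinical-imaging layout: one
row per feature with benign mean +/- SD, malignant mean +/- SD, the
two-independent-samples t statistic and its two-sided p value, flagged
significant at 0.05.  No multiple-testing correction is applied (eleven
uncorrected tests at the 0.05 level).  Spicule values carrying the overflow
sentinel (perfectly smooth boundaries) are excluded per feature with the
exclusion counts reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError

#: the eleven contractual feature columns, in reporting order
FEATURE_COLUMNS = [
    "circularity", "hwr", "spicules", "coarseness_px", "indistinctness_e6",
    "lobulation", "energy", "entropy", "grey_mean", "calcifications",
    "als_deg",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def two_sample_ttest(x, y, variant: str = "pooled") -> TTestResult:
    """Two independent samples t-test (pooled Student or Welch).

    Degenerate inputs are resolved explicitly: zero variance in both
    samples gives t = 0, p = 1 for equal means and p = 0 (flagged) for
    unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("samples must be finite")
    if variant not in ("pooled", "welch"):
        raise ValidationError("variant must be 'pooled' or 'welch'")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return TTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        return TTestResult(t=math.inf if x.mean() > y.mean() else -math.inf,
                           df=df, p=0.0, degenerate=True)
    with warnings.catch_warnings():
        # near-identical samples trip scipy's precision-loss warning; the
        # zero-variance degeneracies are already resolved above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue), degenerate=False)


def _usable(values: pd.Series) -> np.ndarray:
    v = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
    return v[np.isfinite(v)]


def describe_groups(table: pd.DataFrame, group_col: str = "group",
                    features: list[str] | None = None) -> pd.DataFrame:
    """Per-feature, per-group sample mean and SD (n-1 denominator).

    Non-finite values (overflow sentinels, missing cells) are excluded and
    counted in ``n_excluded``; a group with fewer than 2 usable values for
    a feature is flagged instead of summarized.
    """
    features = features or [c for c in FEATURE_COLUMNS if c in table.columns]
    rows = []
    for feat in features:
        for group, sub in table.groupby(group_col, sort=True):
            v = _usable(sub[feat])
            row = {"feature": feat, "group": group, "n": v.size,
                   "n_excluded": len(sub) - v.size}
            if v.size >= 2:
                row.update(mean=float(v.mean()), sd=float(v.std(ddof=1)),
                           flagged=False)
            else:
                row.update(mean=np.nan, sd=np.nan, flagged=True)
            rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(table: pd.DataFrame, group_col: str = "group",
                   variant: str = "pooled",
                   features: list[str] | None = None) -> pd.DataFrame:
    """One comparison row per feature: means +/- SD, t, df, p, significance."""
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    if "benign" in groups and "malignant" in groups:
        g1, g2 = "benign", "malignant"
    else:
        g1, g2 = groups
    features = features or [c for c in FEATURE_COLUMNS if c in table.columns]
    rows = []
    for feat in features:
        x = _usable(table.loc[table[group_col] == g1, feat])
        y = _usable(table.loc[table[group_col] == g2, feat])
        row = {"feature": feat,
               f"{g1}_n": x.size, f"{g2}_n": y.size,
               "n_excluded": int(len(table) - x.size - y.size)}
        if x.size < 2 or y.size < 2:
            row.update({f"{g1}_mean": np.nan, f"{g1}_sd": np.nan,
                        f"{g2}_mean": np.nan, f"{g2}_sd": np.nan,
                        "t": np.nan, "df": np.nan, "p": np.nan,
                        "significant": False, "flagged": True})
        else:
            res = two_sample_ttest(x, y, variant=variant)
            row.update({f"{g1}_mean": float(x.mean()), f"{g1}_sd": float(x.std(ddof=1)),
                        f"{g2}_mean": float(y.mean()), f"{g2}_sd": float(y.std(ddof=1)),
                        "t": res.t, "df": res.df, "p": res.p,
                        "significant": bool(res.p < ALPHA),
                        "flagged": res.degenerate})
        rows.append(row)
    return pd.DataFrame(rows)


def load_pathology_counts() -> pd.DataFrame:
    """The packaged benign/malignant pathology-type count table."""
    with resources.files("echofeat.data").joinpath("pathology_counts.csv").open() as fh:
        return pd.read_csv(fh)


def _round_half_even(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def summarize_pathology(counts: pd.DataFrame) -> dict:
    """Within-group percentages (one decimal, ties to even) and totals."""
    required = {"group", "pathology", "count"}
    if not required.issubset(counts.columns):
        raise ValidationError(f"counts table needs columns {sorted(required)}")
    if (counts["count"] <= 0).any():
        raise ValidationError("counts must be positive integers")
    summary_rows = []
    group_totals = {}
    for group, sub in counts.groupby("group", sort=True):
        total = int(sub["count"].sum())
        if total == 0:
            raise ValidationError(f"empty group {group!r}")
        group_totals[group] = total
        for _, rec in sub.iterrows():
            pct = Decimal(100 * int(rec["count"])) / Decimal(total)
            summary_rows.append({
                "group": group, "pathology": rec["pathology"],
                "n": int(rec["count"]), "percent": _round_half_even(pct),
            })
    return {
        "table": pd.DataFrame(summary_rows),
        "group_totals": group_totals,
        "overall_total": int(sum(group_totals.values())),
    }
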