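"""Comparative statistics: rank tests between conditions or speed classes,
rate/m6A correlations, and per-class summaries.

Everything is two-sided by default; no multiple-testing correction is applied
(a Benjamini-Hochberg helper is provided but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ComparisonResult:
    test_name: str
    groups: tuple[str, str] | tuple[str]
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    effect_summary: dict = field(default_factory=dict)


def _clean(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    return a[np.isfinite(a)]


def compare_groups(
    values_a,
    values_b,
    paired: bool = False,
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided Mann-Whitney (unpaired) or Wilcoxon signed-rank (paired).

    Exact p-values are used where scipy's automatic policy allows (small n
    without ties), otherwise the normal approximation with tie correction.
    Identical samples are degenerate and report p = 1 by convention.
    """
    if paired:
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length vectors")
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
    else:
        a, b = _clean(values_a), _clean(values_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if paired:
        diffs = a - b
        if np.all(diffs == 0):
            return ComparisonResult(
                "wilcoxon_paired", labels, 0.0, 1.0, (len(a), len(b)),
                {"median_a": float(np.median(a)), "median_b": float(np.median(b))},
            )
        res = sps.wilcoxon(a, b, alternative="two-sided")
        name = "wilcoxon_paired"
    else:
        if len(np.unique(np.concatenate([a, b]))) == 1:
            return ComparisonResult(
                "mann_whitney", labels, float(len(a) * len(b) / 2), 1.0,
                (len(a), len(b)),
                {"median_a": float(np.median(a)), "median_b": float(np.median(b))},
            )
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    return ComparisonResult(
        name,
        labels,
        float(res.statistic),
        float(res.pvalue),
        (len(a), len(b)),
        {"median_a": float(np.median(a)), "median_b": float(np.median(b))},
    )


def one_sample_wilcoxon(values, mu: float = 0.0) -> ComparisonResult:
    """One-sample Wilcoxon signed-rank test against ``mu`` (two-sided)."""
    a = _clean(values)
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    d = a - mu
    if np.all(d == 0):
        return ComparisonResult(
            "one_sample_wilcoxon", ("values",), 0.0, 1.0, (len(a),),
            {"median": float(np.median(a))},
        )
    res = sps.wilcoxon(d, alternative="two-sided")
    return ComparisonResult(
        "one_sample_wilcoxon", ("values",), float(res.statistic),
        float(res.pvalue), (len(a),), {"median": float(np.median(a))},
    )


def correlate(x, y, method: str = "spearman") -> ComparisonResult:
    """Spearman's rho or Pearson's r with a two-sided p-value.

    Only pairwise-complete observations enter; zero-variance input yields an
    undefined (NaN) coefficient with a flag in the effect summary.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if len(a) != len(b):
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return ComparisonResult(
            method, ("x", "y"), float("nan"), float("nan"), (len(a), len(a)),
            {"coefficient": float("nan"), "zero_variance": True},
        )
    if method == "spearman":
        coef, p = sps.spearmanr(a, b)
    else:
        coef, p = sps.pearsonr(a, b)
    return ComparisonResult(
        method, ("x", "y"), float(coef), float(p), (len(a), len(a)),
        {"coefficient": float(coef), "zero_variance": False},
    )


def summarize_by_class(
    table: pd.DataFrame,
    value_col: str,
    by: Sequence[str] = ("speed_class", "condition"),
) -> pd.DataFrame:
    """Tidy median/mean/sd/n per grouping cell, deterministically ordered.

    Single-observation cells report sd = 0 with ``sd_undefined = True``;
    empty cells appear with n = 0.
    """
    by = list(by)
    rows = []
    groups = table.groupby(by, sort=True, dropna=False)
    for key, sub in groups:
        key = key if isinstance(key, tuple) else (key,)
        vals = _clean(sub[value_col])
        n = len(vals)
        rows.append(
            {
                **dict(zip(by, key)),
                "measurement": value_col,
                "n": n,
                "median": float(np.median(vals)) if n else float("nan"),
                "mean": float(np.mean(vals)) if n else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if n > 1 else 0.0,
                "sd_undefined": n < 2,
            }
        )
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are the default output)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
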