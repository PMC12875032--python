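"""Cohort demographics, group-comparison tests and the pairwise association map.

Continuous variables are summarized as median (IQR) and compared with
Mann-Whitney U (two groups) or Kruskal-Wallis (more); categorical
variables as n (%) compared with Pearson chi-square.  The pairwise
association map tests every unordered variable pair with the test that
fits its type combination and tiers results into non-significant,
raw p < alpha, and BH-FDR < alpha.  A plain column-centered-SVD PCA
embedding is provided for the cohort scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import floor

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AbundanceMatrix, SampleRecord, records_to_frame
from .de import benjamini_hochberg

__all__ = [
    "SummaryRow",
    "summarize_continuous",
    "percent_of",
    "mann_whitney",
    "chi_square",
    "summarize_cohort",
    "association_matrix",
    "pca_embedding",
]


class DegenerateDataWarning(UserWarning):
    pass


@dataclass
class SummaryRow:
    variable: str
    kind: str  # continuous | categorical
    level: str | None
    median: float | None
    q1: float | None
    q3: float | None
    count: int | None
    percent: int | None
    statistic_name: str
    p: float

    def __post_init__(self) -> None:
        if self.kind == "continuous" and self.median is not None:
            if not (self.q1 <= self.median <= self.q3):
                raise ValueError(f"{self.variable}: IQR bounds must bracket the median")


def summarize_continuous(values) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("summarize_continuous needs at least one finite value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def percent_of(count: int, total: int) -> int:
    """Integer percentage, rounded half-up (15 of 23 -> 65)."""
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if not 0 <= count <= total:
        raise ValueError(f"count must be in [0, total], got {count} of {total}")
    return int(floor(100.0 * count / total + 0.5))


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p.

    Exact null distribution for combined n <= 20 without ties; normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical across both groups", DegenerateDataWarning)
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square on an r x k count table, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or (tab < 0).any() or not np.allclose(tab, np.rint(tab)):
        raise ValueError("table must be a 2-D array of non-negative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("chi-square is undefined with a zero marginal row/column")
    res = stats.chi2_contingency(tab, correction=False)
    expected = res.expected_freq
    if (expected < 5).any():
        warnings.warn("chi-square expected count < 5 in at least one cell", DegenerateDataWarning)
    return float(res.statistic), float(res.pvalue)


_CATEGORICAL_MAX_LEVELS = 5


def _variable_kind(series: pd.Series) -> str:
    vals = series.dropna()
    if vals.empty:
        return "categorical"
    if not pd.api.types.is_numeric_dtype(vals):
        return "categorical"
    return "categorical" if vals.nunique() <= 2 else "continuous"


def summarize_cohort(
    records: list[SampleRecord],
    variables: list[str] | None = None,
    group_col: str = "group",
) -> list[SummaryRow]:
    """Per-variable median (IQR) or n (%) with a between-group test.

    Uses one row per subject (the first sample encountered) so paired D1/D3
    samples do not double-count subjects.
    """
    df = records_to_frame(records)
    df = df.loc[~df["subject_id"].duplicated()]
    if variables is None:
        variables = [c for c in df.columns if c not in ("subject_id", "timepoint", group_col)]
    groups = [g for g, _ in df.groupby(group_col, sort=True)]
    rows: list[SummaryRow] = []
    for var in variables:
        if var not in df.columns:
            raise KeyError(f"variable {var!r} not in metadata")
        series = df[var]
        kind = _variable_kind(series)
        if kind == "continuous":
            per_group = [pd.to_numeric(df.loc[df[group_col] == g, var], errors="coerce").dropna() for g in groups]
            per_group = [g for g in per_group if len(g) > 0]
            med, q1, q3 = summarize_continuous(pd.to_numeric(series, errors="coerce").dropna())
            if len(per_group) >= 2:
                if len(per_group) == 2:
                    _, p = mann_whitney(per_group[0], per_group[1])
                    stat_name = "mann_whitney"
                else:
                    p = float(stats.kruskal(*per_group).pvalue)
                    stat_name = "kruskal_wallis"
            else:
                p, stat_name = float("nan"), "none"
            rows.append(SummaryRow(var, "continuous", None, med, q1, q3, None, None, stat_name, p))
        else:
            sub = df[[group_col, var]].dropna()
            levels = sorted(sub[var].astype(str).unique())
            tab = pd.crosstab(sub[group_col], sub[var].astype(str))
            try:
                _, p = chi_square(tab.to_numpy())
                stat_name = "chi_square"
            except ValueError:
                p, stat_name = float("nan"), "none"
            total = len(sub)
            for lev in levels:
                n = int((sub[var].astype(str) == lev).sum())
                rows.append(
                    SummaryRow(var, "categorical", lev, None, None, None, n,
                               percent_of(n, total) if total else None, stat_name, p)
                )
    return rows


def _pair_test(x: pd.Series, y: pd.Series) -> tuple[str, float]:
    pair = pd.concat([x, y], axis=1, keys=["x", "y"]).dropna()
    if len(pair) < 3:
        raise ValueError("need >=3 complete pairs")
    kx, ky = _variable_kind(pair["x"]), _variable_kind(pair["y"])
    if kx == "continuous" and ky == "continuous":
        xv = pair["x"].astype(float).to_numpy()
        yv = pair["y"].astype(float).to_numpy()
        if np.unique(xv).size == 1 or np.unique(yv).size == 1:
            raise ValueError("constant variable")
        return "pearson", float(stats.pearsonr(xv, yv).pvalue)
    if kx == "categorical" and ky == "categorical":
        tab = pd.crosstab(pair["x"].astype(str), pair["y"].astype(str))
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            raise ValueError("constant variable")
        return "chi_square", chi_square(tab.to_numpy())[1]
    cat, cont = ("x", "y") if kx == "categorical" else ("y", "x")
    groups = [
        pd.to_numeric(g, errors="coerce").dropna().to_numpy()
        for _, g in pair.groupby(pair[cat].astype(str))[cont]
    ]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("constant variable")
    if len(groups) == 2:
        return "mann_whitney", mann_whitney(groups[0], groups[1])[1]
    return "kruskal_wallis", float(stats.kruskal(*groups).pvalue)


def association_matrix(
    records: list[SampleRecord],
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tiered pairwise association table over clinical variables.

    Returns one row per unordered pair with the test used, raw p, BH-FDR
    adjusted p (over the whole pairwise family) and tier in
    {"ns", "p<alpha", "fdr<alpha"}.
    """
    df = records_to_frame(records)
    df = df.loc[~df["subject_id"].duplicated()]
    if variables is None:
        variables = [c for c in df.columns if c not in ("subject_id", "timepoint")]
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    rows = []
    for va, vb in combinations(variables, 2):
        try:
            test, p = _pair_test(df[va], df[vb])
        except ValueError as exc:
            warnings.warn(f"pair ({va}, {vb}): {exc}; tier set to ns", DegenerateDataWarning)
            test, p = "none", np.nan
        rows.append({"var_a": va, "var_b": vb, "test": test, "p": p})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    tier = np.where(out["p_adj"] < alpha, "fdr<alpha", np.where(out["p"] < alpha, "p<alpha", "ns"))
    tier = np.where(out["p"].isna(), "ns", tier)
    out["tier"] = tier
    return out


def pca_embedding(matrix: AbundanceMatrix, k: int = 2) -> pd.DataFrame:
    """First k principal-component scores of the column-centered matrix.

    Component signs are fixed so each component's largest-magnitude
    loading is positive, making the embedding reproducible.
    """
    x = matrix.data.to_numpy(dtype=float)
    if np.isnan(x).any():
        x = np.where(np.isnan(x), np.nanmean(x, axis=0), x)
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 samples and 2 proteins")
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n_samples, n_proteins)={min(n, p)}")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=matrix.data.index, columns=[f"PC{j + 1}" for j in range(k)]
    )
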