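"""Protein-wise correlation with clinical outcomes.

Severity (PELOD-2, continuous) uses Pearson correlation per timepoint:
D1 protein values against D1 scores, D3 against D3.  Mortality (0/1)
uses the point-biserial correlation, which is numerically the Pearson
correlation with the binary outcome coded 0/1.  Within each
(variable, timepoint) panel, p-values are BH-adjusted over the protein
family; panels are never pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import benjamini_hochberg
from .io_formats import AbundanceMatrix, SampleRecord, records_to_frame

__all__ = ["AssociationRecord", "pearson", "point_biserial", "correlate_panel"]


@dataclass
class AssociationRecord:
    protein_id: str
    variable: str
    method: str  # pearson | point_biserial
    rho: float
    n: int
    p: float
    p_adj: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"{self.protein_id}: |rho| must be <= 1")
        if self.n < 3:
            raise ValueError(f"{self.protein_id}: n must be >= 3")


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson needs n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def point_biserial(x, g) -> tuple[float, float]:
    """Correlation between a continuous variable and a 0/1-coded outcome.

    Identical to ``pearson`` with the labels coded numerically.
    """
    g = np.asarray(g, dtype=float)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"point-biserial needs exactly two classes, got {labels.tolist()}")
    return pearson(x, g)


def correlate_panel(
    matrix: AbundanceMatrix,
    records: list[SampleRecord],
    variable: str,
    method: str = "pearson",
    group: str = "SEPSIS",
    timepoint: str | None = None,
) -> pd.DataFrame:
    """One association record per (non-constant) protein for one clinical variable.

    Samples are filtered to ``group``/``timepoint`` and, per protein,
    reduced to pairwise-complete observations.  BH adjustment runs over
    the proteins of this panel only.
    """
    if method not in ("pearson", "point_biserial"):
        raise ValueError(f"unknown method {method!r}")
    meta = records_to_frame(records)
    if variable not in meta.columns:
        raise KeyError(f"variable {variable!r} not in metadata")
    sel = meta["group"] == group
    if timepoint is not None:
        sel &= meta["timepoint"] == timepoint
    meta = meta.loc[sel]
    sids = [s for s in meta.index if s in matrix.data.index]
    if len(sids) < 3:
        raise ValueError("need >=3 samples after filtering")
    values = matrix.values_for(sids)
    yv = pd.to_numeric(meta.loc[sids, variable], errors="coerce").to_numpy()

    rows = []
    skipped = []
    for pid in matrix.protein_ids:
        xv = values[pid].to_numpy(dtype=float)
        keep = np.isfinite(xv) & np.isfinite(yv)
        if keep.sum() < 3:
            skipped.append(pid)
            continue
        xk, yk = xv[keep], yv[keep]
        try:
            if method == "pearson":
                rho, p = pearson(xk, yk)
            else:
                rho, p = point_biserial(xk, yk)
        except ValueError:
            skipped.append(pid)
            continue
        rows.append({"protein_id": pid, "rho": rho, "n": int(keep.sum()), "p": p})
    if skipped:
        warnings.warn(f"skipped {len(skipped)} constant/unusable proteins: {skipped[:5]}...")
    if not rows:
        raise ValueError("no usable proteins in panel")
    out = pd.DataFrame(rows).set_index("protein_id")
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    out.insert(0, "method", method)
    out.insert(0, "variable", variable)
    return out
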