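"""Empirical-Bayes moderated-t differential expression.

The model is the standard hierarchical one: per-protein residual
variances s_g^2 (on d residual degrees of freedom) are assumed drawn
from a scaled inverse-chi-square prior with d0 degrees of freedom and
scale s0^2.  The posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

replaces s_g^2 in the t statistic, which is then referred to a
t-distribution on d0 + d degrees of freedom.  The prior is estimated by
matching the empirical mean and variance of log s_g^2 to the theoretical
digamma/trigamma moments of the prior (moment estimation on the log
scale); when the observed dispersion of log-variances is no larger than
the sampling dispersion, d0 is infinite and all variances shrink
completely to s0^2.

A protein is called differentially expressed when its BH-adjusted p is
<= alpha and its linear fold change is >= fc_min in magnitude
(|log2FC| >= log2(fc_min)); both boundaries inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AbundanceMatrix, SampleRecord

__all__ = [
    "UnpairedContrast",
    "PairedContrast",
    "EBayesParams",
    "fit_contrast",
    "estimate_ebayes_prior",
    "moderated_t",
    "benjamini_hochberg",
    "call_deps",
    "signed_fold_change",
    "run_de",
]


@dataclass(frozen=True)
class UnpairedContrast:
    """Mean(group A) - mean(group B) on independent samples.

    Each side is selected by (group, timepoint); timepoint None matches any.
    """

    group_a: str
    timepoint_a: str | None
    group_b: str
    timepoint_b: str | None

    def label(self) -> str:
        a = self.group_a if self.timepoint_a is None else f"{self.group_a}_{self.timepoint_a}"
        b = self.group_b if self.timepoint_b is None else f"{self.group_b}_{self.timepoint_b}"
        return f"{a}_vs_{b}"


@dataclass(frozen=True)
class PairedContrast:
    """Within-subject difference timepoint A - timepoint B (one-sample test)."""

    timepoint_a: str
    timepoint_b: str
    group: str = "SEPSIS"

    def label(self) -> str:
        return f"{self.group}_{self.timepoint_a}_vs_{self.timepoint_b}_paired"


@dataclass(frozen=True)
class EBayesParams:
    """Inverse-chi-square prior on residual variances: d0 df, scale s0sq."""

    d0: float  # may be math.inf; 0 is the explicit no-shrinkage limit
    s0sq: float

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValueError(f"d0 must be non-negative (possibly inf), got {self.d0}")
        if not self.s0sq > 0:
            raise ValueError(f"s0sq must be positive, got {self.s0sq}")


def _select(records: list[SampleRecord], group: str, timepoint: str | None) -> list[SampleRecord]:
    return [
        r for r in records
        if r.group == group and (timepoint is None or r.timepoint == timepoint)
    ]


def fit_contrast(
    matrix: AbundanceMatrix,
    records: list[SampleRecord],
    contrast: UnpairedContrast | PairedContrast,
) -> pd.DataFrame:
    """Per-protein effect, residual variance, residual df and unscaled variance.

    Returns a DataFrame indexed by protein id with columns
    ``beta`` (effect), ``s2`` (residual variance), ``df`` (residual
    degrees of freedom) and ``v`` (variance of beta in units of s2).
    """
    if isinstance(contrast, UnpairedContrast):
        recs_a = _select(records, contrast.group_a, contrast.timepoint_a)
        recs_b = _select(records, contrast.group_b, contrast.timepoint_b)
        na, nb = len(recs_a), len(recs_b)
        if na < 2 or nb < 2:
            raise ValueError(f"unpaired contrast needs >=2 samples per arm, got {na} and {nb}")
        xa = matrix.values_for([r.sample_id for r in recs_a]).to_numpy()
        xb = matrix.values_for([r.sample_id for r in recs_b]).to_numpy()
        beta = xa.mean(axis=0) - xb.mean(axis=0)
        ssq = xa.var(axis=0, ddof=1) * (na - 1) + xb.var(axis=0, ddof=1) * (nb - 1)
        df = na + nb - 2
        s2 = ssq / df
        v = 1.0 / na + 1.0 / nb
    else:
        recs_a = _select(records, contrast.group, contrast.timepoint_a)
        recs_b = _select(records, contrast.group, contrast.timepoint_b)
        by_subj_a = {r.subject_id: r.sample_id for r in recs_a}
        by_subj_b = {r.subject_id: r.sample_id for r in recs_b}
        orphans = sorted(set(by_subj_a) ^ set(by_subj_b))
        if orphans:
            raise ValueError(f"paired contrast has unmatched subjects: {orphans}")
        subjects = sorted(by_subj_a)
        if len(subjects) < 2:
            raise ValueError(f"paired contrast needs >=2 complete pairs, got {len(subjects)}")
        xa = matrix.values_for([by_subj_a[s] for s in subjects]).to_numpy()
        xb = matrix.values_for([by_subj_b[s] for s in subjects]).to_numpy()
        diff = xa - xb
        n = len(subjects)
        beta = diff.mean(axis=0)
        s2 = diff.var(axis=0, ddof=1)
        df = n - 1
        v = 1.0 / n
    return pd.DataFrame(
        {"beta": beta, "s2": s2, "df": float(df), "v": float(v)},
        index=pd.Index(matrix.protein_ids, name="protein_id"),
    )


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs a positive target")
    # Newton on x with the standard well-conditioned update.
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_ebayes_prior(s2, d: float) -> EBayesParams:
    """Moment-match the inverse-chi-square prior from observed variances.

    Works on z = log(s2): under the model, Var(z) = trigamma(d/2) +
    trigamma(d0/2) and E[z] = log(s0^2) + digamma(d/2) - log(d/2)
    - (digamma(d0/2) - log(d0/2)).  Proteins with s2 == 0 are excluded
    (logged); if the trigamma equation has no positive solution the prior
    is degenerate (d0 = inf, complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} proteins with zero residual variance excluded from prior estimation")
    s2 = s2[ok]
    if s2.size < 2:
        raise ValueError("prior estimation needs >=2 proteins with positive residual variance")
    z = np.log(s2)
    zbar = float(z.mean())
    zvar = float(z.var(ddof=1))
    excess = zvar - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        d0 = math.inf
        log_s0sq = zbar - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0sq = (
            zbar
            - float(special.digamma(d / 2.0))
            + math.log(d / 2.0)
            + float(special.digamma(d0 / 2.0))
            - math.log(d0 / 2.0)
        )
    return EBayesParams(d0=d0, s0sq=float(np.exp(log_s0sq)))


def moderated_t(beta, s2, d: float, v: float, prior: EBayesParams):
    """Moderated t statistic, total df and two-sided p.

    Vectorized over proteins.  d0 = 0 is accepted as the no-shrinkage
    limit (ordinary t); d0 = inf gives the fixed-variance z-form.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    s2 = np.atleast_1d(np.asarray(s2, dtype=float))
    d0, s0sq = prior.d0, prior.s0sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2_post * v)
    zero_var = s2_post == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} proteins with zero posterior variance; p set to 0")
        t = np.where(zero_var, np.where(beta >= 0, np.inf, -np.inf), t)
        t = np.where(zero_var & (beta == 0), 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(zero_var & (beta != 0), 0.0, p)
    p = np.where(np.isnan(t), np.nan, np.minimum(p, 1.0))
    p = np.where((t == 0), 1.0, p)
    return t, df_total, p


def ordinary_t(beta, s2, d: float, v: float):
    """Ordinary (unmoderated) t statistic and two-sided p on d df."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    s2 = np.atleast_1d(np.asarray(s2, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2 * v)
    p = np.minimum(2.0 * stats.t.sf(np.abs(t), d), 1.0)
    return t, float(d), p


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(log2fc: float) -> float:
    """Linear fold change with the sign convention of down-regulation.

    2^log2fc for log2fc >= 0, else -2^(-log2fc): a halving is reported
    as -2, never 0.5, so |signed FC| >= 1 always.
    """
    lf = float(log2fc)
    if not math.isfinite(lf):
        raise ValueError("log2fc must be finite")
    return 2.0 ** lf if lf >= 0 else -(2.0 ** (-lf))


def call_deps(table: pd.DataFrame, fc_min: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
    """Label proteins up/down/ns from log2fc and adjusted p, boundaries inclusive."""
    if "p_adj" not in table.columns:
        raise ValueError("call_deps needs a p_adj column")
    lfc_min = math.log2(fc_min)
    out = table.copy()
    sig = out["p_adj"] <= alpha
    out["status"] = np.where(
        sig & (out["log2fc"] >= lfc_min), "up",
        np.where(sig & (out["log2fc"] <= -lfc_min), "down", "ns"),
    )
    return out


def run_de(
    matrix: AbundanceMatrix,
    records: list[SampleRecord],
    contrast: UnpairedContrast | PairedContrast,
    fc_min: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full moderated-t differential expression for one contrast.

    Returns a DataFrame sorted by adjusted p with columns log2fc,
    signed_fc, t, df, p, p_adj, status.
    """
    fit = fit_contrast(matrix, records, contrast)
    d = float(fit["df"].iloc[0])
    v = float(fit["v"].iloc[0])
    prior = estimate_ebayes_prior(fit["s2"].to_numpy(), d)
    t, df_total, p = moderated_t(fit["beta"].to_numpy(), fit["s2"].to_numpy(), d, v, prior)
    out = pd.DataFrame(
        {
            "log2fc": fit["beta"],
            "signed_fc": [signed_fold_change(b) for b in fit["beta"]],
            "t": t,
            "df": df_total,
            "p": p,
            "p_adj": benjamini_hochberg(p),
        },
        index=fit.index,
    )
    out = call_deps(out, fc_min=fc_min, alpha=alpha)
    return out.sort_values(["p_adj", "p", "protein_id"], kind="mergesort")
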