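"""Hypergeometric over-representation analysis of DEP lists.

For a hit list of n proteins from a measured universe of N, a term
annotating K universe proteins, and an observed overlap of k, the
enrichment p-value is the hypergeometric upper tail P(X >= k)
(one-sided over-representation), the effect size is the cross-product
odds ratio of the 2x2 overlap table, and the direction statistic is
z = (U - D) / sqrt(U + D) over the overlap members' log2 fold-change
signs.  P-values are BH-adjusted over the tested terms.

The default background is the measured panel itself rather than a
whole-genome universe: for a targeted assay, proteins outside the panel
were never at risk of being hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import benjamini_hochberg
from .io_formats import GeneSetCollection

__all__ = ["EnrichmentRecord", "hypergeom_upper", "odds_ratio", "direction_z", "enrich"]


@dataclass
class EnrichmentRecord:
    term_id: str
    k: int  # overlap hits in term
    K: int  # term size within universe
    n: int  # hit-list size within universe
    N: int  # universe size
    odds_ratio: float
    z_score: float
    p: float
    fdr: float
    direction: str  # up | down | mixed
    hit_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError(f"{self.term_id}: k exceeds min(K, n)")
        if self.fdr < self.p - 1e-12:
            raise ValueError(f"{self.term_id}: fdr below raw p")


def _validate_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N and N >= 0):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if N - K - n + k < 0:
        raise ValueError(f"inconsistent counts (negative complement cell): k={k}, K={K}, n={n}, N={N}")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    _validate_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def odds_ratio(k: int, K: int, n: int, N: int) -> float:
    """Cross-product ratio of the 2x2 overlap table.

    Zero-cell policy: 0 when k = 0; +inf when k > 0 and either
    complement cell (K - k or n - k) is zero.
    """
    _validate_counts(k, K, n, N)
    if k == 0:
        return 0.0
    a, b, c, d = k, K - k, n - k, N - K - n + k
    if b == 0 or c == 0:
        return float("inf")
    return (a * d) / (b * c)


def direction_z(member_log2fcs) -> tuple[float, str]:
    """Direction statistic over the overlap members' fold-change signs.

    z = (U - D)/sqrt(U + D) with U/D the up/down counts; members with
    log2FC exactly zero count in neither tally (warned).  Direction is
    "up"/"down" only when unanimous.
    """
    lfc = np.asarray(member_log2fcs, dtype=float)
    if lfc.size == 0:
        raise ValueError("direction_z needs at least one member")
    zeros = int((lfc == 0).sum())
    if zeros:
        warnings.warn(f"{zeros} members with log2fc == 0 counted in neither direction")
    up = int((lfc > 0).sum())
    down = int((lfc < 0).sum())
    total = up + down
    z = 0.0 if total == 0 else (up - down) / np.sqrt(total)
    if total > 0 and down == 0:
        direction = "up"
    elif total > 0 and up == 0:
        direction = "down"
    else:
        direction = "mixed"
    return float(z), direction


def enrich(
    collection: GeneSetCollection,
    hits,
    universe,
    de_table: pd.DataFrame | None = None,
    min_term_size: int = 2,
) -> list[EnrichmentRecord]:
    """Over-representation of ``hits`` within each term of ``collection``.

    Terms are intersected with ``universe`` before counting and tested
    only when min_term_size <= K <= N - min_term_size (degenerate terms
    carry no information).  ``de_table`` (indexed by protein id with a
    ``log2fc`` column) feeds the direction statistic; without it every
    record is direction "mixed" with z = 0.  Records come back sorted by
    p (ties by term id).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits)
    if not hits <= universe:
        raise ValueError(f"hits outside universe: {sorted(hits - universe)[:5]}")
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    N, n = len(universe), len(hits)
    lfc = de_table["log2fc"] if de_table is not None else None

    rows = []
    for term_id, _desc, members in collection.terms:
        in_univ = [m for m in members if m in universe]
        K = len(in_univ)
        if K < min_term_size or K > N - min_term_size:
            continue
        overlap = [m for m in in_univ if m in hits]
        k = len(overlap)
        if lfc is not None and k > 0:
            z, direction = direction_z([float(lfc.get(m, 0.0)) for m in overlap])
        else:
            z, direction = 0.0, "mixed"
        rows.append(
            (term_id, k, K, hypergeom_upper(k, K, n, N), odds_ratio(k, K, n, N), z, direction, overlap)
        )
    if not rows:
        return []
    fdr = benjamini_hochberg([r[3] for r in rows])
    records = [
        EnrichmentRecord(
            term_id=tid, k=k, K=K, n=n, N=N, odds_ratio=orat, z_score=z,
            p=p, fdr=float(q), direction=direction, hit_members=overlap,
        )
        for (tid, k, K, p, orat, z, direction, overlap), q in zip(rows, fdr)
    ]
    records.sort(key=lambda r: (r.p, r.term_id))
    return records


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Flatten enrichment records into the result-table layout."""
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "k": [r.k for r in records],
            "K": [r.K for r in records],
            "n": [r.n for r in records],
            "N": [r.N for r in records],
            "odds_ratio": [r.odds_ratio for r in records],
            "z_score": [r.z_score for r in records],
            "p": [r.p for r in records],
            "fdr": [r.fdr for r in records],
            "direction": [r.direction for r in records],
            "hit_members": ["|".join(r.hit_members) for r in records],
        }
    ).set_index("term_id")
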