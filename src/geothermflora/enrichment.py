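"""Hypergeometric over-/under-representation of taxa within a species group.

For a species pool of size ``N`` containing ``K`` members of a taxon, and a
group of ``n`` species of which ``k`` belong to the taxon, the probability of
observing exactly ``k`` taxon members by chance is hypergeometric,

    p(k) = C(K, k) * C(N - K, n - k) / C(N, n),

and the one-sided representation probabilities are the inclusive tails

    P_over  = sum of p(i) for i in [k, min(K, n)],
    P_under = sum of p(i) for i in [0, k].

Both tails include the observed count, so P_over + P_under = 1 + p(k).
Taxa with P_over <= alpha are called over-represented and taxa with
P_under <= alpha under-represented; Benjamini-Hochberg q-values across the
taxa of a rank are reported alongside the raw calls.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hypergeom_pmf",
    "p_over",
    "p_under",
    "enrich_table",
    "merge_status_sources",
]

logger = logging.getLogger(__name__)

RANKS = ("family", "order", "class")
THERMAL_STATUSES = ("obligate", "facultative")


def _validate(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """P(exactly k taxon members in an n-subset of an N-pool with K members).

    Impossible counts (k > K, or n - k > N - K) return 0 by convention.
    Computed in log-gamma space, stable for pools of hundreds of species.
    """
    _validate(N, K, n, k)
    if k > K or n - k > N - K:
        return 0.0
    return float(stats.hypergeom.pmf(k, N, K, n))


def p_over(N: int, K: int, n: int, k: int) -> float:
    """Inclusive upper tail: probability of k or more taxon members."""
    _validate(N, K, n, k)
    if k > min(K, n):
        return 0.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def p_under(N: int, K: int, n: int, k: int) -> float:
    """Inclusive lower tail: probability of k or fewer taxon members."""
    _validate(N, K, n, k)
    return float(stats.hypergeom.cdf(k, N, K, n))


def bh_qvalues(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def enrich_table(
    pool: pd.DataFrame,
    group: Iterable[str],
    rank: str,
    alpha: float = 0.05,
    fdr_level: float = 0.15,
) -> pd.DataFrame:
    """Per-taxon over/under-representation of a group within the pool.

    Parameters
    ----------
    pool : DataFrame
        One row per species with columns ``species`` and the requested
        ``rank``.  The taxonomic ranks 'family', 'order' and 'class' are
        the standard use; any other categorical column of the pool (e.g. a
        growth-form / biomorph classification) is accepted and tested the
        same way, which is exactly a per-category one-sided Fisher test.
    group : iterable of species names, subset of the pool.
    alpha : raw-p call threshold (primary calls use raw tails).
    fdr_level : Benjamini-Hochberg q-value threshold for the FDR calls.

    Returns a DataFrame with one row per taxon present in the pool:
    N, K, n, k, p_over, p_under, q_over, q_under, call (raw rule),
    call_fdr (q-value rule) and a low-power flag for single-species taxa.
    """
    if rank not in pool.columns or rank == "species":
        raise ValueError(f"rank {rank!r} is not a categorical column of the pool")
    group = set(group)
    pool_species = set(pool["species"])
    stray = group - pool_species
    if stray:
        raise ValueError(f"group species not in pool: {', '.join(sorted(stray))}")
    if not group:
        logger.warning("empty group: all representation probabilities are 1")

    N = len(pool_species)
    n = len(group)
    rows = []
    in_group = pool["species"].isin(group)
    for taxon, sub in pool.groupby(rank, sort=True):
        K = len(sub)
        k = int(in_group[sub.index].sum())
        po = p_over(N, K, n, k)
        pu = p_under(N, K, n, k)
        rows.append(
            {
                "taxon": taxon,
                "rank": rank,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p_over": po,
                "p_under": pu,
                "low_power": K == 1,
            }
        )
    table = pd.DataFrame(rows)
    table["q_over"] = bh_qvalues(table["p_over"])
    table["q_under"] = bh_qvalues(table["p_under"])
    table["call"] = "none"
    table.loc[table["p_over"] <= alpha, "call"] = "over"
    table.loc[table["p_under"] <= alpha, "call"] = "under"
    table["call_fdr"] = "none"
    table.loc[table["q_over"] <= fdr_level, "call_fdr"] = "over"
    table.loc[table["q_under"] <= fdr_level, "call_fdr"] = "under"
    return table


def merge_status_sources(status_a: pd.DataFrame, status_b: pd.DataFrame) -> pd.DataFrame:
    """Merge two thermal-status surveys of overlapping species lists.

    A species thermal (obligate or facultative) in either source is thermal
    in the merge; non-thermal in both sources stays non-thermal; a species
    present in only one source keeps that source's status.  Contradictory
    obligate-vs-facultative labels resolve to facultative (the species was
    observed outside heated ground at least once); likewise an obligate
    label contradicted by a non-thermal one resolves to facultative.
    """
    a = dict(zip(status_a["species"], status_a["status"]))
    b = dict(zip(status_b["species"], status_b["status"]))
    merged = {}
    for sp in sorted(set(a) | set(b)):
        sa, sb = a.get(sp), b.get(sp)
        if sa is None or sb is None:
            merged[sp] = sa if sa is not None else sb
            continue
        thermal_a = sa in THERMAL_STATUSES
        thermal_b = sb in THERMAL_STATUSES
        if not thermal_a and not thermal_b:
            merged[sp] = "non_thermal"
        elif sa == sb:
            merged[sp] = sa
        else:
            # any disagreement involving a thermal label: the species was
            # seen outside heat at least once -> facultative
            merged[sp] = "facultative"
            logger.info("status conflict for %s (%s vs %s) -> facultative", sp, sa, sb)
    return pd.DataFrame({"species": list(merged), "status": list(merged.values())})
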