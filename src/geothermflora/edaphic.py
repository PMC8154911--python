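"""Screen soil properties limiting plant species, and aggregate over thermophytes.

Each (species, soil property) cell is tested twice against the plot-level
cover values: Spearman's rank correlation for monotone dependence and
Hoeffding's D for general (including non-monotone) dependence.  A property
is *important* for a species when either test reaches p <= alpha (default
0.01).  Properties disproportionately important for thermophyte species are
then identified with a one-sided Fisher's exact test over the 2x2 table
(thermophyte vs not) x (important vs not), whose one-sided probability is
the hypergeometric upper tail of :func:`geothermflora.enrichment.p_over`.

No multiple-testing correction is applied across the property x species
grid for the importance calls; Benjamini-Hochberg q-values are reported
alongside as optional columns.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import THERMAL_STATUSES, bh_qvalues, p_over
from .exceptions import UndefinedStatisticError

__all__ = [
    "spearman_screen",
    "hoeffding_d",
    "hoeffding_screen",
    "importance_matrix",
    "thermophyte_property_test",
]

logger = logging.getLogger(__name__)

_MIN_N = 5
_EXACT_SPEARMAN_N = 9


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < _MIN_N:
        raise UndefinedStatisticError(
            f"need at least {_MIN_N} paired observations, got {len(x)}"
        )
    return x, y


def spearman_screen(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an exact two-sided p for small n.

    Mid-ranks handle ties.  For n <= 9 the p-value enumerates all n!
    permutations of one margin; larger samples use the t approximation.
    Raises :class:`UndefinedStatisticError` for constant columns.
    """
    x, y = _clean_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("Spearman rho undefined for constant column")
    n = len(x)
    if n > _EXACT_SPEARMAN_N:
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    rho = float(rxc @ ryc) / denom
    perms = np.array(list(itertools.permutations(range(n))))
    rho_perm = (rxc[perms] @ ryc) / denom
    p = float((np.abs(rho_perm) >= abs(rho) - 1e-12).mean())
    return rho, p


def _rank_kernels(v: np.ndarray) -> np.ndarray:
    """c[i, j] = 1 if v_j < v_i, 1/2 if tied (j != i), else 0."""
    lt = (v[None, :] < v[:, None]).astype(float)
    eq = (v[None, :] == v[:, None]).astype(float)
    np.fill_diagonal(eq, 0.0)
    return lt + 0.5 * eq


def _hoeffding_from_kernels(cx: np.ndarray, cy: np.ndarray) -> float:
    n = cx.shape[0]
    R = 1.0 + cx.sum(axis=1)
    S = 1.0 + cy.sum(axis=1)
    Q = 1.0 + (cx * cy).sum(axis=1)
    d1 = float(((Q - 1) * (Q - 2)).sum())
    d2 = float(((R - 1) * (R - 2) * (S - 1) * (S - 2)).sum())
    d3 = float(((R - 2) * (S - 2) * (Q - 1)).sum())
    num = (n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3
    den = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * num / den


def hoeffding_d(x, y) -> float:
    """Hoeffding's D on the standard [-0.5, 1] scale (ties via mid-counts)."""
    x, y = _clean_pair(x, y)
    return _hoeffding_from_kernels(_rank_kernels(x), _rank_kernels(y))


def hoeffding_screen(
    x,
    y,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
    chunk: int = 2048,
) -> tuple[float, float]:
    """Hoeffding's D with a one-sided permutation p-value.

    One margin is permuted ``n_perm`` times; p is the add-one fraction of
    permutations with D at least as large as observed (large D indicates
    dependence of any shape).
    """
    x, y = _clean_pair(x, y)
    n = len(x)
    cx = _rank_kernels(x)
    cy = _rank_kernels(y)
    d_obs = _hoeffding_from_kernels(cx, cy)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    count = 0
    den = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        perms = rng.permuted(
            np.broadcast_to(np.arange(n), (size, n)).copy(), axis=1
        )
        # relabelling y by a permutation pi maps cy -> cy[pi][:, pi]
        cyp = cy[perms[:, :, None], perms[:, None, :]]
        R = 1.0 + cx.sum(axis=1)  # invariant under y relabelling
        S = 1.0 + cyp.sum(axis=2)
        Q = 1.0 + np.einsum("ij,pij->pi", cx, cyp)
        d1 = ((Q - 1) * (Q - 2)).sum(axis=1)
        d2 = ((R - 1) * (R - 2) * (S - 1) * (S - 2)).sum(axis=1)
        d3 = ((R - 2) * (S - 2) * (Q - 1)).sum(axis=1)
        d_perm = 30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / den
        count += int((d_perm >= d_obs - 1e-12).sum())
        done += size
    p = (count + 1) / (n_perm + 1)
    return float(d_obs), float(p)


def importance_matrix(
    cover: pd.DataFrame,
    soil: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Run both screens for every (species, property) cell.

    Parameters
    ----------
    cover : DataFrame
        Plot x species cover values (%, 0-100), indexed by plot id.
    soil : DataFrame
        Plot x property values, same index as ``cover``.
    alpha : importance threshold applied to min(spearman_p, hoeffding_p).

    Returns a long DataFrame (species, property, n, spearman_rho,
    spearman_p, hoeffding_d, hoeffding_p, important, direction) plus BH
    q-value columns across all cells.  Constant property columns are
    excluded with a warning; missing values are dropped pairwise.
    """
    if not cover.index.equals(soil.index):
        raise ValueError("cover and soil tables must share the same plot index")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for prop in soil.columns:
        pvals = soil[prop].to_numpy(dtype=float)
        finite = pvals[np.isfinite(pvals)]
        if len(finite) == 0 or np.ptp(finite) == 0:
            logger.warning("property %r constant or empty; excluded from screen", prop)
            continue
        for sp in cover.columns:
            cvals = cover[sp].to_numpy(dtype=float)
            keep = np.isfinite(cvals) & np.isfinite(pvals)
            if keep.sum() < _MIN_N:
                continue
            x, y = cvals[keep], pvals[keep]
            try:
                rho, sp_p = spearman_screen(x, y)
            except UndefinedStatisticError:
                rho, sp_p = float("nan"), 1.0
            d, h_p = hoeffding_screen(x, y, n_perm=n_perm, seed=rng)
            important = min(sp_p, h_p) <= alpha
            if sp_p <= alpha and np.isfinite(rho):
                direction = "+" if rho > 0 else "-"
            elif important:
                direction = "nonmonotone"
            else:
                direction = ""
            rows.append(
                {
                    "species": sp,
                    "property": prop,
                    "n": int(keep.sum()),
                    "spearman_rho": rho,
                    "spearman_p": sp_p,
                    "hoeffding_d": d,
                    "hoeffding_p": h_p,
                    "important": important,
                    "direction": direction,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q_spearman"] = bh_qvalues(table["spearman_p"])
        table["q_hoeffding"] = bh_qvalues(table["hoeffding_p"])
    return table


def thermophyte_property_test(
    importance: pd.DataFrame, statuses: Mapping[str, str]
) -> pd.DataFrame:
    """Per-property one-sided Fisher test for thermophyte-biased importance.

    For each property the 2x2 table is (thermophyte vs not) x (important vs
    not) over the species screened; the one-sided enrichment probability is
    the exact hypergeometric upper tail p_over(N, K, n, k) with N species,
    K thermophytes, n important species and k important thermophytes.
    """
    missing = set(importance["species"]) - set(statuses)
    if missing:
        raise ValueError(f"statuses missing for: {', '.join(sorted(missing))}")
    is_thermo = {sp: statuses[sp] in THERMAL_STATUSES for sp in set(importance["species"])}
    if not any(is_thermo.values()):
        logger.warning("no thermophytes among screened species; all p = 1")
    rows = []
    for prop, sub in importance.groupby("property", sort=True):
        species = sub["species"].tolist()
        N = len(species)
        K = sum(is_thermo[sp] for sp in species)
        imp = sub.set_index("species")["important"]
        n = int(imp.sum())
        k = int(sum(imp[sp] and is_thermo[sp] for sp in species))
        p = 1.0 if K == 0 else p_over(N, K, n, k)
        rows.append({"property": prop, "N": N, "K": K, "n": n, "k": k, "fisher_p": p})
    return pd.DataFrame(rows)
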