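"""Soil indices and zone-wise nonparametric comparisons.

Covers the vertical temperature gradient (linear temperature-depth slope k
and its angle alpha = arctan(k)), two oxide-ratio weathering indices (the
silica-titanium index STI and Silica/R2O3), one-sided Mann-Whitney
comparisons between sample groups with Bonferroni correction, grouping of
samples by thermal zone / temperature class / depth, and normalization of
composition profiles to a reference (non-heated) zone.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "temp_gradient",
    "sti",
    "silica_r2o3",
    "zone_compare",
    "normalize_to_reference",
    "group_samples",
    "temperature_class",
    "TEMPERATURE_CLASSES",
]

#: temperature classes (deg C at the sample), left-closed boundaries
TEMPERATURE_CLASSES = (
    (-math.inf, 30.0, "non-heated"),
    (30.0, 50.0, "slightly heated"),
    (50.0, 80.0, "moderately heated"),
    (80.0, math.inf, "hot"),
)


def temp_gradient(series: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Temperature-depth slope k (deg C / cm) and its angle alpha (degrees).

    ``series`` is a sequence of (depth_cm, temperature_C) pairs within the
    0-50 cm layer; with the standard two measurements at 15 and 50 cm the
    least-squares fit reduces to the two-point slope (T50 - T15)/35.
    """
    pts = [(float(d), float(t)) for d, t in series]
    if len(pts) < 2:
        raise ValueError("need at least 2 depth points")
    d = np.array([p[0] for p in pts])
    t = np.array([p[1] for p in pts])
    if not (np.isfinite(d).all() and np.isfinite(t).all()):
        raise ValueError("non-finite depth or temperature")
    if np.ptp(d) == 0:
        raise ValueError("depths must be distinct")
    if (t < -20).any() or (t > 110).any():
        raise ValueError("temperature outside the physically plausible -20..110 C")
    if len(pts) == 2:
        k = (t[1] - t[0]) / (d[1] - d[0])  # exact two-point slope
    else:
        k = float(np.polyfit(d, t, 1)[0])
    return float(k), math.degrees(math.atan(k))


def sti(sio2: float, tio2: float, al2o3: float) -> float:
    """Silica-titanium weathering index.

    STI = 100 * SiO2 / (SiO2/TiO2 + Al2O3/TiO2 + SiO2/Al2O3); oxide inputs
    in mass %.  Higher values indicate less altered material.  Not
    scale-invariant (mixes ratios with an absolute SiO2 term).
    """
    if tio2 <= 0 or al2o3 <= 0:
        raise ValueError("STI undefined for TiO2 <= 0 or Al2O3 <= 0")
    return 100.0 * sio2 / (sio2 / tio2 + al2o3 / tio2 + sio2 / al2o3)


def silica_r2o3(sio2: float, al2o3: float, fe2o3: float, tio2: float) -> float:
    """Silica to sesquioxide ratio SiO2 / (Al2O3 + Fe2O3 + TiO2); unitless,
    invariant under common rescaling of all oxides."""
    den = al2o3 + fe2o3 + tio2
    if den <= 0:
        raise ValueError("Silica/R2O3 undefined for non-positive sesquioxide sum")
    return sio2 / den


_EXACT_MW_COMBINATIONS = 20_000


def _mannwhitney(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """U statistic and p-value.

    Small samples get an exact p by full enumeration of group assignments
    (valid under ties, unlike the classical exact U distribution); larger
    samples use the tie-corrected normal approximation.
    """
    n1, n2 = len(x), len(y)
    if math.comb(n1 + n2, n1) > _EXACT_MW_COMBINATIONS:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    import itertools

    u_all = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(n1 + n2), n1)]
    ) - n1 * (n1 + 1) / 2
    eps = 1e-9
    p_less = float((u_all <= u_obs + eps).mean())
    p_greater = float((u_all >= u_obs - eps).mean())
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValueError("alternative must be 'less', 'greater' or 'two-sided'")
    return u_obs, p


def zone_compare(
    values_by_group: Mapping[str, Sequence[float]], alternative: str = "less"
) -> pd.DataFrame:
    """One-sided Mann-Whitney U for all group pairs, Bonferroni-corrected.

    ``alternative`` is the direction tested for (group_a vs group_b) taken
    in the mapping's order: 'less', 'greater', or 'two-sided'.  The exact U
    distribution is used for small untied samples, the tie-corrected normal
    approximation otherwise.  The Bonferroni factor is the number of
    pairwise tests performed, with p capped at 1.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    groups = {}
    for name in names:
        v = np.asarray(values_by_group[name], dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 finite values")
        groups[name] = v
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        u, p = _mannwhitney(groups[a], groups[b], alternative)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(groups[a]),
                "n_b": len(groups[b]),
                "U": u,
                "p_raw": p,
                "p_bonferroni": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def normalize_to_reference(
    table: pd.DataFrame,
    variables: Sequence[str],
    zone_col: str = "zone",
    reference: str = "I",
    stat: str = "median",
) -> pd.DataFrame:
    """Per-zone composition profile as ratios to a reference zone.

    For each variable, ratio(zone) = stat(zone) / stat(reference); the
    reference row is identically 1.  ``stat`` is 'median' (default, robust)
    or 'mean'.  A zero reference value yields NaN for that variable
    (flagged undefined rather than infinite).  Idempotent: normalizing an
    already-normalized table returns it unchanged.
    """
    if reference not in set(table[zone_col]):
        raise ValueError(f"reference zone {reference!r} not present")
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    agg = table.groupby(zone_col)[list(variables)].agg(stat)
    ref = agg.loc[reference]
    out = agg.divide(ref, axis=1)
    out[ref.index[ref == 0]] = float("nan")
    return out


def temperature_class(t: float) -> str:
    """Class label for a sample temperature; boundaries are left-closed
    (30 C falls in 'slightly heated')."""
    for lo, hi, label in TEMPERATURE_CLASSES:
        if lo <= t < hi:
            return label
    raise ValueError(f"unclassifiable temperature {t!r}")


def group_samples(soil_table: pd.DataFrame, criterion: str) -> pd.DataFrame:
    """Attach a 'group' column partitioning samples by the chosen criterion.

    ``criterion`` is 'zone' (thermal zones I-IV), 'temperature_class'
    (< 30 / 30-50 / 50-80 / >= 80 C at the sample) or 'depth' (sampling
    depth value).  Every sample lands in exactly one group.
    """
    out = soil_table.copy()
    if criterion == "zone":
        if "zone" not in out.columns:
            raise ValueError("soil table has no 'zone' column")
        out["group"] = out["zone"].astype(str)
    elif criterion == "temperature_class":
        if "temperature" not in out.columns:
            raise ValueError("soil table has no 'temperature' column")
        out["group"] = [temperature_class(t) for t in out["temperature"]]
    elif criterion == "depth":
        if "depth" not in out.columns:
            raise ValueError("soil table has no 'depth' column")
        out["group"] = out["depth"].astype(str)
    else:
        raise ValueError("criterion must be 'zone', 'temperature_class' or 'depth'")
    return out
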