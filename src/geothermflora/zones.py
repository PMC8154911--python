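"""Permutation tests for species-composition overlap between thermal zones.

For two zones holding A and B species out of a shared pool, the observed
number of common species is ranked against a null built by drawing
independent uniform subsets of sizes |A| and |B| (without replacement) from
the pool ``n_draws`` times.  The right-sided p is the fraction of null draws
with at least as many common species (zones more similar than spatial
mixing), the left-sided p the fraction with at most as many (more
dissimilar); both tails include ties and carry an add-one correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["OverlapResult", "overlap_test", "all_pairs_matrix"]


@dataclass
class OverlapResult:
    observed: int
    p_right: float
    p_left: float
    null_mean: float
    null_sd: float
    n_draws: int


def _random_subsets(rng, n_draws: int, pool_size: int, k: int) -> np.ndarray:
    """Boolean membership matrix of ``n_draws`` uniform k-subsets."""
    # argpartition of iid uniforms gives a uniform k-subset per row
    u = rng.random((n_draws, pool_size))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k] if k < pool_size else None
    mask = np.zeros((n_draws, pool_size), dtype=bool)
    if idx is None:
        mask[:] = True
    else:
        mask[np.arange(n_draws)[:, None], idx] = True
    return mask


def overlap_test(
    zone_a: Sequence[str],
    zone_b: Sequence[str],
    pool: Sequence[str],
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> OverlapResult:
    """Overlap of two zone compositions against a random-membership null."""
    pool = sorted(set(pool))
    a, b = set(zone_a), set(zone_b)
    for name, z in (("A", a), ("B", b)):
        if not z:
            raise ValueError(f"zone {name} is empty")
        stray = z - set(pool)
        if stray:
            raise ValueError(
                f"zone {name} species not in pool: {', '.join(sorted(stray))}"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = len(a & b)
    ma = _random_subsets(rng, n_draws, len(pool), len(a))
    mb = _random_subsets(rng, n_draws, len(pool), len(b))
    null = (ma & mb).sum(axis=1)
    p_right = (int((null >= observed).sum()) + 1) / (n_draws + 1)
    p_left = (int((null <= observed).sum()) + 1) / (n_draws + 1)
    return OverlapResult(
        observed, p_right, p_left, float(null.mean()), float(null.std(ddof=1)), n_draws
    )


def all_pairs_matrix(
    zones: Mapping[str, Sequence[str]],
    pool: Sequence[str],
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Pairwise overlap tests for all zones.

    Returns symmetric DataFrames keyed 'observed', 'p_right', 'p_left'.
    """
    names = list(zones)
    if len(names) < 2:
        raise ValueError("need at least 2 zones")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = pd.DataFrame(np.zeros((len(names), len(names)), dtype=int), index=names, columns=names)
    right = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    left = right.copy()
    for i, za in enumerate(names):
        for j, zb in enumerate(names):
            if j < i:
                continue
            res = overlap_test(zones[za], zones[zb], pool, n_draws, rng)
            obs.loc[za, zb] = obs.loc[zb, za] = res.observed
            right.loc[za, zb] = right.loc[zb, za] = res.p_right
            left.loc[za, zb] = left.loc[zb, za] = res.p_left
    return {"observed": obs, "p_right": right, "p_left": left}
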