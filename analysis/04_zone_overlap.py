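#!/usr/bin/env python
"""Do the thermal zones share more (or fewer) species than spatial mixing
would produce?

Pairwise overlap permutation tests (1000 draws from the observed plot
pool): a small right-sided p means two zones are more similar than chance,
a small left-sided p less similar.
"""

from _common import SEED, dataset, save

from geothermflora.zones import all_pairs_matrix


def main():
    ds = dataset()
    pool = sorted(set().union(*ds.zone_species.values()))
    mats = all_pairs_matrix(ds.zone_species, pool, n_draws=1000, seed=SEED)
    for key, df in mats.items():
        save(df, f"zones/overlap_{key}.tsv", index=True)
    print(f"plot-pool size: {len(pool)} species")
    print("\nobserved common species:")
    print(mats["observed"].to_string())
    print("\nright-sided p (small = more similar than chance):")
    print(mats["p_right"].round(4).to_string())
    print("\nleft-sided p (small = less similar than chance):")
    print(mats["p_left"].round(4).to_string())


if __name__ == "__main__":
    main()
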