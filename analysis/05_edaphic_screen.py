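#!/usr/bin/env python
"""Which soil properties limit which species, and which matter specifically
for thermophytes?

Per (species, property) cell: Spearman rank correlation (monotone) and
Hoeffding's D with a permutation p (any dependence shape); important when
either p <= 0.01.  Per property: one-sided Fisher's exact test for
importance being concentrated on thermophyte species.
"""

from _common import SEED, dataset, save

from geothermflora.edaphic import importance_matrix, thermophyte_property_test


def main():
    ds = dataset()
    imp = importance_matrix(ds.cover, ds.plot_soil, alpha=0.01, n_perm=999, seed=SEED)
    save(imp, "edaphic/importance.tsv")
    flagged = imp[imp["important"]]
    print(f"screened {imp['species'].nunique()} species x "
          f"{imp['property'].nunique()} properties; {len(flagged)} cells important")
    print(flagged[["species", "property", "spearman_rho", "spearman_p",
                   "hoeffding_p", "direction"]].to_string(index=False))

    statuses = dict(zip(ds.taxonomy["species"], ds.taxonomy["status"]))
    fisher = thermophyte_property_test(imp, statuses)
    save(fisher, "edaphic/thermophyte_fisher.tsv")
    hits = fisher[fisher["fisher_p"] <= 0.05]
    print("\nproperties disproportionately important for thermophytes (p <= 0.05):")
    print(hits.to_string(index=False) if not hits.empty else "  none")
    print("\nplanted cover effects:", ds.planted["cover_effects"])


if __name__ == "__main__":
    main()
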