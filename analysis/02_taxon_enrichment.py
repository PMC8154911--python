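#!/usr/bin/env python
"""Which families, orders and classes are over- or under-represented among
thermophytes?

Hypergeometric tails per taxon for the obligate, facultative, merged-thermal
and non-thermal groups, with raw calls at P <= 0.05 and Benjamini-Hochberg
q-values at the 15% FDR level alongside.
"""

from _common import dataset, save

from geothermflora.enrichment import enrich_table


def main():
    ds = dataset()
    tax = ds.taxonomy
    groups = {
        "obligate": set(tax.loc[tax["status"] == "obligate", "species"]),
        "facultative": set(tax.loc[tax["status"] == "facultative", "species"]),
        "thermal": set(tax.loc[tax["status"] != "non_thermal", "species"]),
        "non_thermal": set(tax.loc[tax["status"] == "non_thermal", "species"]),
    }
    for gname, species in groups.items():
        for rank in ("family", "order", "class"):
            table = enrich_table(tax, species, rank)
            save(table, f"enrichment/{gname}_{rank}.tsv")
            hits = table[table["call"] != "none"]
            if not hits.empty:
                print(f"{gname} / {rank}:")
                print(
                    hits[["taxon", "K", "k", "p_over", "p_under", "call", "call_fdr"]]
                    .to_string(index=False)
                )
    # growth-form composition of the thermal flora vs the whole pool: the
    # same hypergeometric tails act as per-biomorph one-sided Fisher tests
    bio = enrich_table(tax, groups["thermal"], "biomorph")
    save(bio, "enrichment/thermal_biomorph.tsv")
    print("\nthermal biomorph composition:")
    print(bio[["taxon", "K", "k", "p_over", "p_under", "call"]].to_string(index=False))

    print(
        "\nplanted thermal families for reference:",
        ds.planted["thermal_families"],
    )


if __name__ == "__main__":
    main()
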