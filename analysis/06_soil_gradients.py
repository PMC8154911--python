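#!/usr/bin/env python
"""Soil thermal and weathering gradients across the zones.

Per pit: the temperature-depth slope between 15 and 50 cm and its angle
alpha = arctan(k).  Per sample: the silica-titanium index (STI) and
Silica/R2O3.  Zone-wise one-sided Mann-Whitney comparisons of the angles
(Bonferroni-corrected) and topsoil composition normalized to the
non-heated zone I.
"""

import pandas as pd
from _common import dataset, save

from geothermflora.soil import normalize_to_reference, silica_r2o3, sti, temp_gradient, zone_compare


def main():
    ds = dataset()
    soil = ds.soil.copy()
    soil["STI"] = [sti(r.SiO2, r.TiO2, r.Al2O3) for r in soil.itertuples()]
    soil["silica_r2o3"] = [
        silica_r2o3(r.SiO2, r.Al2O3, r.Fe2O3, r.TiO2) for r in soil.itertuples()
    ]
    save(soil, "soil/soil_indices.tsv")

    pits = soil.drop_duplicates("pit")
    angles = pd.DataFrame(
        {
            "pit": pits["pit"],
            "zone": pits["zone"],
            "alpha_deg": [
                temp_gradient([(15.0, r.T15), (50.0, r.T50)])[1] for r in pits.itertuples()
            ],
        }
    )
    save(angles, "soil/gradient_angles.tsv")
    print("gradient angle alpha (degrees) by zone:")
    print(angles.groupby("zone")["alpha_deg"].agg(["mean", "min", "max"]).round(2))

    by_zone = {z: g["alpha_deg"].to_numpy() for z, g in angles.groupby("zone")}
    comp = zone_compare(by_zone, alternative="less")
    save(comp, "soil/angle_zone_compare.tsv")
    print("\none-sided Mann-Whitney on angles (zone_a < zone_b):")
    print(comp.round(4).to_string(index=False))

    topsoil = soil[soil["depth"] == soil["depth"].min()]
    variables = ["SiO2", "TiO2", "Al2O3", "Fe2O3", "kaolinite", "smectite",
                 "quartz", "sand", "silt", "clay", "SOC"]
    profiles = normalize_to_reference(topsoil, variables, reference="I")
    save(profiles, "soil/topsoil_vs_zone_I.tsv", index=True)
    print("\ntopsoil composition, median ratio to zone I:")
    print(profiles.round(2).to_string())


if __name__ == "__main__":
    main()
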