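"""Synthetic-data generator: determinism, counts, planted structure."""

import numpy as np
import pytest
from scipy import stats

from geothermflora.exceptions import InvalidConfigError
from geothermflora.synthetic import (
    SyntheticConfig,
    gen_backbone_tree,
    gen_thermal_status,
    generate,
    load_dataset,
    write_dataset,
)
from geothermflora.trees import as_newick, tip_labels, tree_depth


class TestConfigValidation:
    def test_defaults_valid(self):
        cfg = SyntheticConfig()
        assert cfg.n_species == 292
        assert cfg.n_families == 60

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_families": 1},
            {"tips_per_family": (0, 3)},
            {"tips_per_family": (5, 2)},
            {"n_obligate": -1},
            {"n_obligate": 200, "n_facultative": 200},
            {"clustering_strength": 1.5},
            {"zone_richness": (5, 8, 4, 3)},
            {"zone_richness": (24, 18, 12)},
            {"n_species": 10_000},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(**kwargs)


class TestBackboneTree:
    def test_two_singleton_families(self):
        cfg = SyntheticConfig(
            n_families=2, tips_per_family=(1, 1), n_species=2,
            n_obligate=0, n_facultative=0, zone_richness=(2, 2, 1, 1),
            n_plots=8, n_cover_species=2, n_cover_thermal=0,
            cover_effect_spec=(), seed=0,
        )
        tree, tax = gen_backbone_tree(cfg)
        assert len(tip_labels(tree)) == 2
        depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
        assert depths[0] == pytest.approx(depths[1], abs=1e-9)

    def test_same_seed_identical_newick(self):
        cfg = SyntheticConfig(seed=11)
        t1, _ = gen_backbone_tree(cfg)
        t2, _ = gen_backbone_tree(cfg)
        assert as_newick(t1) == as_newick(t2)

    def test_full_scale_structure(self, dataset):
        tree, tax = dataset.tree, dataset.taxonomy
        assert len(tip_labels(tree)) == 292
        assert tax["family"].nunique() == 60
        assert tree_depth(tree) == pytest.approx(1.0, abs=1e-6)
        # ultrametry
        depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
        assert np.ptp(depths) < 1e-6
        # family monophyly by traversal: the MRCA of each family's tips
        # contains no foreign tips
        fam_of = dict(zip(tax["species"], tax["family"]))
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        for fam, sub in tax.groupby("family"):
            tips = [leaves[s] for s in sub["species"]]
            node = tips[0]
            anc = []
            while node is not None:
                anc.append(node)
                node = node.parent_node
            others = []
            for t in tips[1:]:
                s = set()
                node = t
                while node is not None:
                    s.add(node)
                    node = node.parent_node
                others.append(s)
            mrca = next(n for n in anc if all(n in s for s in others)) if others else tips[0]
            clade = [lf.taxon.label for lf in mrca.leaf_iter()]
            assert {fam_of[l] for l in clade} == {fam}

    def test_each_species_one_family(self, dataset):
        assert dataset.taxonomy["species"].is_unique


class TestThermalStatus:
    def test_exact_counts(self, dataset):
        vc = dataset.taxonomy["status"].value_counts()
        assert vc["obligate"] == 18
        assert vc["facultative"] == 33

    def test_no_thermophytes(self):
        cfg = SyntheticConfig(n_obligate=0, n_facultative=0)
        _, tax = gen_backbone_tree(cfg)
        out = gen_thermal_status(tax, cfg)
        assert (out["status"] == "non_thermal").all()

    def test_full_clustering_single_family(self):
        cfg = SyntheticConfig(
            n_families=5, tips_per_family=(4, 6), n_species=25,
            n_obligate=4, n_facultative=0, clustering_strength=1.0,
            zone_richness=(10, 8, 6, 4), seed=2,
            n_cover_species=10, n_cover_thermal=4,
        )
        _, tax = gen_backbone_tree(cfg)
        out = gen_thermal_status(tax, cfg)
        fams = out.loc[out["status"] == "obligate", "family"].unique()
        assert len(fams) == 1

    def test_zero_clustering_hypergeometric(self):
        """Uniform assignment: per-family thermal counts match the
        hypergeometric expectation."""
        cfg = SyntheticConfig(
            n_families=6, tips_per_family=(3, 7), n_species=30,
            n_obligate=6, n_facultative=0, clustering_strength=0.0,
            zone_richness=(10, 8, 6, 4), seed=0,
            n_cover_species=10, n_cover_thermal=5,
        )
        _, tax = gen_backbone_tree(cfg)
        rng = np.random.default_rng(123)
        reps = 2000
        counts = {f: 0.0 for f in tax["family"].unique()}
        for _ in range(reps):
            out = gen_thermal_status(tax, cfg, rng)
            for f, c in out.loc[out["status"] == "obligate", "family"].value_counts().items():
                counts[f] += c
        fam_sizes = tax["family"].value_counts()
        for fam, total in counts.items():
            K = fam_sizes[fam]
            expect = 6 * K / 30
            var = 6 * (K / 30) * (1 - K / 30) * (30 - 6) / 29
            se = np.sqrt(var / reps)
            assert abs(total / reps - expect) < 4 * se + 1e-9


class TestZoneTables:
    def test_zone_sizes_exact(self, dataset):
        for z, r in zip(("I", "II", "III", "IV"), (24, 18, 12, 8)):
            assert len(dataset.zone_species[z]) == r

    def test_zone_sets_subset_of_pool(self, dataset):
        pool = set(dataset.taxonomy["species"])
        for spp in dataset.zone_species.values():
            assert set(spp) <= pool

    def test_hot_zones_nested(self, dataset):
        zs = dataset.zone_species
        assert set(zs["IV"]) <= set(zs["III"]) <= set(zs["II"])

    def test_soil_gradient_directions(self, dataset):
        by_zone = dataset.soil.groupby("zone")[["pH", "EC", "SOC", "kaolinite"]].mean()
        assert by_zone.loc["IV", "pH"] < by_zone.loc["I", "pH"]
        assert by_zone.loc["IV", "EC"] > by_zone.loc["I", "EC"]
        assert by_zone.loc["IV", "SOC"] < by_zone.loc["I", "SOC"]

    def test_zero_noise_gradient_strict(self):
        from dataclasses import replace
        from geothermflora.synthetic import _default_gradients, GradientSpec

        grads = {
            k: GradientSpec(v.direction, v.zone_means, 0.0, v.bounds)
            for k, v in _default_gradients().items()
        }
        cfg = SyntheticConfig(soil_gradient_spec=grads, seed=5)
        ds = generate(cfg)
        by_zone = ds.soil.groupby("zone")["pH"].mean()
        assert by_zone["I"] > by_zone["II"] > by_zone["III"] > by_zone["IV"]

    def test_particle_fractions_sum(self, dataset):
        total = dataset.soil[["sand", "silt", "clay"]].sum(axis=1)
        np.testing.assert_allclose(total, 100.0, atol=1.0)

    def test_cover_in_range(self, dataset):
        assert (dataset.cover.to_numpy() >= 0).all()
        assert (dataset.cover.to_numpy() <= 100).all()

    def test_planted_cover_correlation(self):
        cfg = SyntheticConfig(n_plots=200, seed=8)
        ds = generate(cfg)
        eff = ds.planted["cover_effects"][0]
        rho = stats.spearmanr(
            ds.cover[eff["species"]], ds.plot_soil[eff["property"]]
        ).statistic
        assert eff["sign"] * rho > 0.5


class TestDeterminismAndIO:
    def test_same_seed_identical_outputs(self, small_config):
        a, b = generate(small_config), generate(small_config)
        assert as_newick(a.tree) == as_newick(b.tree)
        assert a.taxonomy.equals(b.taxonomy)
        assert a.zone_species == b.zone_species
        assert a.soil.equals(b.soil)
        assert a.cover.equals(b.cover)

    def test_roundtrip_through_files(self, small_config, tmp_path):
        ds = generate(small_config)
        write_dataset(ds, tmp_path)
        back = load_dataset(tmp_path)
        assert back.config == small_config
        assert sorted(tip_labels(back.tree)) == sorted(tip_labels(ds.tree))
        assert back.zone_species == {z: sorted(s) for z, s in ds.zone_species.items()}
        np.testing.assert_allclose(
            back.cover.to_numpy(), ds.cover.to_numpy(), rtol=1e-5
        )
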