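"""Newick I/O, grafting and patristic-distance behaviour."""

import itertools

import numpy as np
import pytest

from geothermflora.exceptions import NewickParseError, UnplaceableSpeciesError
from geothermflora.trees import (
    GraftMethod,
    graft_species,
    patristic_matrix,
    read_newick_string,
    sample_pairs,
    tip_labels,
    tree_depth,
    write_newick,
    read_newick,
)


def _tax(df_rows):
    import pandas as pd

    return pd.DataFrame(df_rows, columns=["species", "family", "order", "class"])


class TestNewickIO:
    def test_two_tip_tree(self):
        t = read_newick_string("(A:1,B:1):0;")
        assert sorted(tip_labels(t)) == ["A", "B"]
        assert tree_depth(t) == pytest.approx(1.0)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(NewickParseError, match="duplicate"):
            read_newick_string("(A:1,A:1);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(NewickParseError, match="length"):
            read_newick_string("(A:1,(B,C:1):1);")

    def test_malformed_rejected(self):
        with pytest.raises(NewickParseError):
            read_newick_string("(A:1,(B:1;")

    def test_roundtrip_preserves_distances(self, dataset, distmatrix, tmp_path):
        path = tmp_path / "t.nwk"
        write_newick(dataset.tree, path)
        again = patristic_matrix(read_newick(path), distmatrix.labels)
        np.testing.assert_allclose(again.values, distmatrix.values, atol=1e-9)


class TestPatristic:
    def test_path_sum(self):
        pm = patristic_matrix(read_newick_string("(A:1,B:2):0;"))
        assert pm.distance("A", "B") == pytest.approx(3.0)
        assert pm.distance("A", "A") == 0.0

    def test_mrca_depth_oracle(self, dataset):
        """On an ultrametric depth-h tree, d(a,b) = 2*(h - MRCA height)."""
        tree = dataset.tree
        labels = sorted(tip_labels(tree))[:10]
        pm = patristic_matrix(tree, labels)
        h = tree_depth(tree)
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

        def mrca_root_dist(a, b):
            anc_a = []
            nd = leaves[a]
            while nd is not None:
                anc_a.append(nd)
                nd = nd.parent_node
            anc_b = set()
            nd = leaves[b]
            while nd is not None:
                anc_b.add(nd)
                nd = nd.parent_node
            return next(n for n in anc_a if n in anc_b).distance_from_root()

        for a, b in itertools.combinations(labels, 2):
            expected = 2 * (h - mrca_root_dist(a, b))
            assert pm.distance(a, b) == pytest.approx(expected, abs=1e-8)

    def test_four_point_condition(self, dataset):
        labels = sorted(tip_labels(dataset.tree))[:8]
        pm = patristic_matrix(dataset.tree, labels)
        d = pm.distance
        for w, x, y, z in itertools.combinations(labels, 4):
            sums = sorted([d(w, x) + d(y, z), d(w, y) + d(x, z), d(w, z) + d(x, y)])
            assert sums[1] == pytest.approx(sums[2], abs=1e-9)

    def test_metric_properties(self, distmatrix, rng):
        idx = rng.choice(len(distmatrix.labels), size=15, replace=False)
        sub = distmatrix.values[np.ix_(idx, idx)]
        np.testing.assert_allclose(sub, sub.T, atol=1e-12)
        assert (np.diag(sub) == 0).all()
        for i, j, k in itertools.combinations(range(15), 3):
            assert sub[i, j] <= sub[i, k] + sub[k, j] + 1e-9

    def test_unknown_species(self, dataset):
        with pytest.raises(KeyError):
            patristic_matrix(dataset.tree, ["not_a_species"])


class TestSamplePairs:
    def test_exhaustive_below_cap(self):
        pairs = sample_pairs(list("ABCDE"), max_pairs=100, seed=0)
        assert len(pairs) == 10
        assert len({frozenset(p) for p in pairs}) == 10

    def test_two_species(self):
        assert sample_pairs(["A", "B"], seed=0) == [("A", "B")]

    def test_too_few(self):
        with pytest.raises(ValueError):
            sample_pairs(["A"])

    def test_subsample_distinct_and_uniform(self, rng):
        species = [f"s{i}" for i in range(20)]  # 190 pairs
        counts = {}
        runs = 3000
        for _ in range(runs):
            pairs = sample_pairs(species, max_pairs=100, seed=rng)
            assert len(pairs) == 100
            assert len({frozenset(p) for p in pairs}) == 100
            for p in pairs:
                counts[frozenset(p)] = counts.get(frozenset(p), 0) + 1
        expect = 100 / 190
        se = np.sqrt(expect * (1 - expect) / runs)
        freqs = np.array(list(counts.values())) / runs
        assert len(counts) == 190
        assert (np.abs(freqs - expect) < 3 * se + 1e-9).mean() > 0.98


class TestGrafting:
    TAX = [
        ("A", "famX", "ordX", "c"),
        ("B", "famX", "ordX", "c"),
        ("C", "famY", "ordX", "c"),
        ("D", "famY", "ordX", "c"),
        ("new1", "famX", "ordX", "c"),
        ("lonely", "famZ", "ordX", "c"),
        ("alien", "famQ", "ordQ", "c"),
    ]
    NWK = "((A:1,B:1):2,(C:2,D:2):1):0;"

    def test_basal_polytomy_placement(self):
        tree = read_newick_string(self.NWK)
        out = graft_species(tree, _tax(self.TAX), ["new1"], GraftMethod.basal_polytomy)
        pm = patristic_matrix(out)
        # new tip sits at the famX crown: distance 2 to both A and B
        assert pm.distance("new1", "A") == pytest.approx(2.0)
        assert pm.distance("new1", "B") == pytest.approx(2.0)
        assert pm.distance("new1", "C") == pytest.approx(6.0)
        depths = [lf.distance_from_root() for lf in out.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9

    def test_graft_nothing_is_identity(self):
        tree = read_newick_string(self.NWK)
        out = graft_species(tree, _tax(self.TAX), [], GraftMethod.basal_polytomy)
        assert sorted(tip_labels(out)) == sorted(tip_labels(tree))
        pm0 = patristic_matrix(tree)
        pm1 = patristic_matrix(out, pm0.labels)
        np.testing.assert_allclose(pm1.values, pm0.values, atol=1e-12)

    def test_existing_distances_preserved(self):
        tree = read_newick_string(self.NWK)
        pm0 = patristic_matrix(tree)
        out = graft_species(
            tree, _tax(self.TAX), ["new1", "lonely"], GraftMethod.taxonomy_constrained, seed=1
        )
        pm1 = patristic_matrix(out, pm0.labels)
        np.testing.assert_allclose(pm1.values, pm0.values, atol=1e-12)

    def test_single_tip_family_split(self):
        # famZ absent: taxonomy-constrained attaches 'lonely' at the order MRCA
        tree = read_newick_string(self.NWK)
        out = graft_species(
            tree, _tax(self.TAX), ["lonely"], GraftMethod.taxonomy_constrained
        )
        assert "lonely" in tip_labels(out)
        depths = [lf.distance_from_root() for lf in out.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9

    def test_unplaceable_species_error(self):
        tree = read_newick_string(self.NWK)
        with pytest.raises(UnplaceableSpeciesError, match="alien"):
            graft_species(tree, _tax(self.TAX), ["alien"], GraftMethod.taxonomy_constrained)
        with pytest.raises(UnplaceableSpeciesError):
            graft_species(tree, _tax(self.TAX), ["lonely"], GraftMethod.basal_polytomy)

    @pytest.mark.parametrize("method", list(GraftMethod))
    def test_prune_and_regraft_fullscale(self, dataset, method):
        """Remove ~68 of 292 species and re-attach them by each method."""
        tax = dataset.taxonomy
        rng = np.random.default_rng(5)
        counts = tax["family"].value_counts().to_dict()
        drop = []
        for sp in rng.permutation(tax["species"].to_numpy()):
            fam = tax.set_index("species")["family"][sp]
            if counts[fam] >= 2 and len(drop) < 68:
                drop.append(sp)
                counts[fam] -= 1
        pruned = dataset.tree.clone(depth=1)
        pruned.prune_taxa_with_labels(drop)
        out = graft_species(pruned, tax, drop, method, seed=11)
        assert sorted(tip_labels(out)) == sorted(tax["species"])
        depths = [lf.distance_from_root() for lf in out.leaf_node_iter()]
        assert np.ptp(depths) < 1e-6
        if method is not GraftMethod.taxonomy_constrained:
            pm = patristic_matrix(out)
            fam_of = dict(zip(tax["species"], tax["family"]))
            vals = pm.values + np.diag(np.full(len(pm.labels), np.inf))
            for sp in drop[:20]:
                i = pm.index[sp]
                nearest = pm.labels[int(np.argmin(vals[i]))]
                assert fam_of[nearest] == fam_of[sp]

    def test_basal_grafts_equidistant_outside_family(self):
        tree = read_newick_string(self.NWK)
        out = graft_species(
            tree, _tax(self.TAX), ["new1"], GraftMethod.basal_polytomy
        )
        pm = patristic_matrix(out)
        for outside in ("C", "D"):
            assert pm.distance("new1", outside) == pytest.approx(
                pm.distance("A", outside), abs=1e-12
            )
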