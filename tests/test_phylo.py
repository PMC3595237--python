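import numpy as np
import pandas as pd
import pytest

from osteomip import (
    PhylogeneticAnova,
    phylo_posthoc,
    phylogenetic_anova,
    read_newick,
    simulate_bm,
    write_newick,
)


def star_tree(n_tips: int, length: float = 1.0) -> "dendropy.Tree":
    tips = ",".join(f"t{i}:{length}" for i in range(n_tips))
    return read_newick(f"({tips});")


class TestNewickIO:
    def test_small_tree_hand_computed(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        depths = {l.taxon.label: l.distance_from_root() for l in tree.leaf_node_iter()}
        assert len(depths) == 3
        assert depths == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_malformed_newick_rejected(self):
        with pytest.raises(Exception):
            read_newick("((A:1,B:1:1,C:2);")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_newick("((A:1,A:1):1,C:2);")

    def test_round_trip_preserves_lengths(self):
        text = "((A:1.25,B:1.25):0.75,(C:0.5,D:0.5):1.5);"
        tree = read_newick(text)
        again = read_newick(write_newick(tree))
        d1 = {l.taxon.label: l.distance_from_root() for l in tree.leaf_node_iter()}
        d2 = {l.taxon.label: l.distance_from_root() for l in again.leaf_node_iter()}
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], abs=1e-9)

    def test_pairwise_distances_match_brute_force_path_sums(self):
        """Random small trees: dendropy's distance matrix equals summing edge
        lengths along tip-to-MRCA paths by hand."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            tree = _random_tree(rng, n_tips=int(rng.integers(3, 9)))
            pdm = tree.phylogenetic_distance_matrix()
            leaves = list(tree.leaf_node_iter())
            for i in range(len(leaves)):
                for j in range(i + 1, len(leaves)):
                    expected = _brute_force_distance(tree, leaves[i], leaves[j])
                    got = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
                    assert got == pytest.approx(expected, abs=1e-9)

    def test_nexus_block_accepted(self):
        text = "#NEXUS\nBEGIN TREES;\nTREE t = ((A:1,B:1):1,C:2);\nEND;\n"
        tree = read_newick(text)
        assert len(tree.leaf_nodes()) == 3


def _random_tree(rng, n_tips):
    """Random binary newick built by repeated pair-joining."""
    nodes = [f"t{i}:{rng.uniform(0.1, 2.0):.4f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.4f}")
    return read_newick(nodes[0] + ";")


def _brute_force_distance(tree, leaf_a, leaf_b):
    """Sum of edge lengths along the path a -> MRCA -> b, via parent pointers."""
    # climb from each leaf until the first common ancestor
    seen = {}
    node, d = leaf_a, 0.0
    while node.parent_node is not None:
        d += node.edge.length or 0.0
        node = node.parent_node
        seen[id(node)] = d
    node, d = leaf_b, 0.0
    while node.parent_node is not None:
        d += node.edge.length or 0.0
        node = node.parent_node
        if id(node) in seen:
            return d + seen[id(node)]
    return d


class TestSimulateBM:
    def test_zero_length_star_returns_root_state(self):
        tree = star_tree(5, length=0.0)
        vals = simulate_bm(tree, rate=1.0, root_state=3.5, seed=0, size=10)
        assert np.allclose(vals.to_numpy(), 3.5)

    def test_tip_variance_matches_rate_times_depth(self):
        tree = read_newick("(A:2.5);")
        reps = simulate_bm(tree, rate=1.7, root_state=0.0, seed=1, size=10_000)["A"]
        var = reps.var(ddof=1)
        expected = 1.7 * 2.5
        se = expected * np.sqrt(2.0 / (10_000 - 1))  # SE of a normal variance estimate
        assert abs(var - expected) < 3 * se

    def test_sister_tip_correlation_equals_shared_depth_fraction(self):
        """Two tips diverging at depth d of total T correlate as d/T under BM."""
        tree = read_newick("((A:2,B:2):3,C:5);")
        reps = simulate_bm(tree, rate=1.0, seed=2, size=10_000)
        r = np.corrcoef(reps["A"], reps["B"])[0, 1]
        assert r == pytest.approx(3.0 / 5.0, abs=0.03)
        r_out = np.corrcoef(reps["A"], reps["C"])[0, 1]
        assert abs(r_out) < 0.05

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_bm(star_tree(3), rate=-1.0)

    def test_seed_reproducibility(self):
        tree = star_tree(4)
        a = simulate_bm(tree, seed=7, size=50)
        b = simulate_bm(tree, seed=7, size=50)
        pd.testing.assert_frame_equal(a, b)


class TestPhylogeneticAnova:
    def test_fixture_tree_reproduces_species_mean_f(self, fixture_tree, species_table):
        """Observed F on the published species means matches the printed
        species-level ANOVA: F = 4.152 on df (2, 11)."""
        values = dict(zip(species_table["species_label"], species_table["max_mean"]))
        groups = dict(zip(species_table["species_label"], species_table["gait"]))
        res = phylogenetic_anova(fixture_tree, values, groups, nsim=200, seed=0)
        assert res.df == (2, 11)
        assert res.F_obs == pytest.approx(4.152, rel=0.02)

    def test_phylo_p_exceeds_parametric_p_for_clustered_groups(
        self, fixture_tree, species_table
    ):
        """Gait groups cluster on the tree (bipeds are all macropods), so the
        Brownian null inflates the F tail relative to the iid null."""
        values = dict(zip(species_table["species_label"], species_table["max_mean"]))
        groups = dict(zip(species_table["species_label"], species_table["gait"]))
        res = phylogenetic_anova(fixture_tree, values, groups, nsim=5000, seed=1)
        assert res.p_phylo > res.p_param
        assert res.p_phylo > 0.05  # significance disappears under the tree null

    def test_star_tree_matches_parametric_p(self):
        """On a star tree BM tip values are iid normal, so the simulation p
        converges to the parametric p (within 3 Monte-Carlo SE)."""
        rng = np.random.default_rng(3)
        tree = star_tree(18)
        y = rng.normal(size=18)
        groups = {f"t{i}": ("a", "b", "c")[i % 3] for i in range(18)}
        values = {f"t{i}": y[i] for i in range(18)}
        res = phylogenetic_anova(tree, values, groups, nsim=10_000, seed=4)
        se = np.sqrt(res.p_param * (1 - res.p_param) / res.nsim)
        assert abs(res.p_phylo - res.p_param) < 3 * se + 1.0 / res.nsim

    def test_relabeling_invariance(self, fixture_tree, species_table):
        values = dict(zip(species_table["species_label"], species_table["max_mean"]))
        groups = dict(zip(species_table["species_label"], species_table["gait"]))
        res1 = phylogenetic_anova(fixture_tree, values, groups, nsim=100, seed=5)
        renamed = {s: {"B": "g1", "AQ": "g2", "TQ": "g3"}[g] for s, g in groups.items()}
        res2 = phylogenetic_anova(fixture_tree, values, renamed, nsim=100, seed=5)
        assert res1.F_obs == pytest.approx(res2.F_obs, rel=1e-12)

    def test_missing_tip_data_rejected(self, fixture_tree, species_table):
        values = dict(zip(species_table["species_label"], species_table["max_mean"]))
        groups = dict(zip(species_table["species_label"], species_table["gait"]))
        del values["Wallabia_bicolor"]
        with pytest.raises(ValueError, match="Wallabia_bicolor"):
            phylogenetic_anova(fixture_tree, values, groups, nsim=10)

    def test_rate_scale_invariance_of_null(self):
        """F is scale-free: the same seed gives the identical null F sample
        whatever the BM rate, justifying a fixed rate of 1."""
        tree = star_tree(9)
        from osteomip.phylo import _f_stats_vectorized

        X1 = simulate_bm(tree, rate=1.0, seed=11, size=500).to_numpy()
        X2 = simulate_bm(tree, rate=7.3, seed=11, size=500).to_numpy()
        gi = np.array([0, 1] * 4 + [0])
        f1 = _f_stats_vectorized(X1, gi, 2)
        f2 = _f_stats_vectorized(X2, gi, 2)
        assert np.allclose(f1, f2)

    def test_seeded_result_reproducible(self, fixture_tree, species_table):
        values = dict(zip(species_table["species_label"], species_table["max_mean"]))
        groups = dict(zip(species_table["species_label"], species_table["gait"]))
        r1 = phylogenetic_anova(fixture_tree, values, groups, nsim=500, seed=8)
        r2 = phylogenetic_anova(fixture_tree, values, groups, nsim=500, seed=8)
        assert r1.p_phylo == r2.p_phylo
        assert np.array_equal(r1.null_F_sample, r2.null_F_sample)


class TestPhyloPosthoc:
    def test_identical_groups_on_star_tree_nonsignificant(self):
        rng = np.random.default_rng(9)
        tree = star_tree(12)
        values = {f"t{i}": rng.normal() for i in range(12)}
        groups = {f"t{i}": "ab"[i % 2] for i in range(12)}
        ph = phylo_posthoc(tree, values, groups, nsim=2000, seed=10)
        assert (ph["p_adj"] > 0.05).all()

    def test_holm_adjustment_monotone(self, fixture_tree, species_table):
        values = dict(zip(species_table["species_label"], species_table["max_mean"]))
        groups = dict(zip(species_table["species_label"], species_table["gait"]))
        ph = phylo_posthoc(fixture_tree, values, groups, nsim=1000, seed=11)
        assert (ph["p_adj"] >= ph["p_phylo"] - 1e-12).all()
        assert (ph["p_adj"] <= 1.0).all()

    def test_fixture_pairwise_all_nonsignificant(self, fixture_tree, species_table):
        """On the timed tree, none of the three pairwise gait contrasts of the
        species means stays significant."""
        for col in ("max_mean", "second_mean"):
            values = dict(zip(species_table["species_label"], species_table[col]))
            groups = dict(zip(species_table["species_label"], species_table["gait"]))
            ph = phylo_posthoc(fixture_tree, values, groups, nsim=5000, seed=12)
            assert (ph["p_phylo"] > 0.05).all()


class TestModelWrapper:
    def test_fit_summary_and_posthoc(self, fixture_tree, species_table):
        data = pd.DataFrame(
            {
                "species": species_table["species_label"],
                "gait": species_table["gait"],
                "max_mean": species_table["max_mean"],
            }
        )
        model = PhylogeneticAnova.from_dataframe(fixture_tree, data, "max_mean")
        res = model.fit(nsim=500, seed=13)
        assert res.posthoc is not None and len(res.posthoc) == 3
        text = res.summary()
        assert "phylogenetic p" in text and "post hoc" in text

    def test_null_distribution_plot(self, fixture_tree, species_table, tmp_path):
        import matplotlib

        matplotlib.use("Agg", force=True)
        data = pd.DataFrame(
            {
                "species": species_table["species_label"],
                "gait": species_table["gait"],
                "max_mean": species_table["max_mean"],
            }
        )
        res = PhylogeneticAnova.from_dataframe(fixture_tree, data, "max_mean").fit(
            nsim=200, seed=14
        )
        ax = res.plot_null()
        out = tmp_path / "null.png"
        ax.figure.savefig(out)
        assert out.stat().st_size > 0


class TestPhytoolsCrossCheck:
    def test_matches_phytools_phylanova(self, fixture_tree, species_table, tmp_path):
        """Independent oracle: R phytools' simulation-based phylogenetic ANOVA
        on the same tree and species means gives the same F and a simulation
        p within Monte-Carlo error."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        from osteomip import write_newick

        tree_file = tmp_path / "tree.nwk"
        tree_file.write_text(write_newick(fixture_tree))
        csv = tmp_path / "species.csv"
        species_table.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            f"""
            suppressMessages(library(phytools))
            tree <- read.tree("{tree_file}")
            sp <- read.csv("{csv}")
            x <- setNames(sp$gait, sp$species_label)
            y <- setNames(sp$max_mean, sp$species_label)
            set.seed(1)
            res <- phylANOVA(tree, x, y, nsim=4000, posthoc=FALSE)
            cat(res$F, res$Pf, "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        f_ref, p_ref = map(float, out.stdout.split()[-2:])

        values = dict(zip(species_table["species_label"], species_table["max_mean"]))
        groups = dict(zip(species_table["species_label"], species_table["gait"]))
        res = phylogenetic_anova(fixture_tree, values, groups, nsim=4000, seed=2)
        assert res.F_obs == pytest.approx(f_ref, rel=1e-6)
        se = np.sqrt(p_ref * (1 - p_ref) * (1 / 4000 + 1 / 4000))
        assert abs(res.p_phylo - p_ref) < 4 * se
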