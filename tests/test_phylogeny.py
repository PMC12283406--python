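"""Tree building, Fitch parsimony, branch adjustment, clock scaling, MRCA."""

import copy
import itertools

import numpy as np
import pandas as pd
import pytest

from colonyphylo import phylogeny, signatures as sig, synthetic
from colonyphylo.phylogeny import (build_tree, branch_signature_counts,
                                   exclude_signature_mutations,
                                   handle_negative_counts, make_ultrametric,
                                   node_exposures, place_bulk_sample,
                                   reconstruct_ancestral)
from colonyphylo.synthetic import CohortConfig, simulate_genealogy
from colonyphylo.tree import collapse_unsupported_edges, robinson_foulds


def gm_from_dict(d, colonies=None):
    """{'A': {'m1', 'm2'}, ...} -> binary genotype DataFrame."""
    colonies = colonies or sorted(d)
    sites = sorted(set().union(*d.values())) if d else []
    return pd.DataFrame(
        [[1 if s in d[c] else 0 for s in sites] for c in colonies],
        index=colonies, columns=sites)


class TestBuildTree:
    def test_three_colony_example(self):
        gm = gm_from_dict({"A": {"m1", "m2"}, "B": {"m1", "m3"}, "C": {"m4"}})
        tree = build_tree(gm)
        # topology ((A,B),C) with m1 on the A+B stem
        ab = tree.node_by_id(tree.site_to_branch["m1"])
        assert sorted(ab.leaf_names()) == ["A", "B"]
        assert robinson_foulds(
            tree.root,
            synthetic_tree_from_newick("((A,B),C);")) == 0

    def test_identical_colonies_zero_length_siblings(self):
        gm = gm_from_dict({"A": {"m1"}, "B": {"m1"}, "C": set()})
        tree = build_tree(gm)
        a = [n for n in tree.root.preorder() if n.name == "A"][0]
        b = [n for n in tree.root.preorder() if n.name == "B"][0]
        assert a.parent is b.parent
        assert len(a.mutations) == len(b.mutations) == 0

    def test_every_mutation_assigned_once(self, small_truth):
        gm = synthetic.true_genotype_matrix(small_truth)
        tree = build_tree(gm)
        assert tree.n_assigned_mutations() == gm.shape[1]
        assert sorted(tree.site_to_branch) == sorted(map(str, gm.columns))

    @pytest.mark.parametrize("seed", range(10))
    def test_rf_zero_on_noise_free_cohorts(self, seed):
        truth = simulate_genealogy(CohortConfig(
            n_colonies=50, donor_age=45.0, seed=seed, germline_count=0,
            inculture_rate=0.0, artifact_count=0))
        synthetic.simulate_spectra(truth)
        gm = synthetic.true_genotype_matrix(truth)
        tree = build_tree(gm)
        true_collapsed = collapse_unsupported_edges(copy.deepcopy(truth.tree))
        assert robinson_foulds(tree.root, true_collapsed) == 0
        assert not tree.conflicting_sites

    def test_conflicting_site_flagged_and_assigned(self):
        gm = gm_from_dict({
            "A": {"m1", "m2", "x"}, "B": {"m1", "m2"},
            "C": {"m3", "x"}, "D": {"m3"},
        })
        tree = build_tree(gm)
        assert "x" in tree.conflicting_sites
        # still assigned exactly once, at the carriers' MRCA
        node = tree.node_by_id(tree.site_to_branch["x"])
        assert set(node.leaf_names()) >= {"A", "C"}

    def test_all_missing_column_dropped(self):
        gm = gm_from_dict({"A": {"m1"}, "B": set()})
        gm["m_gone"] = np.nan
        tree = build_tree(gm)
        assert tree.dropped_sites == ["m_gone"]


def synthetic_tree_from_newick(nwk):
    from colonyphylo.tree import parse_newick
    return parse_newick(nwk)


class TestFitch:
    def test_mutation_in_all_tips(self):
        gm = gm_from_dict({"A": {"m"}, "B": {"m"}, "C": {"m"}})
        tree = build_tree(gm)
        anc = reconstruct_ancestral(tree, gm)
        for node in tree.root.preorder():
            state = anc.states[node.node_id][0]
            assert state == (0 if node.parent is None else 1)
        assert anc.changes[0] == 1      # single gain on the root edge

    def test_private_mutation_only_on_tip(self):
        gm = gm_from_dict({"A": {"m"}, "B": set(), "C": set()})
        tree = build_tree(gm)
        anc = reconstruct_ancestral(tree, gm)
        for node in tree.root.preorder():
            expected = 1 if (node.is_leaf and node.name == "A") else 0
            assert anc.states[node.node_id][anc.sites.index("m")] == expected

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_minimum(self, seed):
        """Fitch changes equal brute-force minimum over internal labelings
        (root forced to absent) on random 6-tip instances."""
        rng = np.random.default_rng(seed)
        colonies = list("ABCDEF")
        d = {c: {f"m{j}" for j in range(6) if rng.random() < 0.5}
             for c in colonies}
        if not set().union(*d.values()):
            d["A"].add("m0")
        gm = gm_from_dict(d)
        tree = build_tree(gm)
        anc = reconstruct_ancestral(tree, gm)

        internals = [n for n in tree.root.preorder()
                     if not n.is_leaf and n.parent is not None]
        tips = {n.name: n for n in tree.root.leaves()}
        for j, site in enumerate(anc.sites):
            best = np.inf
            for lab in itertools.product([0, 1], repeat=len(internals)):
                assign = {id(tree.root): 0}
                for node, v in zip(internals, lab):
                    assign[id(node)] = v
                for name, node in tips.items():
                    assign[id(node)] = int(gm.loc[name, site])
                changes = sum(
                    assign[id(n)] != assign[id(n.parent)]
                    for n in tree.root.preorder() if n.parent is not None)
                best = min(best, changes)
            assert anc.changes[j] == best
            # the emitted labeling achieves that score
            emitted = sum(
                anc.states[n.node_id][j] != anc.states[n.parent.node_id][j]
                for n in tree.root.preorder() if n.parent is not None)
            assert emitted == best


class TestNegativeCounts:
    def test_small_negative_zeroed(self):
        res = handle_negative_counts(-0.5, 200)
        assert res.value == 0.0 and not res.flagged

    def test_below_five_percent_zeroed(self):
        res = handle_negative_counts(-8, 200)
        assert res.value == 0.0 and not res.flagged

    def test_large_negative_flagged(self):
        res = handle_negative_counts(-15, 200)
        assert res.flagged

    def test_positive_passthrough(self):
        assert handle_negative_counts(20.0, 200) == (20.0, False)


class TestBranchSignatureCounts:
    def test_child_minus_parent(self, small_truth, reference_set):
        gm = synthetic.true_genotype_matrix(small_truth)
        tree = build_tree(gm)
        som = small_truth.mutations[small_truth.mutations["mut_class"] == "somatic"]
        table = som.set_index(small_truth.site_keys()[som.index])
        expos = node_exposures(tree, table, reference_set)
        counts = branch_signature_counts(tree, expos)
        sig_cols = [c for c in counts.columns if c != "flagged"]
        # per-branch totals approximate molecular lengths (refit tolerance)
        for node in tree.root.preorder():
            if node.parent is None:
                continue
            got = counts.loc[node.node_id, sig_cols].sum()
            assert got == pytest.approx(len(node.mutations), rel=0.25, abs=8)

    def test_equal_exposures_zero(self):
        gm = gm_from_dict({"A": {"m1"}, "B": set()})
        tree = build_tree(gm)
        expos = {n.node_id: pd.Series({"SBS1": 50.0, "SBS5": 10.0})
                 for n in tree.root.preorder()}
        counts = branch_signature_counts(tree, expos)
        assert (counts[["SBS1", "SBS5"]].to_numpy() == 0).all()


class TestUltrametric:
    def test_two_tip_scaling(self):
        gm = gm_from_dict({"A": set("m" + str(i) for i in range(100)),
                           "B": set("x" + str(i) for i in range(120))})
        tree = build_tree(gm)
        make_ultrametric(tree, 60.0)
        for tip in tree.root.leaves():
            assert tip.time == pytest.approx(60.0)
        # implied per-tip scalings: 60/100 and 60/120 years per mutation
        a = [n for n in tree.root.preorder() if n.name == "A"][0]
        b = [n for n in tree.root.preorder() if n.name == "B"][0]
        assert 60.0 / len(a.mutations) == pytest.approx(0.6)
        assert 60.0 / len(b.mutations) == pytest.approx(0.5)

    def test_clocklike_tree_single_constant(self, small_truth):
        gm = synthetic.true_genotype_matrix(small_truth)
        tree = build_tree(gm)
        make_ultrametric(tree, small_truth.config.donor_age)
        age = small_truth.config.donor_age
        for node in tree.root.preorder():
            assert node.time is not None
            assert -1e-9 <= node.time <= age + 1e-9

    def test_monotonicity_invariant(self, small_truth):
        gm = synthetic.true_genotype_matrix(small_truth)
        tree = build_tree(gm)
        make_ultrametric(tree, 40.0)
        worst = max((n.parent.time - n.time) for n in tree.root.preorder()
                    if n.parent is not None)
        assert worst <= 0

    def test_topology_preserved(self, small_truth):
        gm = synthetic.true_genotype_matrix(small_truth)
        t1 = build_tree(gm)
        before = t1.root.to_newick(None)
        make_ultrametric(t1, 40.0)
        assert t1.root.to_newick(None) == before


class TestExcludeSignature:
    def _tree_with_attribution(self, sigs):
        gm = gm_from_dict({"A": {"m1", "m2"}, "B": {"m1"}})
        tree = build_tree(gm)
        att = pd.DataFrame({
            "assigned_signature": sigs,
            "assigned_probability": [0.9] * len(sigs),
        }, index=["m1", "m2"])
        return tree, att

    def test_no_attributed_mutations_unchanged(self):
        tree, att = self._tree_with_attribution(["SBS5", "SBS1"])
        exclude_signature_mutations(tree, att, "SBSC")
        for node in tree.root.preorder():
            assert node.clock_count == len(node.mutations)

    def test_excluded_reduces_clock(self):
        tree, att = self._tree_with_attribution(["SBS5", "SBSC"])
        exclude_signature_mutations(tree, att, "SBSC")
        a = [n for n in tree.root.preorder() if n.name == "A"][0]
        assert a.clock_count == len(a.mutations) - 1

    def test_threshold_one_requires_certainty(self):
        tree, att = self._tree_with_attribution(["SBSC", "SBSC"])
        exclude_signature_mutations(tree, att, "SBSC", posterior_threshold=1.0)
        for node in tree.root.preorder():
            assert node.clock_count == len(node.mutations)

    def test_burst_cohort_clock_rate_recovered(self, reference_set):
        """After excluding melphalan-attributed mutations the root-to-tip
        clock count matches clock_rate x age within 10%."""
        cfg = CohortConfig(n_colonies=25, donor_age=60.0, seed=21,
                           melphalan_exposure=(50.0, 400.0),
                           germline_count=0, inculture_rate=0.0,
                           artifact_count=0)
        truth = simulate_genealogy(cfg)
        synthetic.simulate_spectra(truth, reference_set)
        gm = synthetic.true_genotype_matrix(truth)
        tree = build_tree(gm)
        som = truth.mutations[truth.mutations["mut_class"] == "somatic"]
        table = som.set_index(truth.site_keys()[som.index])
        expo, _ = sig.fit_exposures(sig.count_contexts(table), reference_set)
        att = sig.attribute_mutations(table, expo, reference_set)
        exclude_signature_mutations(tree, att, "SBSC")
        clock_tip_counts = []
        for tip in tree.root.leaves():
            clock_tip_counts.append(
                sum(n.clock_count for n in tip.path_from_root()
                    if n.clock_count is not None))
        mean_clock = np.mean(clock_tip_counts)
        assert mean_clock == pytest.approx(17.2 * 60, rel=0.10)


class TestPlaceBulk:
    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_tip_origin(self, small_truth, seed):
        rng = np.random.default_rng(seed)
        gm = synthetic.true_genotype_matrix(small_truth)
        tree = build_tree(gm)
        tips = small_truth.tree.leaves()
        origin = tips[rng.integers(len(tips))]
        bulk = synthetic.simulate_bulk_tmn(small_truth, origin, n_private=50,
                                           purity=0.8, seed=seed)
        res = place_bulk_sample(tree, bulk)
        assert res.found
        placed = tree.node_by_id(res.branch_node_id)
        assert placed.leaf_names() == [origin.name]

    def test_root_adjacent_bulk(self, small_truth):
        node = small_truth.tree.children[0]
        while len(node.mutations) == 0:
            node = node.children[0]
        gm = synthetic.true_genotype_matrix(small_truth)
        tree = build_tree(gm)
        bulk = synthetic.simulate_bulk_tmn(small_truth, node, n_private=20,
                                           purity=0.9, seed=3)
        res = place_bulk_sample(tree, bulk)
        assert res.found
        placed = tree.node_by_id(res.branch_node_id)
        assert set(placed.leaf_names()) == set(node.leaf_names())

    def test_no_overlap_no_mrca(self, small_truth):
        gm = synthetic.true_genotype_matrix(small_truth)
        tree = build_tree(gm)
        bulk = pd.DataFrame({
            "chrom": ["1"], "pos": [42], "ref": ["C"], "alt": ["T"],
            "vaf": [0.4], "alt_depth": [20], "total_depth": [50]})
        res = place_bulk_sample(tree, bulk)
        assert res.status == "no_mrca"
        assert res.branch_node_id is None


def test_molecular_lengths_sum_to_assigned(small_truth):
    gm = synthetic.true_genotype_matrix(small_truth)
    tree = build_tree(gm)
    total = sum(n.branch_length("molecular") for n in tree.root.preorder())
    assert total == gm.shape[1]
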