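"""Mk-model pruning likelihood, rate fitting and marginal reconstruction."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from wolcall import calligrapha
from wolcall.ancestral import (
    TraitModel,
    TraitTree,
    encode_trait_states,
    fit_rate,
    marginal_posteriors,
    pruning_likelihood,
)
from wolcall.coinfection import classify_cohort

ST_GROUPS = {st.st_id: st.group for st in calligrapha.sequence_types()}


def brute_force(trait_tree: TraitTree, model: TraitModel):
    """Exhaustive joint summation over all ancestral-state assignments."""
    nodes = list(trait_tree.tree.preorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    tips = [n for n in nodes if n.is_leaf()]
    labels = trait_tree.state_labels
    k = len(labels)
    total = 0.0
    node_post = {id(n): np.zeros(k) for n in nodes}
    tip_choices = [
        [labels.index(s) for s in sorted(trait_tree.tip_states[t.taxon.label])]
        for t in tips
    ]
    for internal_states in itertools.product(range(k), repeat=len(internals)):
        for tip_states in itertools.product(*tip_choices):
            state = dict(zip(map(id, internals), internal_states))
            state.update(zip(map(id, tips), tip_states))
            p = 1.0 / k
            for n in nodes:
                if n.parent_node is not None:
                    mat = model.transition_matrix(n.edge.length or 0.0)
                    p *= mat[state[id(n.parent_node)], state[id(n)]]
            total += p
            for n in nodes:
                node_post[id(n)][state[id(n)]] += p
    return math.log(total), {nid: post / total for nid, post in node_post.items()}, nodes


def random_topology(rng, n_tips, states, labels):
    taxa = [f"t{i}" for i in range(n_tips)]
    nodes = [dendropy.Node(taxon=dendropy.Taxon(label=t)) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        b, a = nodes.pop(j), nodes.pop(i)
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.05, 1.5))
        nodes.append(parent)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.update_taxon_namespace()
    tip_states = {t: frozenset({rng.choice(labels)}) for t in taxa}
    # sprinkle one ambiguity set to exercise that path
    tip_states[taxa[0]] = frozenset(rng.choice(labels, size=2, replace=False))
    return TraitTree(tree, tip_states, tuple(labels)), states


class TestPruningOracle:
    @pytest.mark.parametrize("n_tips", [3, 4, 5, 6])
    @pytest.mark.parametrize("k", [2, 4])
    def test_likelihood_and_marginals_match_bruteforce(self, n_tips, k):
        labels = tuple("WXYZ"[:k])
        rng = np.random.default_rng(100 * n_tips + k)
        trait_tree, _ = random_topology(rng, n_tips, None, list(labels))
        model = TraitModel(rate=float(rng.uniform(0.1, 2.0)), n_states=k)
        ll = pruning_likelihood(trait_tree, model)
        ll_brute, post_brute, nodes = brute_force(trait_tree, model)
        assert ll == pytest.approx(ll_brute, rel=1e-10)
        posts = marginal_posteriors(trait_tree, model)
        for post, node in zip(posts, trait_tree.tree.preorder_node_iter()):
            expected = post_brute[id(node)]
            for i, label in enumerate(trait_tree.state_labels):
                assert post.distribution[label] == pytest.approx(
                    expected[i], abs=1e-10
                )

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(3)
        trait_tree, _ = random_topology(rng, 6, None, ["X", "Y"])
        posts = marginal_posteriors(trait_tree, TraitModel(0.7, 2))
        for post in posts:
            assert sum(post.distribution.values()) == pytest.approx(1.0, abs=1e-9)

    def test_contradictory_constraints_raise(self):
        tt = TraitTree.from_newick(
            "(a:1,b:1):0;", {"a": "X", "b": "Y"}, ["X", "Y"]
        )
        with pytest.raises(ValueError):
            pruning_likelihood(tt, TraitModel(rate=0.0, n_states=2))


class TestInvariances:
    def test_rotation_of_children(self):
        left = "((a:0.2,b:0.4):0.3,c:0.8):0.0;"
        right = "(c:0.8,(b:0.4,a:0.2):0.3):0.0;"
        states = {"a": "X", "b": "Y", "c": "X"}
        model = TraitModel(0.6, 2)
        t1 = TraitTree.from_newick(left, states, ["X", "Y"])
        t2 = TraitTree.from_newick(right, states, ["X", "Y"])
        assert pruning_likelihood(t1, model) == pytest.approx(
            pruning_likelihood(t2, model), rel=1e-12
        )
        p1 = {p.node_id: p.distribution for p in marginal_posteriors(t1, model)}
        p2 = {p.node_id: p.distribution for p in marginal_posteriors(t2, model)}
        for tip in states:
            assert p1[tip] == p2[tip]

    def test_high_rate_limit_approaches_root_prior(self):
        tt = TraitTree.from_newick(
            "((a:1,b:1):1,(c:1,d:1):1):0;",
            {"a": "X", "b": "Y", "c": "X", "d": "Y"}, ["X", "Y"],
        )
        posts = marginal_posteriors(tt, TraitModel(rate=500.0, n_states=2))
        root = posts[0]
        assert root.distribution["X"] == pytest.approx(0.5, abs=1e-6)

    def test_low_rate_homogeneous_tips_point_mass(self):
        tt = TraitTree.from_newick(
            "((a:1,b:1):1,c:2):0;", {"a": "X", "b": "X", "c": "X"}, ["X", "Y"]
        )
        posts = marginal_posteriors(tt, TraitModel(rate=1e-9, n_states=2))
        for post in posts:
            assert post.distribution["X"] == pytest.approx(1.0, abs=1e-6)


class TestFitRate:
    def test_identical_tips_rate_zero(self):
        tt = TraitTree.from_newick("(a:1,b:2):0;", {"a": "X", "b": "X"}, ["X", "Y"])
        assert fit_rate(tt).rate == 0.0

    def test_matches_dense_grid_search(self):
        tt = TraitTree.from_newick(
            "((a:0.1,b:0.1):0.8,c:0.9):0.0;", {"a": "X", "b": "X", "c": "Y"},
            ["X", "Y"],
        )
        fitted = fit_rate(tt)
        grid = np.logspace(-3, 2, 40_000)
        lls = [pruning_likelihood(tt, TraitModel(r, 2)) for r in grid]
        best = grid[int(np.argmax(lls))]
        assert fitted.rate == pytest.approx(best, rel=1e-3)
        assert pruning_likelihood(tt, fitted) >= max(lls) - 1e-10

    def test_rate_recovery_from_simulated_histories(self):
        """Median relative error of the ML rate over simulated 200-tip trees
        stays under 20%.  The rate is chosen so a coalescent genealogy (total
        length ~2 ln n) carries a few dozen expected changes — fewer changes
        make any estimator proportionally noisier."""
        from wolcall.simulate import SimulationConfig, simulate_genealogy

        true_rate = 2.5
        errors = []
        for seed in range(16):
            genealogy = simulate_genealogy(
                SimulationConfig(seed=seed, n_haplotypes=200, n_regions=1,
                                 horizontal_rate_by_region={"r": 0.0},
                                 resident_by_region={"r": "wCallB1"})
            )
            rng = np.random.default_rng(seed)
            model = TraitModel(true_rate, 2)
            states = {}
            for node in genealogy.tree.preorder_node_iter():
                if node.parent_node is None:
                    node.sim_state = 0
                else:
                    mat = model.transition_matrix(node.edge.length or 0.0)
                    node.sim_state = int(
                        rng.choice(2, p=mat[node.parent_node.sim_state])
                    )
                if node.is_leaf():
                    states[node.taxon.label] = "XY"[node.sim_state]
            tt = TraitTree(genealogy.tree, {k: frozenset({v}) for k, v in states.items()},
                           ("X", "Y"))
            fitted = fit_rate(tt)
            errors.append(abs(fitted.rate - true_rate) / true_rate)
        assert np.median(errors) < 0.2


class TestTraitEncoding:
    @pytest.fixture()
    def resolved(self, resolved_cohort):
        return resolved_cohort[0]

    def test_full_st_scheme_has_31_states(self, resolved):
        """15 single-ST states + 15 clean double combinations + uninfected;
        the mosaic variant folds into its parent ST."""
        inventory = [st.st_id for st in calligrapha.sequence_types()]
        _, labels = encode_trait_states(resolved, "full_st", st_inventory=inventory)
        assert len(labels) == 31
        assert "uninfected" in labels
        singles = [l for l in labels if "+" not in l and l != "uninfected"]
        combos = [l for l in labels if "+" in l]
        assert len(singles) == 15 and len(combos) == 15
        assert "wCallA1+wCallB1r" not in labels

    def test_grouped_scheme_four_states_and_ambiguity(self, resolved):
        tips, labels = encode_trait_states(resolved, "grouped", st_groups=ST_GROUPS)
        assert set(labels) == {"uninfected", "A", "B", "C"}
        doubles = [s for s in tips.values() if {"A", "C"} <= s or {"A", "B"} <= s]
        assert doubles  # double infections appear as two-group ambiguity sets

    def test_uninfected_state_in_both_schemes(self, resolved):
        for scheme in ("full_st", "grouped"):
            tips, labels = encode_trait_states(resolved, scheme, st_groups=ST_GROUPS)
            uninfected_tips = [
                tip for tip, states in tips.items() if states == {"uninfected"}
            ]
            assert uninfected_tips, scheme


class TestRootRecovery:
    def test_modal_root_state_recovered_at_low_rate(self):
        """Simulating states down coalescent trees at a low rate, the modal
        reconstructed root state matches the truth in >= 80% of replicates."""
        from wolcall.simulate import SimulationConfig, simulate_genealogy

        hits = trials = 0
        for seed in range(200):
            genealogy = simulate_genealogy(
                SimulationConfig(seed=seed, n_haplotypes=25, n_regions=1,
                                 horizontal_rate_by_region={"r": 0.0},
                                 resident_by_region={"r": "wCallB1"})
            )
            rng = np.random.default_rng(10_000 + seed)
            model = TraitModel(rate=0.15, n_states=2)
            true_root = int(rng.integers(0, 2))
            states = {}
            for node in genealogy.tree.preorder_node_iter():
                if node.parent_node is None:
                    node.sim_state = true_root
                else:
                    mat = model.transition_matrix(node.edge.length or 0.0)
                    node.sim_state = int(rng.choice(2, p=mat[node.parent_node.sim_state]))
                if node.is_leaf():
                    states[node.taxon.label] = "XY"[node.sim_state]
            tt = TraitTree(
                genealogy.tree, {k: frozenset({v}) for k, v in states.items()}, ("X", "Y")
            )
            fitted = fit_rate(tt)
            root_post = marginal_posteriors(tt, fitted)[0]
            trials += 1
            hits += root_post.modal_state == "XY"[true_root]
        assert hits / trials >= 0.8
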