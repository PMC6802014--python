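"""Fixed-tree marginal ancestral-state reconstruction of infection states.

Infection is treated as a discrete character evolving along a fixed, rooted
host genealogy under the symmetric k-state Markov model (Mk): all state
exchanges share one instantaneous rate, so the transition probability over a
branch of length t has the closed form

    P(same)   = 1/k + (k-1)/k * exp(-k*mu*t)
    P(differ) = 1/k -   1/k   * exp(-k*mu*t)

with equilibrium frequencies 1/k.  Tips may carry ambiguity sets (a double
infection coded as the set of its two strain groups): their partial
likelihoods are 1 on the members and 0 elsewhere.  The exchange rate is
fitted by bounded 1-D maximum likelihood on the pruning likelihood; marginal
node posteriors come from the standard post-order (partials) plus pre-order
(outside messages) sweep.

Two coding schemes mirror endosymbiont-survey practice: ``full_st`` gives
one state per distinct ST or ST combination plus "uninfected"; ``grouped``
collapses to {uninfected, A, B, C} with doubles as two-group ambiguity sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from wolcall.coinfection import AMBIGUOUS, DOUBLE, SINGLE, UNINFECTED, SpecimenRecord

#: Branch lengths of zero are clamped here to keep P(t) non-singular.
MIN_BRANCH_LENGTH = 1e-9


@dataclass
class TraitTree:
    """A rooted tree with tip state (or ambiguity-set) assignments."""

    tree: dendropy.Tree
    tip_states: dict[str, frozenset[str]]
    state_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = set(self.state_labels)
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        missing = tips - set(self.tip_states)
        if missing:
            raise ValueError(f"tips without state assignment: {sorted(missing)[:5]}")
        for tip, states in self.tip_states.items():
            if not states or not states <= labels:
                raise ValueError(f"tip {tip!r}: invalid state set {sorted(states)}")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @classmethod
    def from_newick(
        cls,
        newick: str,
        tip_states: Mapping[str, str | Iterable[str]],
        state_labels: Sequence[str] | None = None,
    ) -> "TraitTree":
        """Build from a newick string and a tip -> state map.

        Ambiguity sets may be given as ``"A|B"`` strings or iterables.
        """
        tree = dendropy.Tree.get(data=newick, schema="newick")
        states: dict[str, frozenset[str]] = {}
        for tip, value in tip_states.items():
            if isinstance(value, str):
                states[tip] = frozenset(value.split("|"))
            else:
                states[tip] = frozenset(value)
        if state_labels is None:
            state_labels = tuple(sorted(frozenset().union(*states.values())))
        return cls(tree, states, tuple(state_labels))


@dataclass(frozen=True)
class TraitModel:
    """Symmetric k-state Markov model with one exchange rate."""

    rate: float
    n_states: int
    kind: str = "symmetric"

    def transition_matrix(self, t: float) -> np.ndarray:
        k = self.n_states
        t = max(t, MIN_BRANCH_LENGTH)
        decay = math.exp(-k * self.rate * t)
        p_same = 1.0 / k + (k - 1) / k * decay
        p_diff = 1.0 / k - decay / k
        mat = np.full((k, k), p_diff)
        np.fill_diagonal(mat, p_same)
        return mat


@dataclass(frozen=True)
class NodePosterior:
    node_id: str
    distribution: dict[str, float]

    @property
    def modal_state(self) -> str:
        return max(self.distribution, key=lambda s: (self.distribution[s], s))


def _tip_partial(states: frozenset[str], labels: Sequence[str]) -> np.ndarray:
    partial = np.zeros(len(labels))
    for i, label in enumerate(labels):
        if label in states:
            partial[i] = 1.0
    return partial


def _node_id(node: dendropy.Node, index: int) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or f"node{index}"


def pruning_likelihood(
    trait_tree: TraitTree, model: TraitModel, root_prior: str = "uniform"
) -> float:
    """Log-likelihood of the tip states by Felsenstein's pruning algorithm."""
    partials = _postorder_partials(trait_tree, model)
    root = trait_tree.tree.seed_node
    prior = _root_prior(model, root_prior)
    likelihood = float(prior @ partials[id(root)][0])
    scale = partials[id(root)][1]
    if likelihood <= 0:
        raise ValueError("zero likelihood: tip constraints are contradictory")
    return math.log(likelihood) + scale


def _root_prior(model: TraitModel, root_prior: str) -> np.ndarray:
    # uniform and equilibrium coincide for the symmetric model, but both
    # spellings are accepted for clarity at call sites
    if root_prior not in ("uniform", "equilibrium"):
        raise ValueError(f"unknown root prior {root_prior!r}")
    return np.full(model.n_states, 1.0 / model.n_states)


def _postorder_partials(
    trait_tree: TraitTree, model: TraitModel
) -> dict[int, tuple[np.ndarray, float]]:
    """Per-node conditional likelihoods with running log-scale factors."""
    labels = trait_tree.state_labels
    partials: dict[int, tuple[np.ndarray, float]] = {}
    for node in trait_tree.tree.postorder_node_iter():
        if node.is_leaf():
            partials[id(node)] = (
                _tip_partial(trait_tree.tip_states[node.taxon.label], labels),
                0.0,
            )
            continue
        partial = np.ones(len(labels))
        scale = 0.0
        for child in node.child_nodes():
            mat = model.transition_matrix(child.edge.length or 0.0)
            child_partial, child_scale = partials[id(child)]
            partial = partial * (mat @ child_partial)
            scale += child_scale
        top = partial.max()
        if top > 0:  # rescale to dodge underflow on deep trees
            partial = partial / top
            scale += math.log(top)
        partials[id(node)] = (partial, scale)
    return partials


def fit_rate(
    trait_tree: TraitTree,
    max_rate: float = 1e3,
    root_prior: str = "uniform",
) -> TraitModel:
    """Maximum-likelihood exchange rate by bounded scalar optimization.

    With all tips in one state the ML rate is 0 (returned directly with the
    degenerate model).  The search is on log10(rate) over a generous bracket
    and is deterministic.
    """
    k = len(trait_tree.state_labels)
    shared = frozenset(trait_tree.state_labels)
    for states in trait_tree.tip_states.values():
        shared &= states
    if shared:
        # one state satisfies every tip: no evidence of change, ML rate 0
        return TraitModel(rate=0.0, n_states=k)

    def negative_ll(log10_rate: float) -> float:
        model = TraitModel(rate=10.0 ** log10_rate, n_states=k)
        return -pruning_likelihood(trait_tree, model, root_prior)

    result = minimize_scalar(
        negative_ll,
        bounds=(-6.0, math.log10(max_rate)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return TraitModel(rate=float(10.0 ** result.x), n_states=k)


def marginal_posteriors(
    trait_tree: TraitTree,
    model: TraitModel,
    root_prior: str = "uniform",
) -> list[NodePosterior]:
    """Marginal state posteriors for every node (tips included).

    Post-order partials are combined with pre-order "outside" messages: the
    outside vector of a node summarises the likelihood of everything except
    its own subtree, so posterior ∝ outside * partial at each node.
    """
    labels = trait_tree.state_labels
    partials = _postorder_partials(trait_tree, model)
    prior = _root_prior(model, root_prior)

    outside: dict[int, np.ndarray] = {}
    posteriors: list[NodePosterior] = []
    for index, node in enumerate(trait_tree.tree.preorder_node_iter()):
        if node.parent_node is None:
            outside[id(node)] = prior.copy()
        else:
            parent = node.parent_node
            # product of sibling contributions at the parent, times the
            # parent's own outside vector, propagated through this branch
            vec = outside[id(parent)].copy()
            for sibling in parent.child_nodes():
                if sibling is node:
                    continue
                mat = model.transition_matrix(sibling.edge.length or 0.0)
                vec = vec * (mat @ partials[id(sibling)][0])
            mat = model.transition_matrix(node.edge.length or 0.0)
            vec = vec @ mat  # symmetric matrix; row/column transport agree
            top = vec.max()
            if top > 0:
                vec = vec / top
            outside[id(node)] = vec
        joint = outside[id(node)] * partials[id(node)][0]
        total = joint.sum()
        if total <= 0:
            raise ValueError("zero likelihood at node; contradictory constraints")
        dist = joint / total
        posteriors.append(
            NodePosterior(
                _node_id(node, index),
                {label: float(p) for label, p in zip(labels, dist)},
            )
        )
    return posteriors


# --------------------------------------------------------------------------
# Trait coding of resolved cohorts
# --------------------------------------------------------------------------


def encode_trait_states(
    records: Sequence[SpecimenRecord],
    scheme: str = "full_st",
    st_groups: Mapping[str, str] | None = None,
    st_inventory: Iterable[str] | None = None,
    variant_parent: Mapping[str, str] | None = None,
) -> tuple[dict[str, frozenset[str]], tuple[str, ...]]:
    """Reduce a cohort to tip states on (taxon, haplotype) combinations.

    ``full_st``: one state per sequence type of ``st_inventory`` (every ST is
    a possible state whether or not it was ever seen alone) plus one state
    per observed ST *combination* plus ``uninfected``; a tip whose records
    disagree becomes an ambiguity set.  ``grouped``: states
    {uninfected, A, B, C}; a double infection is coded as the ambiguity set
    of its two groups.  ``variant_parent`` folds mosaic variants into their
    parent ST (default: strip a trailing ``r``); records with unresolved STs
    contribute full ambiguity over the infected states.

    Returns (tip -> state set, state labels); tips are named
    ``"<taxon>|<haplotype>"`` with spaces replaced by underscores.
    """
    if scheme not in ("full_st", "grouped"):
        raise ValueError(f"unknown trait scheme {scheme!r}")
    st_groups = dict(st_groups or {})
    inventory = sorted(st_inventory) if st_inventory is not None else sorted(
        {st for r in records if r.infection for st in r.infection.sts}
    )
    folding = dict(variant_parent or {})
    for st in list(inventory):
        parent = folding.get(st, st[:-1] if st.endswith("r") else st)
        if parent != st and parent in inventory:
            folding[st] = parent
            inventory.remove(st)

    def fold(st: str) -> str:
        return folding.get(st, st)

    def label_of(record: SpecimenRecord) -> frozenset[str] | None:
        inf = record.infection
        if inf is None:
            raise ValueError(f"{record.specimen_id} unresolved")
        if inf.status == UNINFECTED:
            return frozenset({UNINFECTED})
        if inf.status == AMBIGUOUS:
            return None  # full ambiguity, filled in once labels are known
        if scheme == "full_st":
            return frozenset({"+".join(sorted({fold(st) for st in inf.sts}))})
        return frozenset({(st_groups.get(st, "wCall?"))[-1] for st in inf.sts})

    per_tip: dict[str, set[frozenset[str] | None]] = {}
    for record in records:
        tip = f"{record.taxon}|{record.cox1_haplotype}".replace(" ", "_")
        per_tip.setdefault(tip, set()).add(label_of(record))

    if scheme == "grouped":
        labels = (UNINFECTED, "A", "B", "C")
    else:
        combos: set[str] = set()
        for states in per_tip.values():
            for s in states:
                if s is not None:
                    combos |= {x for x in s if "+" in x}
        labels = tuple(sorted(set(inventory) | combos)) + (UNINFECTED,)

    infected_labels = frozenset(l for l in labels if l != UNINFECTED)
    tip_states: dict[str, frozenset[str]] = {}
    for tip, states in per_tip.items():
        merged: set[str] = set()
        for s in states:
            merged |= infected_labels if s is None else s
        tip_states[tip] = frozenset(merged)
    return tip_states, labels


def write_posteriors(posteriors: Sequence[NodePosterior], path: str) -> None:
    import csv

    labels = sorted({s for p in posteriors for s in p.distribution})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node", "modal_state", "modal_probability", *labels])
        for post in posteriors:
            writer.writerow(
                [post.node_id, post.modal_state,
                 f"{post.distribution[post.modal_state]:.6f}"]
                + [f"{post.distribution[s]:.6f}" for s in labels]
            )


def annotate_newick(trait_tree: TraitTree, posteriors: Sequence[NodePosterior]) -> str:
    """Newick with comment fields carrying each node's modal state."""
    by_id = {p.node_id: p for p in posteriors}
    for index, node in enumerate(trait_tree.tree.preorder_node_iter()):
        post = by_id.get(_node_id(node, index))
        if post is not None:
            prob = post.distribution[post.modal_state]
            node.annotations.add_new("state", post.modal_state)
            node.annotations.add_new("p", f"{prob:.4f}")
    return trait_tree.tree.as_string(schema="newick", suppress_annotations=False)
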