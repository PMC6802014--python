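"""Synthetic cohorts with ground truth for every pipeline stage.

The generator emulates the structure of a continental endosymbiont survey:

- a neutral (Kingman) coalescent genealogy over mtDNA haplotypes, with
  per-branch Poisson mutation counts giving integer step distances and a
  private mutation per tip so haplotypes are distinct;
- geographic lineages: the genealogy is cut into contiguous clades, one per
  region, so host structure and geography are confounded the way
  post-glacial range expansions leave them;
- infection histories: a backbone strain is inherited vertically down the
  tree and lost with a per-branch probability; at the tips, hosts acquire
  the locally resident strain with a per-region horizontal rate.  A
  cytoplasmic-incompatibility flag forbids the B and C strain classes from
  co-occurring in one host (the later acquisition is rejected), while
  A-class strains coexist with either — reproducing the observed pattern of
  ubiquitous A plus narrowly parapatric B/C;
- emission: doubly infected specimens get position-wise IUPAC-union mixture
  observations; optional per-locus dropout and faint-signal noise.

Default parameter values mirror the survey scale this package models:
~500 specimens, ~80% prevalence with ~70% of infections double, strains
drawn from the packaged ST inventory with the A1-like strain as backbone.
All randomness flows from one seeded generator; outputs are byte-identical
for a fixed (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from wolcall import calligrapha
from wolcall.coinfection import SpecimenRecord, StTable
from wolcall.mlst import LOCUS_NAMES, SequenceType
from wolcall.network import NestedCladeHierarchy


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic survey.

    Rates are probabilities in [0, 1]: ``vertical_loss_rate`` applies per
    branch of the haplotype genealogy, ``horizontal_rate_by_region`` per
    sampled host.  ``strain_inventory`` must name the backbone strain and
    one resident strain per region.
    """

    n_specimens: int = 500
    n_haplotypes: int = 40
    n_regions: int = 2
    vertical_loss_rate: float = 0.05
    horizontal_rate_by_region: Mapping[str, float] = field(
        default_factory=lambda: {"west": 0.8, "east": 0.8}
    )
    resident_by_region: Mapping[str, str] = field(
        default_factory=lambda: {"west": "wCallB1", "east": "wCallC1"}
    )
    backbone_st: str = "wCallA1"
    ci_exclusion: bool = True
    mutation_rate: float = 3.0  # expected mutations per unit branch length
    dropout: float = 0.0  # per-locus probability of no amplification
    faint_rate: float = 0.0  # per-locus probability of a "?low" signal
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("vertical_loss_rate", self.vertical_loss_rate),
            ("dropout", self.dropout),
            ("faint_rate", self.faint_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for region, rate in self.horizontal_rate_by_region.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"horizontal rate for {region!r} must be in [0, 1]")
        if set(self.horizontal_rate_by_region) != set(self.resident_by_region):
            raise ConfigError("horizontal_rate_by_region and resident_by_region disagree")
        if len(self.resident_by_region) != self.n_regions:
            raise ConfigError("need exactly one resident strain per region")

    def strain_inventory(self) -> list[SequenceType]:
        return calligrapha.sequence_types(include_mosaic=False)

    @classmethod
    def from_file(cls, path: str) -> "SimulationConfig":
        """Read a config from a JSON file (keys as in the dataclass)."""
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


@dataclass
class Genealogy:
    """A labelled haplotype tree with step distances and regions."""

    tree: dendropy.Tree
    haplotypes: list[str]
    region_of: dict[str, str]
    step_distance: dict[tuple[str, str], int]
    hierarchy: NestedCladeHierarchy


@dataclass
class GroundTruth:
    """Everything the generator knows: regenerable from (config, seed)."""

    config: SimulationConfig
    genealogy: Genealogy
    tip_infections: dict[str, tuple[str, ...]]  # haplotype -> ST ids
    node_infections: dict[str, tuple[str, ...]]  # internal node -> ST ids
    specimens: list[SpecimenRecord] = field(default_factory=list)
    true_infection: dict[str, tuple[str, ...]] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Genealogy
# --------------------------------------------------------------------------


def simulate_genealogy(config: SimulationConfig, max_nest_level: int = 3) -> Genealogy:
    """Neutral coalescent over haplotypes, with regions and nesting design.

    Pairs of lineages coalesce at exponential times with rate k(k-1)/2;
    mutations fall on branches as Poisson(rate × length) with one private
    mutation forced per tip (haplotypes must be distinct).  Regions are the
    maximal clades obtained by cutting the deepest ``n_regions - 1`` splits.
    The nesting table is derived by the network rules from the mutational
    step distances.
    """
    if config.n_haplotypes < 2:
        raise ConfigError("need at least two haplotypes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_haplotypes
    labels = [f"H{i + 1:02d}" for i in range(n)]

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        node.age = 0.0
        nodes.append(node)
    time = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        time += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.age = time
        right, left = nodes.pop(j), nodes.pop(i)
        for child in (left, right):
            parent.add_child(child)
            child.edge.length = time - child.age
        nodes.append(parent)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = 0.0

    # per-branch mutation counts; one forced private mutation per tip
    mutation_counter = 0
    for node in tree.preorder_node_iter():
        length = node.edge.length or 0.0
        count = int(rng.poisson(config.mutation_rate * length))
        if node.is_leaf():
            count = max(count, 1)
        node.mutations = [mutation_counter + m for m in range(count)]
        mutation_counter += count

    # mutational step distance = symmetric difference of root-path mutations
    path_sets: dict[str, frozenset[int]] = {}
    def collect(node, acc):
        acc = acc | frozenset(getattr(node, "mutations", ()))
        if node.is_leaf():
            path_sets[node.taxon.label] = acc
        for child in node.child_nodes():
            collect(child, acc)
    collect(tree.seed_node, frozenset())
    step = {
        (a, b): len(path_sets[a] ^ path_sets[b])
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }

    # regions: cut the n_regions-1 deepest splits -> contiguous clades
    internal = sorted(
        (node for node in tree.preorder_node_iter() if not node.is_leaf()),
        key=lambda nd: -nd.age,
    )
    region_roots: list[dendropy.Node] = [tree.seed_node]
    for node in internal:
        if len(region_roots) >= config.n_regions:
            break
        if node in region_roots:
            region_roots.remove(node)
            region_roots.extend(node.child_nodes())
    region_names = sorted(config.horizontal_rate_by_region)
    region_of: dict[str, str] = {}
    # assign larger clades to regions in listed order (deterministic)
    clades = sorted(
        (sorted(leaf.taxon.label for leaf in root.leaf_iter()) for root in region_roots),
        key=lambda c: (-len(c), c[0]),
    )
    for region, clade in zip(region_names, clades):
        for label in clade:
            region_of[label] = region

    hierarchy = _hierarchy_from_tree(tree, max_nest_level)
    return Genealogy(tree, labels, region_of, step, hierarchy)


def _hierarchy_from_tree(tree: dendropy.Tree, n_levels: int) -> NestedCladeHierarchy:
    """Nested clades by cutting the genealogy at increasing depths.

    Level k groups tips that coalesce below the k-th age quantile of the
    internal nodes; deeper cuts strictly coarsen shallower ones, so the
    result is always a valid hierarchy.  (Network-based nesting is for
    observed data; the generator knows the true tree, and the tie-rich
    Poisson step distances of a simulated genealogy make a
    union-of-spanning-trees network too dense to nest meaningfully.)
    """
    ages = sorted(
        node.age for node in tree.preorder_node_iter() if not node.is_leaf()
    )
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    levels: list[dict[str, frozenset]] = [
        {f"0-{i + 1}": frozenset({label}) for i, label in enumerate(labels)}
    ]
    for k in range(1, n_levels + 1):
        threshold = ages[min(len(ages) - 1, (k * len(ages)) // (n_levels + 1))]
        clades: list[frozenset] = []
        assigned: set[str] = set()
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.age <= threshold:
                tips = frozenset(
                    leaf.taxon.label
                    for leaf in (node.leaf_iter() if not node.is_leaf() else [node])
                )
                if not tips & assigned:
                    clades.append(tips)
                    assigned |= tips
        clades.sort(key=lambda c: min(c))
        levels.append({f"{k}-{i + 1}": clade for i, clade in enumerate(clades)})
    return NestedCladeHierarchy(levels=levels)


# --------------------------------------------------------------------------
# Infection histories
# --------------------------------------------------------------------------


def _group_of(st_id: str, table: StTable) -> str:
    return table.get(st_id).group[-1]  # "A" | "B" | "C"


def simulate_infections(
    genealogy: Genealogy, config: SimulationConfig
) -> tuple[dict[str, tuple[str, ...]], dict[str, tuple[str, ...]]]:
    """Evolve infection states down the tree; returns (tip, node) truths.

    The backbone strain starts at the root and is lost independently on each
    branch with ``vertical_loss_rate``.  Horizontal acquisition of the
    region-resident strain happens at the tips (per haplotype here; sampled
    hosts inherit their haplotype's state and roll individual horizontal
    acquisitions in :func:`emit_dataset` — see there).  Under CI exclusion a
    host never carries both a B- and a C-group strain.
    """
    table = StTable(config.strain_inventory())
    for region, st_id in config.resident_by_region.items():
        if st_id not in table:
            raise ConfigError(f"region {region!r}: resident strain {st_id!r} unknown")
    if config.backbone_st not in table:
        raise ConfigError(f"backbone strain {config.backbone_st!r} unknown")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    node_state: dict[int, tuple[str, ...]] = {}
    node_infections: dict[str, tuple[str, ...]] = {}
    tip_infections: dict[str, tuple[str, ...]] = {}
    index = 0
    for node in genealogy.tree.preorder_node_iter():
        if node.parent_node is None:
            state: tuple[str, ...] = (config.backbone_st,)
        else:
            state = node_state[id(node.parent_node)]
            if state and rng.random() < config.vertical_loss_rate:
                state = ()
        node_state[id(node)] = state
        if node.is_leaf():
            tip_infections[node.taxon.label] = state
        else:
            node_infections[f"node{index}"] = state
        index += 1
    return tip_infections, node_infections


def _acquire(
    state: tuple[str, ...],
    resident: str,
    table: StTable,
    ci_exclusion: bool,
) -> tuple[str, ...]:
    """Add the resident strain to a host state, honouring CI exclusion."""
    if resident in state:
        return state
    groups = {_group_of(st, table) for st in state}
    res_group = _group_of(resident, table)
    if ci_exclusion and res_group in ("B", "C") and ({"B", "C"} - {res_group}) & groups:
        return state  # incompatible acquisition rejected
    return tuple(sorted(state + (resident,)))


# --------------------------------------------------------------------------
# Dataset emission
# --------------------------------------------------------------------------


def emit_dataset(config: SimulationConfig) -> GroundTruth:
    """Full synthetic dataset: specimens with observations plus all truths.

    Hosts are drawn uniformly over haplotypes (multinomial); each host
    inherits its haplotype's vertical state and then rolls horizontal
    acquisition of its region's resident strain.  Observations are the
    locus-wise allele unions of the carried STs, with optional dropout and
    faint-signal noise applied per locus.
    """
    genealogy = simulate_genealogy(config)
    tip_infections, node_infections = simulate_infections(genealogy, config)
    table = StTable(config.strain_inventory())
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    specimens: list[SpecimenRecord] = []
    true_infection: dict[str, tuple[str, ...]] = {}
    haplotype_draw = rng.integers(0, len(genealogy.haplotypes), size=config.n_specimens)
    for i, hap_index in enumerate(haplotype_draw):
        haplotype = genealogy.haplotypes[int(hap_index)]
        region = genealogy.region_of[haplotype]
        state = tip_infections[haplotype]
        if rng.random() < config.horizontal_rate_by_region[region]:
            state = _acquire(
                state, config.resident_by_region[region], table, config.ci_exclusion
            )
        specimen_id = f"SIM{i + 1:04d}"
        true_infection[specimen_id] = state

        observations: dict[str, str] = {}
        profiles = [table.get(st).profile for st in state]
        for locus in LOCUS_NAMES:
            if not profiles:
                observations[locus] = ""
                continue
            roll = rng.random()
            if roll < config.dropout:
                observations[locus] = ""
            elif roll < config.dropout + config.faint_rate:
                observations[locus] = "?low"
            else:
                observations[locus] = "/".join(sorted({p[locus] for p in profiles}))
        # region doubles as a simple nuclear genotype proxy: two Wg alleles
        # drawn from a region-biased pool
        wg_pool = {"west": ("w1", "w2"), "east": ("e1", "e2")}.get(region)
        if wg_pool is None:
            wg_pool = (f"{region}-1", f"{region}-2")
        wg = "/".join(sorted(rng.choice(wg_pool, size=2)))
        specimens.append(
            SpecimenRecord(
                specimen_id=specimen_id,
                taxon="Synthetica generica",
                region=region,
                cox1_haplotype=haplotype,
                wg_genotype=wg,
                observations=observations,
            )
        )
    return GroundTruth(
        config=config,
        genealogy=genealogy,
        tip_infections=tip_infections,
        node_infections=node_infections,
        specimens=specimens,
        true_infection=true_infection,
    )


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    """Ground-truth JSON: config echo, tree, regions, per-specimen truth."""
    payload = {
        "config": asdict(truth.config),
        "newick": truth.genealogy.tree.as_string(schema="newick").strip(),
        "region_of": truth.genealogy.region_of,
        "tip_infections": {k: list(v) for k, v in truth.tip_infections.items()},
        "node_infections": {k: list(v) for k, v in truth.node_infections.items()},
        "true_infection": {k: list(v) for k, v in truth.true_infection.items()},
    }
    payload["config"]["horizontal_rate_by_region"] = dict(
        truth.config.horizontal_rate_by_region
    )
    payload["config"]["resident_by_region"] = dict(truth.config.resident_by_region)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
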