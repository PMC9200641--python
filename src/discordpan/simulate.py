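"""Synthetic-data generators with known ground truth.

Three generators cover every input the pipeline needs:

* gene trees drawn under the multispecies coalescent (MSC) from a species
  tree with branch lengths in coalescent units (2N generations), optionally
  with a single introgression pulse of fraction ``gamma``;
* nucleotide alignments evolved along those gene trees under JC69;
* pan-gene presence/absence matrices with configured category proportions.

The MSC kernel is the standard one: within each species-tree branch, k
lineages coalesce with exponential waiting times at rate k(k-1)/2, and
uncoalesced lineages pass to the parent branch. An introgression pulse
relocates each lineage sitting in the recipient branch at time ``t_m`` to the
donor branch, independently with probability ``gamma`` per lineage per locus,
which is the simplest model under which the f4-ratio has expectation gamma.

Per-locus random streams are split from the master seed, so changing
``n_loci`` never perturbs earlier loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np

from .io import MultiAlignment, PresenceAbsenceMatrix, parse_tree


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass(frozen=True)
class IntrogressionScenario:
    """A single admixture pulse from ``donor`` into ``recipient``.

    ``donor``/``recipient`` name species-tree branches (leaf labels, or
    internal node labels when present); ``t_m`` is the pulse time in
    coalescent units before present and must fall inside both branches'
    time spans; ``gamma`` is the per-lineage relocation probability.
    """

    donor: str
    recipient: str
    t_m: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigError(f"gamma must be in [0,1], got {self.gamma}")
        if self.t_m < 0:
            raise ConfigError("t_m must be >= 0")


@dataclass
class MSCConfig:
    """Configuration for :func:`simulate_gene_trees`."""

    species_tree: dendropy.Tree
    n_loci: int
    samples_per_species: int = 1
    seed: int = 0
    scenario: Optional[IntrogressionScenario] = None

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if self.samples_per_species < 1:
            raise ConfigError("samples_per_species must be >= 1")


@dataclass
class SeqSimConfig:
    """Configuration for :func:`simulate_alignment`.

    ``mutation_scale`` converts coalescent-unit branch lengths into expected
    substitutions/site (a theta-like scale factor).
    """

    locus_length: int
    mutation_scale: float
    model: str = "JC69"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.locus_length < 1:
            raise ConfigError("locus_length must be >= 1")
        if self.mutation_scale < 0:
            raise ConfigError("mutation_scale must be >= 0")
        if self.model != "JC69":
            raise ConfigError(f"unsupported model {self.model!r}")


# ---------------------------------------------------------------------------
# MSC gene-tree simulation


class _Lineage:
    __slots__ = ("label", "age", "children")

    def __init__(self, label, age, children=()):
        self.label = label
        self.age = age
        self.children = children


def _node_ages(tree: dendropy.Tree) -> dict:
    """Node ages with leaves at time 0 (ultrametric species tree assumed)."""
    ages = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(
                ages[ch] + (ch.edge.length or 0.0) for ch in node.child_nodes()
            )
    return ages


def _branch_label(node: dendropy.Node) -> Optional[str]:
    if node.is_leaf():
        return node.taxon.label if node.taxon else node.label
    return node.label


def _find_branch(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if _branch_label(node) == label:
            return node
    raise ConfigError(f"branch label {label!r} not found in species tree")


def simulate_gene_trees(config: MSCConfig) -> tuple[list[dendropy.Tree], list[bool]]:
    """Draw ``n_loci`` gene trees under the MSC, with an optional pulse.

    Returns the gene trees (branch lengths in coalescent units) and a
    per-locus provenance flag: True when at least one lineage relocated
    through the introgression pulse at that locus. With ``gamma = 0`` the
    output is identical to a scenario-free run under the same seed.
    """
    stree = config.species_tree
    ages = _node_ages(stree)
    for node in stree.preorder_node_iter():
        if node.parent_node is not None and (node.edge.length or 0.0) < 0:
            raise ConfigError("species-tree branch lengths must be >= 0")

    scenario = config.scenario
    donor_node = recipient_node = None
    if scenario is not None:
        donor_node = _find_branch(stree, scenario.donor)
        recipient_node = _find_branch(stree, scenario.recipient)
        for node, name in ((donor_node, "donor"), (recipient_node, "recipient")):
            if node.parent_node is None:
                raise ConfigError(f"{name} cannot be the root branch")
            lo, hi = ages[node], ages[node.parent_node]
            if not lo <= scenario.t_m < hi:
                raise ConfigError(
                    f"t_m={scenario.t_m} outside {name} branch span [{lo}, {hi})"
                )

    leaves = [lv for lv in stree.leaf_node_iter()]
    sample_labels = {}
    for lv in leaves:
        sp = _branch_label(lv)
        if config.samples_per_species == 1:
            sample_labels[lv] = [sp]
        else:
            sample_labels[lv] = [
                f"{sp}_{i}" for i in range(config.samples_per_species)
            ]

    # Events in forward-in-past order: internal node merge times, plus pulse.
    # Ties in age break child-before-parent (postorder) so a parent's merge
    # never runs before its children's pools exist.
    postorder_index = {
        n: i for i, n in enumerate(stree.postorder_node_iter())
    }
    internal = sorted(
        (n for n in stree.preorder_node_iter() if not n.is_leaf()),
        key=lambda n: (ages[n], postorder_index[n]),
    )
    root = stree.seed_node

    taxon_ns = dendropy.TaxonNamespace(
        [lab for lv in leaves for lab in sample_labels[lv]]
    )

    trees: list[dendropy.Tree] = []
    introgressed_flags: list[bool] = []
    for locus in range(config.n_loci):
        rng = np.random.default_rng([config.seed, locus])
        # lineages-by-branch: keyed by the child node of the branch
        pools: dict[dendropy.Node, list[_Lineage]] = {
            lv: [_Lineage(lab, 0.0) for lab in sample_labels[lv]] for lv in leaves
        }
        introgressed = False

        events: list[tuple[float, str, object]] = [
            (ages[n], "merge", n) for n in internal
        ]
        if scenario is not None and scenario.gamma > 0:
            events.append((scenario.t_m, "pulse", None))
        # pulses fire before a merge at the same instant
        events.sort(key=lambda e: (e[0], e[1] != "pulse"))

        t_now = 0.0
        for t_event, kind, node in events:
            dt = t_event - t_now
            if dt > 0:
                for pool in pools.values():
                    _coalesce_in_place(pool, t_now, dt, rng)
            t_now = t_event
            if kind == "pulse":
                src = pools.get(recipient_node, [])
                moved = [
                    lin for lin in src if rng.random() < scenario.gamma
                ]
                if moved:
                    introgressed = True
                    pools[recipient_node] = [l for l in src if l not in moved]
                    pools.setdefault(donor_node, []).extend(moved)
            else:
                merged: list[_Lineage] = []
                for ch in node.child_nodes():
                    merged.extend(pools.pop(ch, []))
                pools[node] = merged

        # Above the root: coalesce the remaining lineages to a single ancestor.
        pool = pools[root]
        _coalesce_in_place(pool, t_now, np.inf, rng)
        trees.append(_lineage_to_tree(pool[0], taxon_ns))
        introgressed_flags.append(introgressed)
    return trees, introgressed_flags


def _coalesce_in_place(pool: list[_Lineage], t_start: float, duration: float, rng) -> None:
    """Run the coalescent on ``pool`` for ``duration`` time units."""
    t = 0.0
    while len(pool) > 1:
        k = len(pool)
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if t + wait > duration:
            return
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        b = pool.pop(j)
        a = pool.pop(i)
        pool.append(_Lineage(None, t_start + t, (a, b)))


def _lineage_to_tree(root: _Lineage, taxon_ns: dendropy.TaxonNamespace) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=taxon_ns)

    def build(lin: _Lineage, parent_age: float) -> dendropy.Node:
        node = dendropy.Node()
        node.edge.length = parent_age - lin.age
        if not lin.children:
            node.taxon = taxon_ns.get_taxon(lin.label)
        else:
            for ch in lin.children:
                node.add_child(build(ch, lin.age))
        return node

    seed = dendropy.Node()
    for ch in root.children:
        seed.add_child(build(ch, root.age))
    if not root.children:  # single-sample corner case
        seed.taxon = taxon_ns.get_taxon(root.label)
    tree.seed_node = seed
    return tree


# ---------------------------------------------------------------------------
# JC69 sequence simulation


def simulate_alignment(tree: dendropy.Tree, config: SeqSimConfig) -> MultiAlignment:
    """Evolve a JC69 alignment along ``tree``.

    The root sequence is uniform over {A,C,G,T}; along each branch a site
    changes with probability (3/4)(1 - exp(-4 d / 3)) where d is the branch
    length times ``mutation_scale``, and a changed site picks one of the
    three other bases uniformly.
    """
    arr, labels = simulate_alignment_array(tree, config)
    return MultiAlignment.from_array(labels, arr)


def simulate_alignment_array(
    tree: dendropy.Tree, config: SeqSimConfig
) -> tuple[np.ndarray, list[str]]:
    """Same as :func:`simulate_alignment` but returns the uint8 matrix directly."""
    rng = np.random.default_rng(config.seed)
    L = config.locus_length
    root_seq = rng.integers(0, 4, size=L, dtype=np.uint8)
    seqs: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root_seq}
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            parent_seq = root_seq
        else:
            d = node.edge.length
            if d is None:
                d = 0.0
            if d < 0:
                raise ConfigError("negative branch length in gene tree")
            d *= config.mutation_scale
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            parent_seq = seqs[node.parent_node]
            if p_change > 0:
                hit = rng.random(L) < p_change
                child = parent_seq.copy()
                n_hit = int(hit.sum())
                if n_hit:
                    child[hit] = (
                        child[hit] + rng.integers(1, 4, size=n_hit, dtype=np.uint8)
                    ) % 4
            else:
                child = parent_seq
            seqs[node] = child
        if node.is_leaf():
            labels.append(node.taxon.label if node.taxon else str(node.label))
            rows.append(seqs[node])
        # free parent memory lazily; trees are small so no bookkeeping needed
    return np.vstack(rows), labels


# ---------------------------------------------------------------------------
# Presence/absence generator


#: Default category proportions, matching the published potato pan-genome
#: split: core 25.5%, soft-core 11.2%, shell 55.4%, accession-specific 7.9%.
DEFAULT_PAN_PROPORTIONS = (0.255, 0.112, 0.554, 0.079)

PAN_CATEGORIES = ("core", "soft_core", "shell", "specific")


def simulate_presence_absence(
    n_accessions: int,
    n_clusters: int,
    proportions: tuple[float, float, float, float] = DEFAULT_PAN_PROPORTIONS,
    seed: int = 0,
    soft_core_min: Optional[int] = None,
) -> tuple[PresenceAbsenceMatrix, list[str]]:
    """Generate a binary matrix with known core/soft-core/shell/specific labels.

    Each cluster gets a true category (largest-remainder apportionment of
    ``proportions``), an occupancy drawn uniformly from that category's band
    (core: n; soft-core: [soft_core_min, n-1]; shell: [2, soft_core_min-1];
    specific: 1), and a uniformly random set of present accessions.
    """
    if n_accessions < 5:
        raise ConfigError("n_accessions must be >= 5 (category bands degenerate)")
    props = np.asarray(proportions, dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ConfigError("proportions must be >= 0 and sum to 1")
    if soft_core_min is None:
        soft_core_min = min(int(np.ceil(0.933 * n_accessions)), n_accessions - 1)
    soft_core_min = max(soft_core_min, 3)
    if not 3 <= soft_core_min <= n_accessions - 1:
        raise ConfigError("soft_core_min out of range")

    # largest-remainder apportionment of cluster counts
    raw = props * n_clusters
    counts = np.floor(raw).astype(int)
    rem = n_clusters - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1

    rng = np.random.default_rng(seed)
    labels: list[str] = []
    values = np.zeros((n_clusters, n_accessions), dtype=np.uint8)
    row = 0
    bands = {
        "core": (n_accessions, n_accessions),
        "soft_core": (soft_core_min, n_accessions - 1),
        "shell": (2, soft_core_min - 1),
        "specific": (1, 1),
    }
    for cat, count in zip(PAN_CATEGORIES, counts):
        lo, hi = bands[cat]
        for _ in range(count):
            occ = int(rng.integers(lo, hi + 1))
            cols = rng.choice(n_accessions, size=occ, replace=False)
            values[row, cols] = 1
            labels.append(cat)
            row += 1
    cluster_ids = [f"cluster{i:05d}" for i in range(n_clusters)]
    accession_ids = [f"acc{j:02d}" for j in range(n_accessions)]
    return PresenceAbsenceMatrix(cluster_ids, accession_ids, values), labels


# ---------------------------------------------------------------------------
# Convenience species trees


def four_taxon_species_tree(internal_length: float, tip: float = 1.0) -> dendropy.Tree:
    """Species tree (((A,B),C),D) with the AB->ABC internal branch ``internal_length``
    and a 1-unit ABC->root branch; ultrametric, leaves at time 0."""
    t = internal_length
    nwk = (
        f"(((A:{tip},B:{tip}):{t},C:{tip + t}):1.0,D:{tip + t + 1.0});"
    )
    return parse_tree(nwk)
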