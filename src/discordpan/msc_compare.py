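"""Observed-vs-simulated quartet-frequency comparison and theta estimation.

For every four-species subset, each gene tree induces one of three unrooted
quartet topologies; the per-subset topology frequencies from an observed set
of trees (e.g. window trees) are compared against frequencies from an MSC
simulation by Pearson correlation. Under the MSC an internal species-tree
branch of t coalescent units gives the concordant quartet probability
1 - (2/3) e^(-t) and (1/3) e^(-t) for each discordant one.

Theta for an internal branch is the ratio of its length in mutation units
(substitutions/site, e.g. a concatenation ML tree) to its length in
coalescent units (e.g. an ASTRAL tree), a proxy for effective population
size on that branch.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class QuartetFrequencyTable:
    """Per four-species-subset quartet topology frequencies.

    ``freqs`` maps (subset tuple, topology key) -> frequency; within each
    subset the three resolved-topology frequencies sum to 1 (unresolved
    induced quartets are tallied separately and excluded from
    normalization). ``n_trees`` records usable trees per subset.
    """

    freqs: dict[tuple[tuple[str, ...], str], float]
    n_trees: dict[tuple[str, ...], int]
    n_unresolved: dict[tuple[str, ...], int]

    def subsets(self) -> list[tuple[str, ...]]:
        return sorted(self.n_trees)


@dataclass
class ThetaEstimate:
    """Effective-population-size proxy for one internal branch."""

    branch: frozenset
    mutation_units: float
    coalescent_units: float
    theta: Optional[float]  # None when the coalescent length is 0 (flagged)


def quartet_topology_key(pair1: tuple[str, str], pair2: tuple[str, str]) -> str:
    """Canonical 'ab|cd' key: pairs internally sorted, smaller pair first."""
    a = tuple(sorted(pair1))
    b = tuple(sorted(pair2))
    a, b = sorted((a, b))
    return f"{a[0]},{a[1]}|{b[0]},{b[1]}"


def _topological_distances(tree: dendropy.Tree, wanted: set[str]) -> Optional[dict]:
    """Leaf-to-leaf edge-count distances for the wanted labels (None if absent)."""
    labels = {}
    for lv in tree.leaf_node_iter():
        if lv.taxon and lv.taxon.label in wanted:
            labels[lv.taxon.label] = lv
    if set(labels) != wanted:
        return None
    pdm = {}
    # BFS from each wanted leaf over the unrooted adjacency
    adj: dict = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        adj.setdefault(edge.tail_node, []).append(edge.head_node)
        adj.setdefault(edge.head_node, []).append(edge.tail_node)
    for name, leaf in labels.items():
        dist = {leaf: 0}
        frontier = [leaf]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adj.get(node, []):
                    if nb not in dist:
                        dist[nb] = dist[node] + 1
                        nxt.append(nb)
            frontier = nxt
        for other, lv in labels.items():
            pdm[(name, other)] = dist[lv]
    return pdm


def induced_quartet(tree_dists: dict, quartet: tuple[str, str, str, str]) -> Optional[str]:
    """Resolve the quartet via the four-point condition on topological distances.

    Returns the 'ab|cd' key of the unique minimal pairing, or None for an
    unresolved (polytomous) induced quartet.
    """
    a, b, c, d = quartet
    s1 = tree_dists[(a, b)] + tree_dists[(c, d)]
    s2 = tree_dists[(a, c)] + tree_dists[(b, d)]
    s3 = tree_dists[(a, d)] + tree_dists[(b, c)]
    sums = [(s1, ((a, b), (c, d))), (s2, ((a, c), (b, d))), (s3, ((a, d), (b, c)))]
    sums.sort(key=lambda x: x[0])
    if sums[0][0] == sums[1][0]:
        return None
    return quartet_topology_key(*sums[0][1])


def quartet_frequencies(
    trees: Sequence[dendropy.Tree], species: Sequence[str]
) -> QuartetFrequencyTable:
    """Tally induced quartet topologies for every 4-subset of ``species``.

    Trees missing any species of a subset are skipped for that subset (and
    logged); frequencies normalize over resolved tallies per subset.
    """
    if not trees:
        raise ValueError("need at least one tree")
    species = sorted(species)
    subsets = list(itertools.combinations(species, 4))
    counts: dict = {s: {} for s in subsets}
    n_trees = {s: 0 for s in subsets}
    n_unres = {s: 0 for s in subsets}
    n_skipped = 0
    wanted = set(species)
    for tree in trees:
        dists = _topological_distances(tree, wanted)
        if dists is None:
            # retry per subset for trees with partial leaf sets
            present = {
                lv.taxon.label for lv in tree.leaf_node_iter() if lv.taxon
            } & wanted
            dists = _topological_distances(tree, present)
        for sub in subsets:
            if any((x, x) not in dists for x in sub):
                n_skipped += 1
                continue
            key = induced_quartet(dists, sub)
            if key is None:
                n_unres[sub] += 1
                continue
            counts[sub][key] = counts[sub].get(key, 0) + 1
            n_trees[sub] += 1
    if n_skipped:
        logger.info("quartet_frequencies: %d tree/subset pairs skipped", n_skipped)
    freqs = {}
    for sub in subsets:
        total = n_trees[sub]
        a, b, c, d = sub
        for key in (
            quartet_topology_key((a, b), (c, d)),
            quartet_topology_key((a, c), (b, d)),
            quartet_topology_key((a, d), (b, c)),
        ):
            freqs[(sub, key)] = counts[sub].get(key, 0) / total if total else 0.0
    return QuartetFrequencyTable(freqs, n_trees, n_unres)


def compare_frequencies(
    obs: QuartetFrequencyTable, sim: QuartetFrequencyTable
) -> tuple[float, pd.DataFrame]:
    """Pearson r over all paired (subset, topology) frequencies, plus the
    paired table for plotting."""
    keys = sorted(set(obs.freqs) & set(sim.freqs))
    if len(keys) < 3:
        raise ValueError("need >= 3 paired frequency values")
    table = pd.DataFrame(
        {
            "subset": [",".join(k[0]) for k in keys],
            "topology": [k[1] for k in keys],
            "observed": [obs.freqs[k] for k in keys],
            "simulated": [sim.freqs[k] for k in keys],
        }
    )
    r = float(stats.pearsonr(table["observed"], table["simulated"]).statistic)
    return r, table


# ---------------------------------------------------------------------------
# Theta


def _internal_branches(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Map each internal bipartition to its length, keyed by the smaller
    (then lexicographically first) side."""
    leaves = {lv.taxon.label for lv in tree.leaf_node_iter()}
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lv.taxon.label for lv in node.leaf_iter())
        if not (1 < len(side) < len(leaves) - 1):
            continue
        other = frozenset(leaves - side)
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        out[key] = out.get(key, 0.0) + (node.edge.length or 0.0)
    return out


def estimate_theta(
    tree_mutation_units: dendropy.Tree, tree_coalescent_units: dendropy.Tree
) -> list[ThetaEstimate]:
    """Per internal branch, theta = mutation-unit length / coalescent-unit length.

    The two trees must share leaf set and topology (matched by bipartition);
    branches with zero coalescent length are flagged with ``theta=None``.
    """
    mut = _internal_branches(tree_mutation_units)
    coal = _internal_branches(tree_coalescent_units)
    if set(mut) != set(coal):
        raise ValueError("trees do not share the same internal bipartitions")
    out = []
    for key in sorted(mut, key=lambda s: (len(s), sorted(s))):
        m, c = mut[key], coal[key]
        theta = m / c if c > 0 else None
        out.append(ThetaEstimate(key, m, c, theta))
    return out


def expected_quartet_frequencies(t: float) -> tuple[float, float, float]:
    """Closed-form MSC quartet probabilities for an internal branch of t
    coalescent units: (concordant, discordant, discordant)."""
    e = np.exp(-t)
    return (1.0 - 2.0 * e / 3.0, e / 3.0, e / 3.0)
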