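"""Windowed phylogenetic discordance: split, filter, infer, classify.

A reference-anchored alignment is cut into non-overlapping windows (100 kb by
default), each window passes three filters — fully aligned length > 10 kb,
missing rate < 20%, mean bootstrap > 80 (all strict, as printed) — and a
per-window tree is inferred by neighbor joining on Jukes-Cantor distances
with a site-resampling bootstrap. Window trees are then classified by the
position of one focal clade (e.g. Etuberosum relative to Petota and
Lycopersicon) and summarized into a topology spectrum.

NJ replaces per-window maximum likelihood deliberately: the discordance
summary depends on topology classes, not on branch-length model fidelity,
and NJ is exact on additive distances and deterministic under a seed.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .io import MultiAlignment, Region

#: JC distance assigned to saturated pairs (p >= 3/4).
SATURATION_SENTINEL = 10.0

TOPOLOGY_CLASSES = (
    "ETB_sister_to_PET",
    "ETB_sister_to_LYC",
    "ETB_sister_to_(PET+LYC)",
    "other",
)


class TreeInferenceError(ValueError):
    pass


@dataclass
class WindowFilterConfig:
    """The three window filters, with the published defaults."""

    window_size: int = 100_000
    min_aligned: int = 10_000
    max_missing: float = 0.20
    min_mean_bootstrap: float = 80.0

    def __post_init__(self) -> None:
        if not 0 < self.min_aligned <= self.window_size:
            raise ValueError("need 0 < min_aligned <= window_size")
        if not 0 <= self.max_missing <= 1:
            raise ValueError("max_missing must be in [0,1]")


@dataclass
class WindowRecord:
    """One genomic window with filter diagnostics and (optionally) its tree."""

    region: Region
    aligned_length: int
    missing_rate: float
    tree: Optional[dendropy.Tree] = None
    mean_bootstrap: Optional[float] = None
    passed: bool = False
    diagnostics: dict = field(default_factory=dict)
    topology_class: Optional[str] = None
    partial: bool = False


@dataclass
class TopologySpectrum:
    """Counts of canonical window-tree topologies and focal-clade classes."""

    spectrum: dict[str, int]
    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    n_windows_total: int
    n_windows_passed: int

    @property
    def n_distinct_topologies(self) -> int:
        return len(self.spectrum)


# ---------------------------------------------------------------------------
# Windowing


def split_windows(aln: MultiAlignment, cfg: WindowFilterConfig) -> list[MultiAlignment]:
    """Cut into consecutive [k*w, (k+1)*w) windows on the reference grid.

    The grid is anchored at multiples of the window size; a trailing (or
    leading) partial window is retained — downstream it carries the
    ``partial`` flag and is excluded from the spectrum by default.
    """
    if aln.region is None:
        raise ValueError("alignment must carry a region to be windowed")
    w = cfg.window_size
    start, end = aln.region.start, aln.region.end
    out = []
    k = start // w
    while k * w < end:
        lo = max(start, k * w)
        hi = min(end, (k + 1) * w)
        out.append(aln.subset_columns(lo - start, hi - start))
        k += 1
    return out


def window_stats(aln: MultiAlignment) -> tuple[int, float]:
    """(fully aligned length, missing rate).

    Fully aligned length counts columns with zero missing characters across
    all taxa; the missing rate is missing cells over all cells (gap and N
    both count as missing).
    """
    arr = aln.to_array()
    missing = arr == 255
    aligned = int((~missing.any(axis=0)).sum())
    rate = float(missing.mean()) if arr.size else 0.0
    return aligned, rate


def apply_mask(aln: MultiAlignment, mask: Sequence[Region]) -> MultiAlignment:
    """Hard-mask (to N) the columns covered by BED regions (e.g. genes/repeats)."""
    if aln.region is None:
        raise ValueError("alignment must carry a region to be masked")
    arr = aln.to_array()
    start = aln.region.start
    for reg in mask:
        if reg.chrom != aln.region.chrom:
            continue
        lo = max(reg.start, aln.region.start) - start
        hi = min(reg.end, aln.region.end) - start
        if hi > lo:
            arr[:, lo:hi] = 255
    return MultiAlignment.from_array(
        aln.taxon_labels, arr, ref_taxon=aln.ref_taxon, region=aln.region
    )


def filter_window(rec: WindowRecord, cfg: WindowFilterConfig) -> tuple[bool, dict]:
    """Apply the three filters with strict inequalities, as printed."""
    diag = {
        "aligned_ok": rec.aligned_length > cfg.min_aligned,
        "missing_ok": rec.missing_rate < cfg.max_missing,
        "bootstrap_ok": (
            rec.mean_bootstrap is not None
            and rec.mean_bootstrap > cfg.min_mean_bootstrap
        ),
    }
    return all(diag.values()), diag


# ---------------------------------------------------------------------------
# JC distances and neighbor joining


def jc_distance_matrix(aln: MultiAlignment) -> np.ndarray:
    """Pairwise Jukes-Cantor distances d = -(3/4) ln(1 - (4/3) p).

    p is the mismatch fraction over pairwise-complete sites; saturated pairs
    (p >= 3/4) get :data:`SATURATION_SENTINEL` with a warning; a pair with no
    comparable sites is an error naming the pair.
    """
    arr = aln.to_array()
    n = arr.shape[0]
    if n < 3:
        raise TreeInferenceError("need >= 3 taxa")
    dist = np.zeros((n, n))
    valid = arr != 255
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        m = int(both.sum())
        if m == 0:
            raise TreeInferenceError(
                f"no comparable sites for pair ({aln.taxon_labels[i]}, {aln.taxon_labels[j]})"
            )
        p = float((arr[i, both] != arr[j, both]).sum()) / m
        if p >= 0.75:
            warnings.warn(
                f"saturated pair ({aln.taxon_labels[i]}, {aln.taxon_labels[j]}): p={p:.3f}",
                RuntimeWarning,
                stacklevel=2,
            )
            d = SATURATION_SENTINEL
        else:
            d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
        dist[i, j] = dist[j, i] = d
    return dist


def _nj_topology(dist: np.ndarray, labels: Sequence[str]):
    """Saitou-Nei neighbor joining; returns a nested-tuple unrooted tree.

    Nodes are (children tuple, ...) or leaf label strings; edge lengths are
    carried alongside. Ties in the Q criterion break by lexicographic order
    of the joined clusters' smallest member labels.
    """
    n = len(labels)
    children: dict[int, list[tuple[int, float]]] = {}
    next_id = n
    store = {i: labels[i] for i in range(n)}
    # tie-break representative: the cluster's smallest leaf label
    rep_of = {i: str(labels[i]) for i in range(n)}
    active = list(range(n))
    dmat = {(i, j): float(dist[i, j]) for i in range(n) for j in range(n) if i < j}

    def get(i, j):
        return dmat[(i, j) if i < j else (j, i)]

    def put(i, j, v):
        dmat[(i, j) if i < j else (j, i)] = v

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * get(a, b) - r[a] - r[b]
            key = (q, tuple(sorted((rep_of[a], rep_of[b]))))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        dab = get(a, b)
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        u = next_id
        next_id += 1
        children[u] = [(a, la), (b, lb)]
        rep_of[u] = min(rep_of[a], rep_of[b])
        for k in active:
            if k in (a, b):
                continue
            put(u, k, 0.5 * (get(a, k) + get(b, k) - dab))
        active = [k for k in active if k not in (a, b)] + [u]

    a, b, c = active
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    root = next_id
    children[root] = [(a, la), (b, lb), (c, lc)]
    return root, children, store


def nj_tree(
    dist: np.ndarray,
    labels: Sequence[str],
    aln: Optional[MultiAlignment] = None,
    bootstrap: int = 0,
    seed: Optional[int] = None,
) -> dendropy.Tree:
    """Neighbor-joining tree, optionally with site-resampling bootstrap supports.

    Bootstrap requires the alignment the distances came from; supports are the
    percentage of replicates whose NJ tree contains each internal bipartition,
    stored on internal nodes (``node.support`` and the node label).
    """
    root, children, store = _nj_topology(dist, labels)
    tree = _to_dendropy(root, children, store, labels)
    if bootstrap > 0:
        if aln is None:
            raise ValueError("bootstrap requires the source alignment")
        rng = np.random.default_rng(seed)
        tally: Counter = Counter()
        arr = aln.to_array()
        n_cols = arr.shape[1]
        for _ in range(bootstrap):
            cols = rng.integers(0, n_cols, size=n_cols)
            rep_aln = MultiAlignment.from_array(aln.taxon_labels, arr[:, cols])
            rep_dist = _jc_distance_quiet(rep_aln)
            rroot, rchildren, rstore = _nj_topology(rep_dist, labels)
            for bip in _bipartitions(rroot, rchildren, rstore, labels):
                tally[bip] += 1
        _annotate_supports(tree, tally, bootstrap, set(map(str, labels)))
    return tree


def _jc_distance_quiet(aln: MultiAlignment) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return jc_distance_matrix(aln)


def _to_dendropy(root, children, store, labels) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace([str(l) for l in labels])
    tree = dendropy.Tree(taxon_namespace=ns)

    def build(node_id, length):
        node = dendropy.Node()
        node.edge.length = length
        if node_id in children:
            for ch, l in children[node_id]:
                node.add_child(build(ch, l))
        else:
            node.taxon = ns.get_taxon(str(store[node_id]))
        return node

    seed = dendropy.Node()
    for ch, l in children[root]:
        seed.add_child(build(ch, l))
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


def _bipartitions(root, children, store, labels) -> set[frozenset]:
    """Non-trivial bipartitions, each keyed by the side excluding the min label."""
    all_labels = set(map(str, labels))
    anchor = min(all_labels)
    bips = set()

    def walk(node_id):
        if node_id not in children:
            return frozenset([str(store[node_id])])
        acc = frozenset()
        for ch, _ in children[node_id]:
            side = walk(ch)
            acc |= side
            if 1 < len(side) < len(all_labels) - 1:
                key = side if anchor not in side else frozenset(all_labels - side)
                bips.add(key)
        return acc

    walk(root)
    return bips


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions of a dendropy tree, anchored like NJ's."""
    all_labels = {lv.taxon.label for lv in tree.leaf_node_iter()}
    anchor = min(all_labels)
    bips = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lv.taxon.label for lv in node.leaf_iter())
        if 1 < len(side) < len(all_labels) - 1:
            key = side if anchor not in side else frozenset(all_labels - side)
            bips.add(key)
    return bips


def _annotate_supports(tree, tally, n_reps, all_labels) -> None:
    anchor = min(all_labels)
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lv.taxon.label for lv in node.leaf_iter())
        if not (1 < len(side) < len(all_labels) - 1):
            continue
        key = side if anchor not in side else frozenset(all_labels - side)
        support = 100.0 * tally.get(key, 0) / n_reps
        node.support = support
        node.label = f"{support:g}"


def mean_bootstrap(tree: dendropy.Tree) -> Optional[float]:
    vals = [
        node.support
        for node in tree.postorder_node_iter()
        if getattr(node, "support", None) is not None
    ]
    return float(np.mean(vals)) if vals else None


# ---------------------------------------------------------------------------
# Topology classification and spectrum


def classify_topology(tree: dendropy.Tree, groups: dict[str, str]) -> str:
    """Classify the sister of the focal ETB clade after rooting on OUT.

    ``groups`` maps leaf labels to PET / LYC / ETB / OUT. When PET, LYC and
    ETB are each monophyletic (against everything else, outgroup included)
    the class names ETB's sister; otherwise ``other``.
    """
    leaves = {lv.taxon.label for lv in tree.leaf_node_iter()}
    sets = {g: frozenset(t for t, gg in groups.items() if gg == g) & leaves
            for g in ("PET", "LYC", "ETB", "OUT")}
    for g, s in sets.items():
        if not s:
            raise ValueError(f"group {g} has no taxa in the tree")
    bips = tree_bipartitions(tree)
    anchor = min(leaves)

    def present(side: frozenset) -> bool:
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            return True  # trivial bipartitions always hold
        key = side if anchor not in side else frozenset(leaves - side)
        return key in bips

    if not all(present(sets[g]) for g in ("PET", "LYC", "ETB")):
        return "other"
    if present(sets["ETB"] | sets["PET"]):
        return "ETB_sister_to_PET"
    if present(sets["ETB"] | sets["LYC"]):
        return "ETB_sister_to_LYC"
    if present(sets["PET"] | sets["LYC"]):
        return "ETB_sister_to_(PET+LYC)"
    return "other"


def canonical_topology(tree: dendropy.Tree) -> str:
    """Canonical string of the unrooted topology (labels only, sorted order)."""
    adj: dict = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        adj.setdefault(edge.tail_node, []).append(edge.head_node)
        adj.setdefault(edge.head_node, []).append(edge.tail_node)
    leaves = {lv: lv.taxon.label for lv in tree.leaf_node_iter()}
    start = min(leaves, key=lambda lv: leaves[lv])

    def render(node, parent) -> str:
        nbrs = [n for n in adj.get(node, []) if n is not parent]
        if not nbrs:
            return leaves[node]
        if len(nbrs) == 1:  # degree-2 node (e.g. a rooted tree's root): pass through
            return render(nbrs[0], node)
        return "(" + ",".join(sorted(render(n, node) for n in nbrs)) + ")"

    hub = adj[start][0]
    return f"({leaves[start]},{render(hub, start)})"


def build_window_records(
    aln: MultiAlignment,
    cfg: WindowFilterConfig,
    groups: Optional[dict[str, str]] = None,
    bootstrap: int = 100,
    seed: int = 0,
) -> list[WindowRecord]:
    """Window the alignment, filter, infer NJ trees, classify topologies.

    Trees are inferred only for windows passing the alignment-level filters
    (aligned length, missing rate); the bootstrap filter is then applied, and
    topology classes assigned to passing windows when ``groups`` is given.
    """
    records = []
    for wi, win in enumerate(split_windows(aln, cfg)):
        aligned, miss = window_stats(win)
        rec = WindowRecord(
            region=win.region,
            aligned_length=aligned,
            missing_rate=miss,
            partial=len(win.region) < cfg.window_size,
        )
        if aligned > cfg.min_aligned and miss < cfg.max_missing and not rec.partial:
            dist = _jc_distance_quiet(win)
            rec.tree = nj_tree(
                dist, win.taxon_labels, aln=win, bootstrap=bootstrap,
                seed=np.random.SeedSequence([seed, wi]).generate_state(1)[0] % (2**31),
            )
            rec.mean_bootstrap = mean_bootstrap(rec.tree) if bootstrap else 100.0
        rec.passed, rec.diagnostics = filter_window(rec, cfg)
        if rec.partial:
            rec.passed = False
            rec.diagnostics["partial"] = True
        if rec.passed and groups is not None:
            rec.topology_class = classify_topology(rec.tree, groups)
        records.append(rec)
    return records


def topology_spectrum(records: Sequence[WindowRecord]) -> TopologySpectrum:
    """Tally canonical topologies and focal-clade classes over passed windows."""
    spectrum: Counter = Counter()
    classes: Counter = Counter()
    n_passed = 0
    for rec in records:
        if not rec.passed or rec.tree is None:
            continue
        n_passed += 1
        spectrum[canonical_topology(rec.tree)] += 1
        if rec.topology_class is not None:
            classes[rec.topology_class] += 1
    fractions = {
        k: (classes[k] / n_passed if n_passed else 0.0) for k in classes
    }
    return TopologySpectrum(
        dict(spectrum), dict(classes), fractions, len(records), n_passed
    )
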