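import itertools
import math

import numpy as np
import pytest

from discordpan.io import MultiAlignment, Region, parse_tree
from discordpan.windows import (
    SATURATION_SENTINEL,
    TreeInferenceError,
    WindowFilterConfig,
    WindowRecord,
    build_window_records,
    canonical_topology,
    classify_topology,
    filter_window,
    jc_distance_matrix,
    nj_tree,
    split_windows,
    topology_spectrum,
    window_stats,
)
from tests.conftest import make_region_alignment


class TestSplitWindows:
    def test_250kb_region_gives_three_windows_last_partial(self):
        aln = make_region_alignment(3, 250_000)
        cfg = WindowFilterConfig()
        wins = split_windows(aln, cfg)
        assert [len(w.region) for w in wins] == [100_000, 100_000, 50_000]

    def test_exact_window_region(self):
        aln = make_region_alignment(3, 100_000)
        wins = split_windows(aln, WindowFilterConfig())
        assert len(wins) == 1 and len(wins[0].region) == 100_000

    def test_just_short_region_is_single_partial(self):
        aln = make_region_alignment(3, 99_999)
        wins = split_windows(aln, WindowFilterConfig())
        assert len(wins) == 1 and len(wins[0].region) == 99_999

    def test_windows_tile_region_exactly(self):
        aln = make_region_alignment(3, 230_001, start=12_345)
        wins = split_windows(aln, WindowFilterConfig())
        covered = sum(len(w.region) for w in wins)
        assert covered == len(aln.region)
        for a, b in zip(wins, wins[1:]):
            assert a.region.end == b.region.start

    def test_windows_align_to_reference_grid(self):
        aln = make_region_alignment(2, 150_000, start=150_000)
        wins = split_windows(aln, WindowFilterConfig())
        assert [(w.region.start, w.region.end) for w in wins] == [
            (150_000, 200_000),
            (200_000, 300_000),
        ]


class TestFilterWindow:
    CFG = WindowFilterConfig()

    def make(self, aligned=50_000, missing=0.10, boot=95.0):
        return WindowRecord(
            Region("chr1", 0, 100_000), aligned, missing, mean_bootstrap=boot
        )

    def test_all_criteria_pass(self):
        ok, diag = filter_window(self.make(), self.CFG)
        assert ok and all(diag.values())

    def test_short_alignment_fails(self):
        ok, diag = filter_window(self.make(aligned=9_000), self.CFG)
        assert not ok and not diag["aligned_ok"]

    @pytest.mark.parametrize(
        "field,value",
        [("aligned", 10_000), ("missing", 0.20), ("boot", 80.0)],
    )
    def test_thresholds_are_strict(self, field, value):
        kwargs = {field: value}
        ok, _ = filter_window(self.make(**kwargs), self.CFG)
        assert not ok

    def test_filter_monotone_in_thresholds(self):
        # relaxing any threshold never converts pass -> fail
        rec = self.make(aligned=12_000, missing=0.15, boot=85.0)
        base_ok, _ = filter_window(rec, self.CFG)
        assert base_ok
        relaxed = WindowFilterConfig(
            window_size=100_000, min_aligned=5_000, max_missing=0.5, min_mean_bootstrap=50
        )
        assert filter_window(rec, relaxed)[0]

    def test_window_stats_counts_gap_and_n_as_missing(self):
        aln = MultiAlignment(["a", "b"], ["ACG-", "ANGT"])
        aligned, rate = window_stats(aln)
        assert aligned == 2  # columns 0 and 2 complete
        assert rate == pytest.approx(2 / 8)


class TestJcDistance:
    def test_identical_rows_zero(self):
        aln = MultiAlignment(["a", "b", "c"], ["ACGT" * 10] * 3)
        assert jc_distance_matrix(aln).max() == 0

    def test_inverts_jc_closed_form(self):
        # p = 0.0937 is the expected mismatch at true distance 0.1
        n, k = 10_000, 937
        row_a = "A" * n
        row_b = "C" * k + "A" * (n - k)
        aln = MultiAlignment(["a", "b", "c"], [row_a, row_b, row_a])
        d = jc_distance_matrix(aln)[0, 1]
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * (k / n) / 3), rel=1e-9)
        assert d == pytest.approx(0.1, abs=5e-4)

    def test_saturated_pair_sentinel_with_warning(self):
        aln = MultiAlignment(["a", "b", "c"], ["AAAA", "CCCC", "AAAA"])
        with pytest.warns(RuntimeWarning, match="saturated"):
            d = jc_distance_matrix(aln)
        assert d[0, 1] == SATURATION_SENTINEL

    def test_no_comparable_sites_rejected(self):
        aln = MultiAlignment(["a", "b", "c"], ["AA--", "--AA", "AAAA"])
        with pytest.raises(TreeInferenceError, match="a.*b"):
            jc_distance_matrix(aln)


def _additive_distances(newick: str, labels: list[str]) -> np.ndarray:
    """Path-length distances on a tree: the NJ oracle input."""
    tree = parse_tree(newick)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return d


def _ls_best_topology(d: np.ndarray, labels: list[str]) -> frozenset:
    """Exhaustive least-squares search over all 15 unrooted 5-taxon topologies.

    Returns the non-trivial bipartition set of the best-fitting topology.
    """
    n = len(labels)
    assert n == 5
    best = None
    pairs = list(itertools.combinations(range(n), 2))
    for split1 in itertools.combinations(range(n), 2):
        rest = [i for i in range(n) if i not in split1]
        for split2 in itertools.combinations(rest, 2):
            # topology: cherry split1, cherry split2, fifth taxon on the spine
            bips = {
                frozenset(labels[i] for i in split1),
                frozenset(labels[i] for i in split2),
            }
            # design matrix: columns = 5 pendant edges + 2 internal edges
            A = np.zeros((len(pairs), 7))
            for r, (i, j) in enumerate(pairs):
                A[r, i] = A[r, j] = 1
                if (i in split1) != (j in split1):
                    A[r, 5] = 1
                if (i in split2) != (j in split2):
                    A[r, 6] = 1
            y = np.array([d[i, j] for i, j in pairs])
            x, res, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(((A @ x - y) ** 2).sum())
            if best is None or rss < best[0] - 1e-12:
                best = (rss, bips)
    return frozenset(frozenset(b) for b in best[1])


def _tree_bips(tree) -> frozenset:
    from discordpan.windows import tree_bipartitions

    leaves = {lv.taxon.label for lv in tree.leaf_node_iter()}
    out = set()
    for bip in tree_bipartitions(tree):
        out.add(min(bip, frozenset(leaves - bip), key=lambda s: (len(s), sorted(s))))
    return frozenset(out)


class TestNeighborJoining:
    def test_exact_on_additive_four_taxon_tree(self):
        labels = ["A", "B", "C", "D"]
        d = _additive_distances("((A:1,B:2):1,(C:1,D:1));", labels)
        tree = nj_tree(d, labels)
        assert canonical_topology(tree) == canonical_topology(
            parse_tree("((A,B),(C,D));")
        )
        # branch lengths recovered exactly on the additive matrix
        lengths = {
            lv.taxon.label: lv.edge.length for lv in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_five_taxon_topologies_match_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("ABCDE")
        # random caterpillar/balanced shapes with random positive lengths
        l = rng.uniform(0.5, 2.0, size=8)
        shapes = [
            f"(((A:{l[0]},B:{l[1]}):{l[5]},C:{l[2]}):{l[6]},(D:{l[3]},E:{l[4]}));",
            f"((A:{l[0]},B:{l[1]}):{l[5]},((C:{l[2]},D:{l[3]}):{l[6]},E:{l[4]}));",
        ]
        nwk = shapes[seed % 2]
        d = _additive_distances(nwk, labels)
        tree = nj_tree(d, labels)
        assert _tree_bips(tree) == _tree_bips(parse_tree(nwk))
        assert _tree_bips(tree) == _ls_best_topology(d, labels)

    def test_three_taxa_star(self):
        d = np.array([[0, 2.0, 3.0], [2.0, 0, 4.0], [3.0, 4.0, 0]])
        tree = nj_tree(d, ["a", "b", "c"])
        assert len(tree.seed_node.child_nodes()) == 3

    def test_matches_scikit_bio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(7)]
        # noisy additive matrix keeps a unique NJ solution
        base = _additive_distances(
            "(((t0:1,t1:1.2):0.8,(t2:0.9,t3:1.1):0.7):0.5,((t4:1,t5:1):0.6,t6:1.4));",
            labels,
        )
        noise = rng.uniform(0, 0.05, size=base.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        d = base + noise
        mine = nj_tree(d, labels)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        import io as _io

        ref = parse_tree(str(theirs))
        assert _tree_bips(mine) == _tree_bips(ref)

    def test_bootstrap_supports_high_on_clean_signal(self):
        rng = np.random.default_rng(1)
        # strongly resolved 4-taxon alignment
        tree = parse_tree("((A:0.05,B:0.05):0.1,(C:0.05,D:0.05):0.1);")
        from discordpan.simulate import SeqSimConfig, simulate_alignment

        aln = simulate_alignment(tree, SeqSimConfig(3000, 1.0, seed=5))
        d = jc_distance_matrix(aln)
        out = nj_tree(d, aln.taxon_labels, aln=aln, bootstrap=50, seed=2)
        supports = [
            n.support for n in out.postorder_node_iter() if hasattr(n, "support")
        ]
        assert supports and min(supports) > 90


ETB_GROUPS = {
    "pet1": "PET", "pet2": "PET", "lyc1": "LYC", "lyc2": "LYC",
    "etb1": "ETB", "out1": "OUT",
}


class TestClassifyTopology:
    def test_etb_sister_to_pet(self):
        t = parse_tree("(((etb1,(pet1,pet2)),(lyc1,lyc2)),out1);")
        assert classify_topology(t, ETB_GROUPS) == "ETB_sister_to_PET"

    def test_etb_sister_to_lyc(self):
        t = parse_tree("(((etb1,(lyc1,lyc2)),(pet1,pet2)),out1);")
        assert classify_topology(t, ETB_GROUPS) == "ETB_sister_to_LYC"

    def test_etb_outside_pet_lyc(self):
        t = parse_tree("((((pet1,pet2),(lyc1,lyc2)),etb1),out1);")
        assert classify_topology(t, ETB_GROUPS) == "ETB_sister_to_(PET+LYC)"

    def test_paraphyletic_group_is_other(self):
        t = parse_tree("(((pet1,(lyc1,pet2)),(lyc2,etb1)),out1);")
        assert classify_topology(t, ETB_GROUPS) == "other"

    def test_missing_outgroup_rejected(self):
        t = parse_tree("((pet1,pet2),(lyc1,(lyc2,etb1)));")
        with pytest.raises(ValueError, match="OUT"):
            classify_topology(t, ETB_GROUPS)


class TestSpectrum:
    def _record(self, nwk, cls=None):
        return WindowRecord(
            Region("chr1", 0, 1), 1, 0.0, tree=parse_tree(nwk), passed=True,
            topology_class=cls,
        )

    def test_identical_topologies_collapse(self):
        recs = [self._record("((A,B),(C,D));") for _ in range(10)]
        spec = topology_spectrum(recs)
        assert spec.n_windows_passed == 10
        assert spec.spectrum == {next(iter(spec.spectrum)): 10}
        assert spec.n_distinct_topologies == 1

    def test_branch_lengths_do_not_split_topologies(self):
        recs = [
            self._record("((A:1,B:2):0.5,(C:1,D:9));"),
            self._record("((B:5,A:1):2,(D:1,C:1));"),
        ]
        assert topology_spectrum(recs).n_distinct_topologies == 1

    def test_class_fractions_sum_to_one(self):
        recs = [
            self._record("((A,B),(C,D));", "ETB_sister_to_PET"),
            self._record("((A,C),(B,D));", "other"),
            self._record("((A,D),(B,C));", "other"),
        ]
        spec = topology_spectrum(recs)
        assert sum(spec.class_fractions.values()) == pytest.approx(1.0)
        assert sum(spec.class_counts.values()) == spec.n_windows_passed


class TestWindowPipeline:
    def test_simulated_windows_are_inferred_and_classified(self):
        from discordpan.workflows import simulate_loci_alignment

        stree = parse_tree("(((P:0.5,Q:0.5):1.0,R:1.5):1.0,S:2.5);")
        aln = simulate_loci_alignment(stree, 20, 1000, 0.05, seed=6)
        cfg = WindowFilterConfig(
            window_size=1000, min_aligned=500, max_missing=0.2, min_mean_bootstrap=60
        )
        groups = {"P": "PET", "Q": "LYC", "R": "ETB", "S": "OUT"}
        recs = build_window_records(aln, cfg, groups=groups, bootstrap=20, seed=1)
        assert len(recs) == 20
        spec = topology_spectrum(recs)
        assert spec.n_windows_passed > 0
        assert sum(spec.class_counts.values()) == spec.n_windows_passed
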