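"""End-to-end simulation/analysis pipelines built from the module surface.

These are the desk-scale study designs: multi-locus MSC + JC69 simulation
feeding the site-pattern statistics (D, f4-ratio), the windowed NJ
discordance pipeline, and observed-vs-simulated quartet-frequency
comparison. Defaults are the study conditions used throughout the tests and
the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np

from .io import MultiAlignment, Region, parse_tree
from .msc_compare import compare_frequencies, quartet_frequencies
from .simulate import (
    IntrogressionScenario,
    MSCConfig,
    SeqSimConfig,
    simulate_alignment_array,
    simulate_gene_trees,
)
from .site_patterns import (
    DStatResult,
    F4Result,
    block_jackknife,
    count_site_patterns,
    f4_ratio,
)
from .windows import (
    TopologySpectrum,
    WindowFilterConfig,
    build_window_records,
    topology_spectrum,
)

#: Four-taxon tree for D-statistic replicates: symmetric P1/P2 split 0.5
#: coalescent units below the P3 join, S. melongena-like outgroup far out.
DSTAT_SPECIES_TREE = "(((P1:1.0,P2:1.0):0.5,P3:1.5):1.0,O:2.5);"

#: Five-taxon Patterson configuration for the f4-ratio: recipient X sister to
#: B, reference A above them, donor C outside, outgroup O.
F4_SPECIES_TREE = "((((B:1.0,X:1.0):0.5,A:1.5):0.5,C:2.0):1.0,O:3.0);"

#: Five-species caterpillar with 0.5-unit internal branches for the
#: end-to-end self-consistency design.
END_TO_END_SPECIES_TREE = (
    "((((A:0.5,B:0.5):0.5,C:1.0):0.5,D:1.5):0.5,O:2.0);"
)


def _locus_seed(master: int, locus: int, salt: int) -> int:
    return int(np.random.SeedSequence([master, locus, salt]).generate_state(1)[0] % (2**31))


def simulate_loci_alignment(
    species_tree: dendropy.Tree,
    n_loci: int,
    locus_length: int,
    mutation_scale: float,
    seed: int,
    scenario: Optional[IntrogressionScenario] = None,
    chrom: str = "sim",
) -> MultiAlignment:
    """MSC gene trees + JC69 loci, concatenated into one reference-anchored
    alignment (locus k occupies columns [k*L, (k+1)*L))."""
    trees, _ = simulate_gene_trees(
        MSCConfig(species_tree, n_loci=n_loci, seed=seed, scenario=scenario)
    )
    labels = sorted(
        lv.taxon.label for lv in species_tree.leaf_node_iter()
    )
    chunks = []
    for i, gt in enumerate(trees):
        arr, arr_labels = simulate_alignment_array(
            gt, SeqSimConfig(locus_length, mutation_scale, seed=_locus_seed(seed, i, 7))
        )
        order = [arr_labels.index(l) for l in labels]
        chunks.append(arr[order])
    big = np.hstack(chunks)
    return MultiAlignment.from_array(
        labels, big, region=Region(chrom, 0, n_loci * locus_length)
    )


def dstat_replicate(
    seed: int,
    gamma: float = 0.0,
    n_loci: int = 2000,
    locus_length: int = 500,
    mutation_scale: float = 0.01,
    n_blocks: int = 20,
    t_m: float = 0.5,
) -> DStatResult:
    """One D-statistic replicate on the four-taxon design.

    With ``gamma > 0`` a P3 -> P2 pulse at ``t_m`` coalescent units injects
    donor ancestry into P2, inflating ABBA over BABA.
    """
    stree = parse_tree(DSTAT_SPECIES_TREE)
    scenario = None
    if gamma > 0:
        scenario = IntrogressionScenario("P3", "P2", t_m, gamma)
    aln = simulate_loci_alignment(
        stree, n_loci, locus_length, mutation_scale, seed, scenario
    )
    groups = {"P1": "P1", "P2": "P2", "P3": "P3", "O": "O"}
    blocks = count_site_patterns(aln, groups, n_blocks=n_blocks)
    return block_jackknife(blocks)


def f4_ratio_replicate(
    seed: int,
    gamma: float = 0.3,
    n_loci: int = 2000,
    locus_length: int = 500,
    mutation_scale: float = 0.01,
    n_blocks: int = 20,
    t_m: float = 0.5,
) -> F4Result:
    """One f4-ratio replicate in the Patterson configuration.

    alpha = f4(A,O;X,B) / f4(A,O;C,B) estimates the C -> X pulse fraction.
    """
    stree = parse_tree(F4_SPECIES_TREE)
    scenario = None
    if gamma > 0:
        scenario = IntrogressionScenario("C", "X", t_m, gamma)
    aln = simulate_loci_alignment(
        stree, n_loci, locus_length, mutation_scale, seed, scenario
    )
    groups = {t: t for t in ("A", "B", "C", "X", "O")}
    return f4_ratio(
        aln,
        numerator_quartet=("A", "O", "X", "B"),
        denominator_quartet=("A", "O", "C", "B"),
        groups=groups,
        n_blocks=n_blocks,
    )


@dataclass
class EndToEndResult:
    """Self-consistency summary of the simulate -> windows -> compare design."""

    pearson_r: float
    spectrum: TopologySpectrum
    max_abs_z: float
    dstat_by_trio: dict[tuple[str, str, str], DStatResult]


#: Trios of the end-to-end species tree, ordered (P1, P2, P3) by relatedness.
END_TO_END_TRIOS = (
    ("A", "B", "C"),
    ("A", "B", "D"),
    ("A", "C", "D"),
    ("B", "C", "D"),
)


def end_to_end_self_consistency(
    seed: int,
    n_windows: int = 300,
    locus_length: int = 2000,
    mutation_scale: float = 0.05,
    bootstrap: int = 50,
    n_sim_trees: int = 5000,
) -> EndToEndResult:
    """No-gene-flow self-consistency run on the five-species design.

    Simulates ``n_windows`` loci, infers per-window NJ trees, compares the
    window-tree quartet frequencies against a fresh MSC simulation (Pearson
    r), and computes D/Z for every species-tree-ordered trio on the same
    alignment (expected null).
    """
    stree = parse_tree(END_TO_END_SPECIES_TREE)
    aln = simulate_loci_alignment(
        stree, n_windows, locus_length, mutation_scale, seed
    )
    cfg = WindowFilterConfig(
        window_size=locus_length,
        min_aligned=locus_length // 2,
        max_missing=0.20,
        min_mean_bootstrap=80.0,
    )
    records = build_window_records(aln, cfg, bootstrap=bootstrap, seed=seed)
    spectrum = topology_spectrum(records)

    species = sorted(lv.taxon.label for lv in stree.leaf_node_iter())
    window_trees = [r.tree for r in records if r.passed and r.tree is not None]
    obs = quartet_frequencies(window_trees, species)
    fresh, _ = simulate_gene_trees(
        MSCConfig(stree, n_loci=n_sim_trees, seed=seed + 1)
    )
    sim = quartet_frequencies(fresh, species)
    r, _ = compare_frequencies(obs, sim)

    dstats = {}
    max_abs_z = 0.0
    for trio in END_TO_END_TRIOS:
        groups = {trio[0]: "P1", trio[1]: "P2", trio[2]: "P3", "O": "O"}
        blocks = count_site_patterns(aln, groups, n_blocks=20)
        res = block_jackknife(blocks)
        dstats[trio] = res
        if np.isfinite(res.Z):
            max_abs_z = max(max_abs_z, abs(res.Z))
    return EndToEndResult(r, spectrum, max_abs_z, dstats)
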