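"""Pan-gene occupancy classification, accumulation curves and NG86 Ka/Ks.

Clusters are classified by how many accessions carry them: core (all n),
soft-core (nearly all: 42-44 of 45, generalized as [ceil(0.933 n), n-1]),
accession-specific (exactly 1) and shell (everything between). Pan/core
accumulation curves follow the totally-random design: at each genome count
k, sample subsets uniformly (500 combinations, 30 replications by default).

Ka/Ks uses the Nei-Gojobori (1986) method: per-codon synonymous site
fractions from the nine single-nucleotide neighbors, differences averaged
over all minimal mutational pathways (pathways through stop codons skipped
and the rest renormalized), and a Jukes-Cantor correction of the
proportions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import PresenceAbsenceMatrix

CATEGORIES = ("core", "soft_core", "shell", "specific")

#: Standard genetic code on DNA codons; '*' marks stops.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_BASES = "ACGT"


class CdsError(ValueError):
    """Raised for CDS pairs that violate the codon-alignment contract."""


# ---------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class PanThresholds:
    """Occupancy bands partitioning 1..n into the four categories.

    At n = 45 the defaults reproduce the published bands exactly:
    core {45}, soft-core {42..44}, shell {2..41}, specific {1}.
    """

    n: int
    soft_core_min: int

    @classmethod
    def for_n(cls, n: int, soft_core_min: Optional[int] = None) -> "PanThresholds":
        if n < 5:
            raise ValueError("need >= 5 accessions (category bands degenerate)")
        if soft_core_min is None:
            soft_core_min = min(int(math.ceil(0.933 * n)), n - 1)
        soft_core_min = max(soft_core_min, 3)
        if not 3 <= soft_core_min <= n - 1:
            raise ValueError("soft_core_min out of range")
        return cls(n, soft_core_min)

    def category(self, occupancy: int) -> str:
        if not 1 <= occupancy <= self.n:
            raise ValueError(f"occupancy {occupancy} outside 1..{self.n}")
        if occupancy == self.n:
            return "core"
        if occupancy >= self.soft_core_min:
            return "soft_core"
        if occupancy == 1:
            return "specific"
        return "shell"

    @property
    def bands(self) -> dict[str, tuple[int, int]]:
        return {
            "core": (self.n, self.n),
            "soft_core": (self.soft_core_min, self.n - 1),
            "shell": (2, self.soft_core_min - 1),
            "specific": (1, 1),
        }


@dataclass
class PanClassification:
    labels: list[str]  # per-cluster category, in matrix row order
    counts: dict[str, int]
    fractions: dict[str, float]
    thresholds: PanThresholds


def classify_clusters(
    matrix: PresenceAbsenceMatrix, thresholds: Optional[PanThresholds] = None
) -> PanClassification:
    """Assign each cluster its occupancy category and summarize counts."""
    if thresholds is None:
        thresholds = PanThresholds.for_n(matrix.n_accessions)
    if thresholds.n != matrix.n_accessions:
        raise ValueError("thresholds built for a different accession count")
    occ = matrix.occupancy()
    labels = [thresholds.category(int(o)) for o in occ]
    counts = {c: labels.count(c) for c in CATEGORIES}
    total = len(labels)
    fractions = {c: (counts[c] / total if total else 0.0) for c in CATEGORIES}
    return PanClassification(labels, counts, fractions, thresholds)


# ---------------------------------------------------------------------------
# Accumulation curve


@dataclass
class AccumulationCurve:
    """Pan/core cluster counts as genomes are added in random order."""

    k: np.ndarray
    pan_mean: np.ndarray
    pan_min: np.ndarray
    pan_max: np.ndarray
    core_mean: np.ndarray
    core_min: np.ndarray
    core_max: np.ndarray
    n_combinations: int
    replications: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "pan_mean": self.pan_mean,
                "pan_min": self.pan_min,
                "pan_max": self.pan_max,
                "core_mean": self.core_mean,
                "core_min": self.core_min,
                "core_max": self.core_max,
            }
        )


def accumulation_curve(
    matrix: PresenceAbsenceMatrix,
    n_combinations: int = 500,
    replications: int = 30,
    seed: int = 0,
) -> AccumulationCurve:
    """Totally-random pan/core accumulation curve.

    For each k in 1..n and each replication, min(n_combinations, C(n, k))
    accession subsets are drawn uniformly (all distinct subsets enumerated
    when C(n, k) is within the budget); pan size counts clusters present in
    at least one sampled accession, core size clusters present in all.
    """
    vals = matrix.values.astype(bool)
    n = matrix.n_accessions
    if n < 2:
        raise ValueError("need >= 2 accessions")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, n + 1)
    shape = (len(ks),)
    pan_mean = np.zeros(shape)
    pan_min = np.zeros(shape)
    pan_max = np.zeros(shape)
    core_mean = np.zeros(shape)
    core_min = np.zeros(shape)
    core_max = np.zeros(shape)
    for ki, k in enumerate(ks):
        total_subsets = math.comb(n, int(k))
        rep_pan, rep_core = [], []
        all_pan, all_core = [], []
        for _ in range(replications):
            if total_subsets <= n_combinations:
                subsets = [list(s) for s in itertools.combinations(range(n), int(k))]
            else:
                subsets = [
                    rng.choice(n, size=int(k), replace=False) for _ in range(n_combinations)
                ]
            pans, cores = [], []
            for cols in subsets:
                sub = vals[:, cols]
                pans.append(int(sub.any(axis=1).sum()))
                cores.append(int(sub.all(axis=1).sum()))
            rep_pan.append(float(np.mean(pans)))
            rep_core.append(float(np.mean(cores)))
            all_pan.extend(pans)
            all_core.extend(cores)
        pan_mean[ki] = float(np.mean(rep_pan))
        core_mean[ki] = float(np.mean(rep_core))
        pan_min[ki], pan_max[ki] = min(all_pan), max(all_pan)
        core_min[ki], core_max[ki] = min(all_core), max(all_core)
    return AccumulationCurve(
        ks, pan_mean, pan_min, pan_max, core_mean, core_min, core_max,
        n_combinations, replications, seed,
    )


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


@dataclass
class KaKsResult:
    Ka: float
    Ks: float
    ratio: Optional[float]  # None when Ks = 0 (flagged undefined)
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    saturated: bool = False


def _codon_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site fractions from the 9 neighbors.

    Each position contributes the fraction of its three possible changes that
    are synonymous; changes creating a stop codon count as nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return 3.0 - s, s


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences, averaged over minimal pathways.

    Pathways passing through a stop codon are skipped and the remainder
    renormalized; if every pathway is blocked, all are used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*" and len(diff_pos) > 1 and nxt != c2:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((steps, blocked))
    usable = [p for p, blocked in pathways if not blocked]
    if not usable:
        usable = [p for p, _ in pathways]
    nd = sd = 0.0
    for steps in usable:
        for a, b in steps:
            if GENETIC_CODE[a] == GENETIC_CODE[b] and GENETIC_CODE[a] != "*":
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return nd / k, sd / k


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("inf"), True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0, False


def ng86_kaks(cds1: str, cds2: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for a codon-aligned CDS pair.

    Sequences must be equal length, a multiple of 3, and free of internal
    stop codons; codons containing a gap or ambiguity in either sequence are
    skipped. ``ratio`` is None (flagged) when Ks = 0.
    """
    cds1, cds2 = cds1.upper(), cds2.upper()
    if len(cds1) != len(cds2):
        raise CdsError("sequences differ in length")
    if len(cds1) % 3:
        raise CdsError("length not a multiple of 3")
    n_codons = len(cds1) // 3
    N = S = Nd = Sd = 0.0
    for i in range(n_codons):
        c1 = cds1[3 * i: 3 * i + 3]
        c2 = cds2[3 * i: 3 * i + 3]
        if c1 not in GENETIC_CODE or c2 not in GENETIC_CODE:
            continue  # gap or ambiguity
        for which, c in (("first", c1), ("second", c2)):
            if GENETIC_CODE[c] == "*" and i < n_codons - 1:
                raise CdsError(f"internal stop codon at codon {i} in {which} sequence")
        if GENETIC_CODE[c1] == "*" or GENETIC_CODE[c2] == "*":
            continue  # terminal stop codons carry no site information
        n1, s1 = _codon_sites(c1)
        n2, s2 = _codon_sites(c2)
        N += (n1 + n2) / 2.0
        S += (s1 + s2) / 2.0
        nd, sd = _codon_differences(c1, c2)
        Nd += nd
        Sd += sd
    if N == 0 and S == 0:
        raise CdsError("no comparable codons")
    pn = Nd / N if N > 0 else 0.0
    ps = Sd / S if S > 0 else 0.0
    ka, sat_n = _jc_correct(pn)
    ks, sat_s = _jc_correct(ps)
    saturated = sat_n or sat_s
    ratio = None
    if ks > 0 and math.isfinite(ks) and math.isfinite(ka):
        ratio = ka / ks
    return KaKsResult(ka, ks, ratio, N, S, Nd, Sd, saturated=saturated)
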