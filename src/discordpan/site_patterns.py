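"""Polarized site-pattern counts and gene-flow / ILS statistics.

Counts the six polarized biallelic patterns (BAAA, ABAA, AABA, BBAA, ABBA,
BABA) for a (P1, P2, P3, O) group assignment, and derives from them:

* the ABBA-BABA D statistic with a delete-one block-jackknife Z score;
* four-population f4 and the f4-ratio admixture-fraction estimate alpha;
* the per-site ILS fraction
  (C_ABBA + C_BABA) / [(C_BAAA + C_ABAA + C_AABA + 2(C_BBAA + C_BABA + C_ABBA)) / 3].

Pattern accumulation is frequency-weighted (Patterson style): with
per-group derived-allele frequencies p1, p2, p3 a site adds
(1-p1) p2 p3 to ABBA, p1 (1-p2) p3 to BABA, and so on; with one haploid
sample per group this reduces to integer pattern counting. The ancestral
state is the outgroup consensus; sites with a polymorphic or missing
outgroup, or more than two alleles, are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .io import MultiAlignment, Region, SnpTable

GROUP_NAMES = ("P1", "P2", "P3", "O")


class UndefinedStatisticError(ValueError):
    """Raised when a statistic's denominator is zero / empty."""


@dataclass
class SitePatternCounts:
    """Frequency-weighted accumulators for the six polarized site patterns."""

    c_baaa: float = 0.0
    c_abaa: float = 0.0
    c_aaba: float = 0.0
    c_bbaa: float = 0.0
    c_abba: float = 0.0
    c_baba: float = 0.0
    n_sites_used: int = 0
    block_id: Optional[str] = None

    def __add__(self, other: "SitePatternCounts") -> "SitePatternCounts":
        return SitePatternCounts(
            self.c_baaa + other.c_baaa,
            self.c_abaa + other.c_abaa,
            self.c_aaba + other.c_aaba,
            self.c_bbaa + other.c_bbaa,
            self.c_abba + other.c_abba,
            self.c_baba + other.c_baba,
            self.n_sites_used + other.n_sites_used,
        )

    def total(self) -> float:
        return (
            self.c_baaa + self.c_abaa + self.c_aaba
            + self.c_bbaa + self.c_abba + self.c_baba
        )


@dataclass
class DStatResult:
    """D with its block-jackknife standard error and Z score."""

    D: float
    Z: float
    jackknife_SE: float
    n_blocks: int
    counts: SitePatternCounts
    z_defined: bool = True


@dataclass
class F4BlockSums:
    """Per-block running sums for an f4 quartet: sum of (pW-pX)(pY-pZ) and n sites."""

    sums: np.ndarray
    n_sites: np.ndarray

    @property
    def f4_total(self) -> float:
        n = float(self.n_sites.sum())
        if n == 0:
            raise UndefinedStatisticError("no usable sites for f4")
        return float(self.sums.sum()) / n


@dataclass
class F4Result:
    """An f4 statistic (optionally an f4-ratio alpha) with jackknife uncertainty."""

    f4: float
    Z: float
    jackknife_SE: float
    n_blocks: int
    n_sites: int
    quartet: tuple[str, str, str, str]
    alpha: Optional[float] = None
    alpha_SE: Optional[float] = None
    alpha_Z: Optional[float] = None
    denominator_quartet: Optional[tuple[str, str, str, str]] = None


@dataclass
class ILSProfile:
    """Per-block ILS values and the fraction of blocks above a cutoff."""

    per_block: list[float]
    cutoff: float
    genome_fraction_ils: float


# ---------------------------------------------------------------------------
# Per-site group frequencies


def _group_frequencies(
    data: Union[MultiAlignment, SnpTable],
    groups: dict[str, str],
    group_names: Sequence[str],
    polarize: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site derived (or arbitrary-allele) frequencies for each group.

    Returns ``(freqs, usable, positions)`` where ``freqs`` is a
    (len(group_names), n_sites) float array, ``usable`` a boolean mask of
    sites passing the biallelic/polarization rules and ``positions`` the
    0-based reference coordinates of the sites (column index when the
    alignment has no region).

    With ``polarize`` the last group is the outgroup and frequencies are of
    the derived allele; otherwise frequencies are of one consistent allele
    per site (f4 is invariant to which).
    """
    if isinstance(data, MultiAlignment):
        return _group_frequencies_alignment(data, groups, group_names, polarize)
    return _group_frequencies_snps(data, groups, group_names, polarize)


def _group_rows(labels: list[str], groups: dict[str, str], name: str) -> list[int]:
    rows = [i for i, t in enumerate(labels) if groups.get(t) == name]
    if not rows:
        raise ConfigErrorLike(f"group {name!r} has no taxa in the data")
    return rows


class ConfigErrorLike(ValueError):
    """Group assignment does not match the data."""


def _group_frequencies_alignment(aln, groups, group_names, polarize):
    arr = aln.to_array()
    for taxon in groups:
        if taxon not in aln.taxon_labels:
            raise ConfigErrorLike(f"taxon {taxon!r} not in alignment")
    idx = {g: _group_rows(aln.taxon_labels, groups, g) for g in group_names}
    n_cols = arr.shape[1]

    # allele counts per group: (n_groups, 4, cols)
    counts = np.empty((len(group_names), 4, n_cols), dtype=np.int32)
    for gi, g in enumerate(group_names):
        sub = arr[idx[g]]
        for a in range(4):
            counts[gi, a] = (sub == a).sum(axis=0)
    nonmissing = counts.sum(axis=1)  # (n_groups, cols)
    usable = (nonmissing > 0).all(axis=0)

    total = counts.sum(axis=0)  # (4, cols) pooled allele counts over all groups
    if polarize:
        out_counts = counts[-1]  # outgroup is last
        out_ok = (out_counts > 0).sum(axis=0) == 1  # fixed, non-missing
        anc = out_counts.argmax(axis=0)
        ingroup = total - out_counts
        non_anc = ingroup.copy()
        np.put_along_axis(non_anc, anc[None, :], 0, axis=0)
        n_other = (non_anc > 0).sum(axis=0)
        usable &= out_ok & (n_other == 1)  # biallelic and segregating in the ingroup
        target = non_anc.argmax(axis=0)
    else:
        n_alleles = (total > 0).sum(axis=0)
        usable &= n_alleles == 2
        target = total.argmax(axis=0)  # one consistent allele per site

    cols = np.arange(n_cols)
    freqs = counts[:, target, cols] / np.maximum(nonmissing, 1)
    start = aln.region.start if aln.region is not None else 0
    return freqs.astype(float), usable, start + cols


def _group_frequencies_snps(table: SnpTable, groups, group_names, polarize):
    for taxon in groups:
        if taxon not in table.taxa:
            raise ConfigErrorLike(f"taxon {taxon!r} not in SNP table")
    idx = {g: _group_rows(table.taxa, groups, g) for g in group_names}
    n_sites = len(table.sites)
    fmat = np.full((len(table.taxa), n_sites), np.nan)
    for j, site in enumerate(table.sites):
        for i, t in enumerate(table.taxa):
            v = site.freqs.get(t)
            if v is not None:
                fmat[i, j] = v

    freqs = np.empty((len(group_names), n_sites))
    has_data = np.ones(n_sites, dtype=bool)
    for gi, g in enumerate(group_names):
        sub = fmat[idx[g]]
        ok = ~np.isnan(sub)
        cnt = ok.sum(axis=0)
        has_data &= cnt > 0
        with np.errstate(invalid="ignore"):
            freqs[gi] = np.nansum(sub, axis=0) / np.maximum(cnt, 1)
    usable = has_data
    if polarize:
        out = freqs[-1]
        fixed_ref = np.isclose(out, 0.0)
        fixed_alt = np.isclose(out, 1.0)
        usable = usable & (fixed_ref | fixed_alt)
        # where the outgroup carries ALT, the derived allele is REF
        freqs = np.where(fixed_alt[None, :], 1.0 - freqs, freqs)
        seg = (freqs[:-1] > 0).any(axis=0)
        usable &= seg
    positions = np.array([s.pos for s in table.sites])
    return freqs, usable, positions


def _block_assignment(
    positions: np.ndarray,
    usable: np.ndarray,
    blocks: Optional[Sequence[Region]],
    n_blocks: Optional[int],
    chroms: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, list[str]]:
    """Map usable sites to block indices; -1 drops a site from all blocks."""
    n = len(positions)
    assign = np.full(n, -1, dtype=int)
    if blocks is not None:
        ids = []
        for bi, reg in enumerate(blocks):
            in_block = (positions >= reg.start) & (positions < reg.end)
            if chroms is not None:
                in_block &= np.asarray(chroms) == reg.chrom
            assign[in_block] = bi
            ids.append(f"{reg.chrom}:{reg.start}-{reg.end}")
        assign[~usable] = -1
        return assign, ids
    k = n_blocks or 1
    usable_idx = np.flatnonzero(usable)
    if len(usable_idx) == 0:
        return assign, [f"block{i}" for i in range(k)]
    # contiguous equal-count chunks of usable sites
    chunk = np.minimum((np.arange(len(usable_idx)) * k) // max(len(usable_idx), 1), k - 1)
    assign[usable_idx] = chunk
    return assign, [f"block{i}" for i in range(k)]


# ---------------------------------------------------------------------------
# Pattern counting


def count_site_patterns(
    data: Union[MultiAlignment, SnpTable],
    groups: dict[str, str],
    blocks: Optional[Sequence[Region]] = None,
    n_blocks: Optional[int] = None,
    frequency_weighted: bool = True,
) -> list[SitePatternCounts]:
    """Count polarized site patterns, one :class:`SitePatternCounts` per block.

    ``groups`` maps taxon labels to ``P1``/``P2``/``P3``/``O``. With no
    ``blocks`` (BED regions) and no ``n_blocks`` a single pooled block is
    returned; ``n_blocks`` splits usable sites into contiguous equal-count
    chunks. ``frequency_weighted=False`` rounds group frequencies to the
    group consensus (ties skipped) before accumulating.
    """
    freqs, usable, positions = _group_frequencies(data, groups, GROUP_NAMES, polarize=True)
    chroms = None
    if isinstance(data, SnpTable):
        chroms = [s.chrom for s in data.sites]
    assign, block_ids = _block_assignment(positions, usable, blocks, n_blocks, chroms)

    p1, p2, p3 = freqs[0], freqs[1], freqs[2]
    if not frequency_weighted:
        ties = np.isclose(p1, 0.5) | np.isclose(p2, 0.5) | np.isclose(p3, 0.5)
        assign = assign.copy()
        assign[ties] = -1
        p1, p2, p3 = np.round(p1), np.round(p2), np.round(p3)

    q1, q2, q3 = 1 - p1, 1 - p2, 1 - p3
    weights = {
        "c_baaa": p1 * q2 * q3,
        "c_abaa": q1 * p2 * q3,
        "c_aaba": q1 * q2 * p3,
        "c_bbaa": p1 * p2 * q3,
        "c_abba": q1 * p2 * p3,
        "c_baba": p1 * q2 * p3,
    }
    results = []
    for bi, bid in enumerate(block_ids):
        mask = assign == bi
        counts = SitePatternCounts(block_id=bid, n_sites_used=int(mask.sum()))
        for name, w in weights.items():
            setattr(counts, name, float(w[mask].sum()))
        results.append(counts)
    return results


def pool_counts(block_counts: Sequence[SitePatternCounts]) -> SitePatternCounts:
    total = SitePatternCounts()
    for c in block_counts:
        total = total + c
    return total


# ---------------------------------------------------------------------------
# D statistic and jackknife


def d_statistic(counts: SitePatternCounts) -> float:
    """D = (ABBA - BABA) / (ABBA + BABA)."""
    denom = counts.c_abba + counts.c_baba
    if denom <= 0:
        raise UndefinedStatisticError("c_ABBA + c_BABA = 0; D undefined")
    return (counts.c_abba - counts.c_baba) / denom


def block_jackknife(
    block_counts: Sequence[SitePatternCounts],
    statistic: Union[str, Callable[[SitePatternCounts], float]] = "D",
) -> DStatResult:
    """Delete-one block jackknife over :class:`SitePatternCounts` blocks.

    The pseudo-statistic for each deleted block is recomputed on the pooled
    remaining counts; SE^2 = ((n-1)/n) * sum((D_-i - mean)^2) and
    Z = D_total / SE. Empty blocks (no usable sites) are ignored.
    """
    func = d_statistic if statistic == "D" else statistic
    nonempty = [c for c in block_counts if c.n_sites_used > 0]
    if len(nonempty) < 2:
        raise UndefinedStatisticError("need >= 2 non-empty blocks for the jackknife")
    total = pool_counts(nonempty)
    d_total = func(total)
    pseudo = []
    for i, c in enumerate(nonempty):
        rest = SitePatternCounts(
            total.c_baaa - c.c_baaa,
            total.c_abaa - c.c_abaa,
            total.c_aaba - c.c_aaba,
            total.c_bbaa - c.c_bbaa,
            total.c_abba - c.c_abba,
            total.c_baba - c.c_baba,
            total.n_sites_used - c.n_sites_used,
        )
        pseudo.append(func(rest))
    pseudo = np.asarray(pseudo)
    n = len(pseudo)
    se = math.sqrt((n - 1) / n * float(((pseudo - pseudo.mean()) ** 2).sum()))
    if se > 0:
        return DStatResult(d_total, d_total / se, se, n, total)
    z = 0.0 if d_total == 0 else float("nan")
    return DStatResult(d_total, z, 0.0, n, total, z_defined=(d_total == 0))


# ---------------------------------------------------------------------------
# f4 and f4-ratio


def f4_block_sums(
    data: Union[MultiAlignment, SnpTable],
    quartet: tuple[str, str, str, str],
    groups: dict[str, str],
    blocks: Optional[Sequence[Region]] = None,
    n_blocks: Optional[int] = None,
) -> F4BlockSums:
    """Per-block sums of (pW - pX)(pY - pZ) for the ordered group quartet."""
    freqs, usable, positions = _group_frequencies(data, groups, quartet, polarize=False)
    chroms = [s.chrom for s in data.sites] if isinstance(data, SnpTable) else None
    assign, block_ids = _block_assignment(positions, usable, blocks, n_blocks, chroms)
    contrib = (freqs[0] - freqs[1]) * (freqs[2] - freqs[3])
    k = len(block_ids)
    sums = np.zeros(k)
    ns = np.zeros(k, dtype=int)
    for bi in range(k):
        mask = assign == bi
        sums[bi] = float(contrib[mask].sum())
        ns[bi] = int(mask.sum())
    return F4BlockSums(sums, ns)


def _jackknife_ratio(
    num: F4BlockSums, den: F4BlockSums
) -> tuple[float, float, int]:
    """Delete-one jackknife on a ratio of per-block (sum, n) accumulators."""
    keep = (num.n_sites + den.n_sites) > 0
    ns, nn = num.sums[keep], num.n_sites[keep]
    ds, dn = den.sums[keep], den.n_sites[keep]
    n = int(keep.sum())
    if n < 2:
        raise UndefinedStatisticError("need >= 2 non-empty blocks")
    tot = _ratio_of_means(ns.sum(), nn.sum(), ds.sum(), dn.sum())
    pseudo = np.array(
        [
            _ratio_of_means(ns.sum() - ns[i], nn.sum() - nn[i], ds.sum() - ds[i], dn.sum() - dn[i])
            for i in range(n)
        ]
    )
    se = math.sqrt((n - 1) / n * float(((pseudo - pseudo.mean()) ** 2).sum()))
    return tot, se, n


def _ratio_of_means(num_sum, num_n, den_sum, den_n) -> float:
    if den_n == 0 or num_n == 0:
        raise UndefinedStatisticError("empty jackknife remainder")
    den = den_sum / den_n
    if den == 0:
        raise UndefinedStatisticError("zero denominator f4 in jackknife")
    return (num_sum / num_n) / den


def f4(
    data: Union[MultiAlignment, SnpTable],
    quartet: tuple[str, str, str, str],
    groups: dict[str, str],
    blocks: Optional[Sequence[Region]] = None,
    n_blocks: int = 20,
) -> F4Result:
    """f4(W,X;Y,Z) = mean over usable sites of (pW - pX)(pY - pZ), with a
    block-jackknife Z score (default 20 equal-count blocks)."""
    bs = f4_block_sums(data, quartet, groups, blocks, n_blocks)
    keep = bs.n_sites > 0
    n = int(keep.sum())
    if bs.n_sites.sum() == 0:
        raise UndefinedStatisticError("no usable sites for f4")
    total = bs.f4_total
    if n >= 2:
        sums, ns = bs.sums[keep], bs.n_sites[keep]
        pseudo = np.array(
            [(sums.sum() - sums[i]) / (ns.sum() - ns[i]) for i in range(n)]
        )
        se = math.sqrt((n - 1) / n * float(((pseudo - pseudo.mean()) ** 2).sum()))
    else:
        se = 0.0
    z = total / se if se > 0 else (0.0 if total == 0 else float("nan"))
    return F4Result(total, z, se, n, int(bs.n_sites.sum()), quartet)


def f4_ratio(
    data: Union[MultiAlignment, SnpTable],
    numerator_quartet: tuple[str, str, str, str],
    denominator_quartet: tuple[str, str, str, str],
    groups: dict[str, str],
    blocks: Optional[Sequence[Region]] = None,
    n_blocks: int = 20,
    min_denominator_z: float = 3.0,
) -> F4Result:
    """f4-ratio alpha = f4(numerator) / f4(denominator), jackknifed over blocks.

    In the Patterson configuration for a species tree (((A,B),X? ...),O) with
    recipient X admixed from donor C, alpha = f4(A,O;X,B) / f4(A,O;C,B)
    estimates the admixture fraction gamma. The denominator must be
    significantly non-zero (|Z| >= ``min_denominator_z``).
    """
    den_res = f4(data, denominator_quartet, groups, blocks, n_blocks)
    if not math.isfinite(den_res.Z) or abs(den_res.Z) < min_denominator_z:
        raise UndefinedStatisticError(
            f"denominator f4 not significantly non-zero (Z={den_res.Z:.3g})"
        )
    num = f4_block_sums(data, numerator_quartet, groups, blocks, n_blocks)
    den = f4_block_sums(data, denominator_quartet, groups, blocks, n_blocks)
    alpha, alpha_se, n = _jackknife_ratio(num, den)
    num_res = f4(data, numerator_quartet, groups, blocks, n_blocks)
    return F4Result(
        num_res.f4,
        num_res.Z,
        num_res.jackknife_SE,
        n,
        num_res.n_sites,
        numerator_quartet,
        alpha=alpha,
        alpha_SE=alpha_se,
        alpha_Z=alpha / alpha_se if alpha_se > 0 else float("nan"),
        denominator_quartet=denominator_quartet,
    )


# ---------------------------------------------------------------------------
# ILS


def ils_fraction(counts: SitePatternCounts) -> float:
    """ILS level: (C_ABBA + C_BABA) divided by the (weighted third of the)
    total count of segregating sites,
    (C_BAAA + C_ABAA + C_AABA + 2 (C_BBAA + C_BABA + C_ABBA)) / 3."""
    denom = (
        counts.c_baaa + counts.c_abaa + counts.c_aaba
        + 2.0 * (counts.c_bbaa + counts.c_baba + counts.c_abba)
    ) / 3.0
    if denom <= 0:
        raise UndefinedStatisticError("zero denominator in ILS fraction")
    return (counts.c_abba + counts.c_baba) / denom


def ils_profile(
    block_counts: Sequence[SitePatternCounts], cutoff: float = 0.5
) -> ILSProfile:
    """Per-block ILS values and the fraction of blocks above ``cutoff``.

    The block-fraction rule is a stand-in aggregation (the published
    genome-wide per cent was produced by an unspecified per-SNP aggregation);
    the per-block values themselves follow the per-site formula on pooled
    counts.
    """
    values = []
    for c in block_counts:
        if c.n_sites_used == 0:
            continue
        try:
            values.append(ils_fraction(c))
        except UndefinedStatisticError:
            values.append(0.0)
    if not values:
        raise UndefinedStatisticError("no non-empty blocks")
    frac = sum(v > cutoff for v in values) / len(values)
    return ILSProfile(values, cutoff, frac)
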