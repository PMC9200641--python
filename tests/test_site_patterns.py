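import math

import numpy as np
import pytest

from discordpan.io import MultiAlignment, SnpSite, SnpTable
from discordpan.site_patterns import (
    SitePatternCounts,
    UndefinedStatisticError,
    block_jackknife,
    count_site_patterns,
    d_statistic,
    f4,
    f4_ratio,
    ils_fraction,
    ils_profile,
    pool_counts,
)

GROUPS = {"P1": "P1", "P2": "P2", "P3": "P3", "O": "O"}


class TestCountSitePatterns:
    def test_no_segregating_sites_gives_zero_counts(self):
        aln = MultiAlignment(["P1", "P2", "P3", "O"], ["AAAA"] * 4)
        (counts,) = count_site_patterns(aln, GROUPS)
        assert counts.total() == 0
        assert counts.n_sites_used == 0

    def test_manual_per_site_classification(self, four_taxon_alignment):
        # sites: (G,A,A,A)->BAAA  (A,G,G,A)->ABBA  (G,A,G,A)->BABA
        (counts,) = count_site_patterns(four_taxon_alignment, GROUPS)
        assert counts.c_baaa == 1
        assert counts.c_abba == 1
        assert counts.c_baba == 1
        assert counts.c_abaa == counts.c_aaba == counts.c_bbaa == 0
        assert counts.n_sites_used == 3

    def test_frequency_weighting_splits_half_derived_site(self):
        # p1 = p2 = 0.5, p3 = 1 at a single site
        aln = MultiAlignment(
            ["P1a", "P1b", "P2a", "P2b", "P3", "O"],
            ["G", "A", "G", "A", "G", "A"],
        )
        groups = {"P1a": "P1", "P1b": "P1", "P2a": "P2", "P2b": "P2", "P3": "P3", "O": "O"}
        (counts,) = count_site_patterns(aln, groups)
        assert counts.c_abba == pytest.approx(0.25)
        assert counts.c_baba == pytest.approx(0.25)

    def test_polymorphic_outgroup_site_skipped(self):
        aln = MultiAlignment(
            ["P1", "P2", "P3", "O1", "O2"],
            ["G", "A", "A", "A", "G"],
        )
        groups = dict(GROUPS, O1="O", O2="O")
        del groups["O"]
        (counts,) = count_site_patterns(aln, groups)
        assert counts.n_sites_used == 0

    def test_triallelic_site_skipped(self):
        aln = MultiAlignment(["P1", "P2", "P3", "O"], ["G", "C", "A", "A"])
        (counts,) = count_site_patterns(aln, GROUPS)
        assert counts.n_sites_used == 0

    def test_missing_group_label_rejected(self, four_taxon_alignment):
        with pytest.raises(ValueError):
            count_site_patterns(four_taxon_alignment, {"P1": "P1", "P2": "P2", "P3": "P3"})

    def test_haploid_accumulator_equals_site_count(self):
        # with one haploid sample per group every usable segregating site
        # contributes weight exactly 1 across the eight polarized patterns;
        # sites outside the six tallied ones (e.g. BBBA) reduce the total
        aln = MultiAlignment(
            ["P1", "P2", "P3", "O"],
            ["GAGGG", "AGAGG", "AGGGG", "AAAAG"],
        )
        (counts,) = count_site_patterns(aln, GROUPS)
        assert counts.total() <= counts.n_sites_used

    def test_block_additivity(self, four_taxon_alignment):
        pooled = count_site_patterns(four_taxon_alignment, GROUPS)[0]
        blocks = count_site_patterns(four_taxon_alignment, GROUPS, n_blocks=3)
        summed = pool_counts(blocks)
        for field in ("c_baaa", "c_abaa", "c_aaba", "c_bbaa", "c_abba", "c_baba"):
            assert getattr(summed, field) == getattr(pooled, field)
        assert summed.n_sites_used == pooled.n_sites_used

    def test_snp_table_input_matches_alignment(self, four_taxon_alignment):
        # same three sites expressed as a SNP table (ALT = derived allele)
        sites = [
            SnpSite("chr1", 0, "A", "G", {"P1": 1.0, "P2": 0.0, "P3": 0.0, "O": 0.0}),
            SnpSite("chr1", 1, "A", "G", {"P1": 0.0, "P2": 1.0, "P3": 1.0, "O": 0.0}),
            SnpSite("chr1", 2, "A", "G", {"P1": 1.0, "P2": 0.0, "P3": 1.0, "O": 0.0}),
        ]
        table = SnpTable(["P1", "P2", "P3", "O"], sites)
        (counts,) = count_site_patterns(table, GROUPS)
        ref = count_site_patterns(four_taxon_alignment, GROUPS)[0]
        assert counts.c_baaa == ref.c_baaa
        assert counts.c_abba == ref.c_abba
        assert counts.c_baba == ref.c_baba


class TestDStatistic:
    def test_symmetric_counts_give_zero(self):
        assert d_statistic(SitePatternCounts(c_abba=10, c_baba=10)) == 0

    def test_boundary(self):
        assert d_statistic(SitePatternCounts(c_abba=10, c_baba=0)) == 1

    def test_arithmetic(self):
        assert d_statistic(SitePatternCounts(c_abba=30, c_baba=20)) == pytest.approx(0.2)

    def test_zero_denominator_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            d_statistic(SitePatternCounts())


class TestBlockJackknife:
    def test_symmetric_null_gives_zero(self):
        blocks = [
            SitePatternCounts(c_abba=k, c_baba=k, n_sites_used=2 * k)
            for k in (1, 2, 3, 4)
        ]
        res = block_jackknife(blocks)
        assert res.D == 0 and res.Z == 0

    def test_matches_independent_delete_one_enumeration(self):
        pairs = [(3, 1), (2, 2), (4, 0), (1, 3), (5, 1)]
        blocks = [
            SitePatternCounts(c_abba=a, c_baba=b, n_sites_used=a + b) for a, b in pairs
        ]
        res = block_jackknife(blocks)
        # independent literal enumeration of the delete-one scheme
        tot_a = sum(a for a, _ in pairs)
        tot_b = sum(b for _, b in pairs)
        d_total = (tot_a - tot_b) / (tot_a + tot_b)
        pseudo = []
        for i in range(len(pairs)):
            ra = tot_a - pairs[i][0]
            rb = tot_b - pairs[i][1]
            pseudo.append((ra - rb) / (ra + rb))
        mean = sum(pseudo) / len(pseudo)
        se = math.sqrt((len(pseudo) - 1) / len(pseudo) * sum((p - mean) ** 2 for p in pseudo))
        assert res.D == pytest.approx(8 / 22)
        assert res.D == pytest.approx(d_total)
        assert res.jackknife_SE == pytest.approx(se)
        assert res.Z == pytest.approx(d_total / se)

    def test_single_block_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            block_jackknife([SitePatternCounts(c_abba=3, c_baba=1, n_sites_used=4)])

    def test_identical_blocks_nonzero_d_flagged(self):
        blocks = [SitePatternCounts(c_abba=4, c_baba=2, n_sites_used=6)] * 5
        res = block_jackknife(blocks)
        assert res.jackknife_SE == 0
        assert not res.z_defined
        assert math.isnan(res.Z)


def _freq_table(rows: dict[str, list[float]]) -> SnpTable:
    taxa = list(rows)
    n = len(next(iter(rows.values())))
    sites = [
        SnpSite("chr1", j, "A", "G", {t: rows[t][j] for t in taxa})
        for j in range(n)
    ]
    return SnpTable(taxa, sites)


class TestF4:
    QUARTET = ("W", "X", "Y", "Z")
    GROUPS = {"W": "W", "X": "X", "Y": "Y", "Z": "Z"}

    def test_equal_first_pair_gives_zero(self):
        table = _freq_table({"W": [0.5, 0.2], "X": [0.5, 0.2], "Y": [1.0, 0.0], "Z": [0.0, 1.0]})
        res = f4(table, self.QUARTET, self.GROUPS, n_blocks=1)
        assert res.f4 == 0

    def test_antisymmetric_in_first_pair(self):
        table = _freq_table({"W": [1.0, 0.5], "X": [0.0, 0.0], "Y": [1.0, 0.0], "Z": [0.0, 1.0]})
        a = f4(table, ("W", "X", "Y", "Z"), self.GROUPS, n_blocks=1).f4
        b = f4(table, ("X", "W", "Y", "Z"), self.GROUPS, n_blocks=1).f4
        assert a == pytest.approx(-b)

    def test_arithmetic(self):
        table = _freq_table({"W": [1.0, 0.5], "X": [0.0, 0.0], "Y": [1.0, 0.0], "Z": [0.0, 1.0]})
        res = f4(table, self.QUARTET, self.GROUPS, n_blocks=1)
        assert res.f4 == pytest.approx((1 * 1 + 0.5 * (-1)) / 2)

    def test_no_usable_sites_rejected(self):
        table = _freq_table({"W": [None], "X": [0.0], "Y": [0.0], "Z": [1.0]})
        with pytest.raises(UndefinedStatisticError):
            f4(table, self.QUARTET, self.GROUPS, n_blocks=1)

    def test_ratio_of_identical_quartets_is_one(self):
        rng = np.random.default_rng(0)
        rows = {t: list(rng.random(200)) for t in ("W", "X", "Y", "Z")}
        table = _freq_table(rows)
        res = f4_ratio(table, self.QUARTET, self.QUARTET, self.GROUPS, n_blocks=10,
                       min_denominator_z=0.0)
        assert res.alpha == pytest.approx(1.0)
        assert res.alpha_SE == pytest.approx(0.0, abs=1e-12)


class TestIlsFraction:
    def test_no_discordant_patterns(self):
        c = SitePatternCounts(c_baaa=2, c_abaa=2, c_aaba=2, c_bbaa=4)
        assert ils_fraction(c) == 0

    def test_printed_formula_arithmetic(self):
        c = SitePatternCounts(c_baaa=2, c_abaa=2, c_aaba=2, c_bbaa=4, c_abba=3, c_baba=3)
        assert ils_fraction(c) == pytest.approx(18 / 26)

    def test_concordant_only(self):
        assert ils_fraction(SitePatternCounts(c_bbaa=9)) == 0

    def test_zero_denominator_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ils_fraction(SitePatternCounts())

    def test_profile_fraction(self):
        blocks = [
            SitePatternCounts(c_bbaa=10, n_sites_used=10),
            SitePatternCounts(c_abba=5, c_baba=5, c_bbaa=1, n_sites_used=11),
        ]
        prof = ils_profile(blocks, cutoff=0.5)
        assert len(prof.per_block) == 2
        assert prof.genome_fraction_ils == pytest.approx(0.5)
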