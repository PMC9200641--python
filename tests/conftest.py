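import numpy as np
import pytest

from discordpan.io import MultiAlignment, Region, parse_tree


@pytest.fixture
def four_taxon_alignment():
    """Tiny alignment with a known site-pattern decomposition (one haploid
    sample per group): site 1 BAAA, site 2 ABBA, site 3 BABA."""
    return MultiAlignment(
        ["P1", "P2", "P3", "O"],
        ["GAG", "AGA", "AGG", "AAA"],
    )


@pytest.fixture
def balanced_species_tree():
    """(((A,B),C),D) with a 0.5-unit internal branch, ultrametric."""
    return parse_tree("(((A:1.0,B:1.0):0.5,C:1.5):1.0,D:2.5);")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_region_alignment(n_taxa: int, length: int, chrom: str = "chr1", start: int = 0):
    """Constant-A alignment anchored to [start, start+length)."""
    labels = [f"T{i}" for i in range(n_taxa)]
    rows = ["A" * length] * n_taxa
    return MultiAlignment(labels, rows, region=Region(chrom, start, start + length))
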