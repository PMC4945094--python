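"""Shared fixtures: a small amplicon template and an MRC-like map setup."""

import numpy as np
import pytest

from xover.mapping import MarkerMap
from xover.pollen import AmpliconTemplate
from xover.simulate import TrueRateMap, marker_map_for, simulate_amplicon


@pytest.fixture(scope="session")
def small_template() -> AmpliconTemplate:
    """A 400 bp two-haplotype template with 4 SNPs at known positions."""
    rng = np.random.default_rng(1234)
    col = "".join(rng.choice(list("ACGT"), size=400))
    snp_pos = [60, 140, 230, 330]  # 1-based
    ler = list(col)
    for p in snp_pos:
        ler[p - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[col[p - 1]]
    return AmpliconTemplate.from_sequences(col, "".join(ler))


@pytest.fixture(scope="session")
def amplicon() -> AmpliconTemplate:
    """Full-size synthetic pollen-typing amplicon (~9.4 kb, 40 SNPs)."""
    return simulate_amplicon(seed=3)


@pytest.fixture()
def mrc_like():
    """An MRC1-like setup: 93 intervals over 3.87 Mb, one 30x hotspot, 22.8 cM."""
    rate_map = TrueRateMap.uniform(1, 3_870_000, 93, total_cm=22.8)
    rate_map = rate_map.with_multiplier(40, 30.0)
    marker_map = marker_map_for(rate_map, 94)
    return rate_map, marker_map


@pytest.fixture()
def four_marker_map() -> MarkerMap:
    return MarkerMap(chrom="chr1", ids=("m1", "m2", "m3", "m4"),
                     positions=np.array([100, 200, 300, 400]))
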