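"""Shared fixtures: small grids, profile builders, frozen comparison data."""

import numpy as np
import pytest

from sctc_cnv.genome_bins import (
    BinGrid,
    NormalizedProfile,
    ReadCountProfile,
    make_bin_grid,
    sigma_delta,
)


@pytest.fixture
def tiny_grid():
    """Two chromosomes, 5 + 3 bins of 100."""
    return make_bin_grid({"chrA": 480, "chrB": 250}, bin_size=100)


@pytest.fixture
def small_grid():
    """One chromosome, 300 bins of 100 kb."""
    return make_bin_grid({"chr1": 300 * 100_000}, bin_size=100_000)


@pytest.fixture
def two_chrom_grid():
    """Two chromosomes, 200 bins each."""
    return make_bin_grid(
        {"chr1": 200 * 100_000, "chr2": 200 * 100_000}, bin_size=100_000
    )


def profile_from_values(grid: BinGrid, values, sample_id="s") -> NormalizedProfile:
    """Wrap a raw log2 array (NaN = missing) as a NormalizedProfile."""
    values = np.asarray(values, dtype=float)
    assert len(values) == grid.n_bins
    return NormalizedProfile(
        sample_id=sample_id,
        grid=grid,
        log2_ratio=values,
        sigma_delta=sigma_delta(values),
        empty_bin_count=int((np.isnan(values) & grid.usable).sum()),
    )


def counts_from_array(grid: BinGrid, counts, sample_id="s") -> ReadCountProfile:
    counts = np.asarray(counts, dtype=np.int64)
    return ReadCountProfile(
        sample_id=sample_id,
        grid=grid,
        raw_counts=counts,
        total_mapped_reads=int(counts.sum()),
    )


# ---------------------------------------------------------------------------
# Frozen paired datasets from the published method comparison the package's
# Wilcoxon implementation is checked against.
# ---------------------------------------------------------------------------

#: Library yields (nM) of 23 samples prepared with two library kits
#: (PCR-free vs adapter-based low-pass).  No ties; the exact signed-rank
#: branch applies.
LIBRARY_YIELD_PCRFREE = [
    4.7, 3.0, 5.3, 6.9, 5.3, 7.9, 8.3, 4.9, 4.0, 3.5, 3.6, 4.9,
    4.9, 4.3, 2.4, 6.6, 5.1, 8.1, 1.9, 1.4, 4.3, 3.4, 1.4,
]
LIBRARY_YIELD_LOWPASS = [
    45.8, 19.2, 82.8, 123.1, 53.2, 47.0, 75.1, 83.9, 23.1, 7.3, 22.4, 7.0,
    101.3, 82.3, 65.5, 4.8, 24.7, 55.3, 80.2, 25.9, 5.8, 93.7, 15.5,
]

#: Genome-wide leukocyte MADs under the two library kits (11 pairs, ties
#: among |differences| present; the exact branch handles them via midranks).
LEUKO_MAD_PCRFREE = [
    0.198, 0.194, 0.220, 0.277, 0.237, 0.255, 0.236, 0.201, 0.295, 0.216, 0.219,
]
LEUKO_MAD_LOWPASS = [
    0.169, 0.162, 0.214, 0.244, 0.235, 0.236, 0.226, 0.217, 0.296, 0.226, 0.223,
]

#: Chromosome-2 MADs of tumour-cell samples under two WGA methods
#: (6 complete pairs after dropping failed/unavailable entries).
WGA_MAD_METHOD_A = [0.292, 0.292, 0.260, 0.266, 0.241, 0.062]
WGA_MAD_METHOD_B = [0.769, 0.534, 0.763, 1.114, 0.286, 0.107]
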