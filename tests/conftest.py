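"""Shared synthetic-data fixtures.

Session-scoped so the expensive generation and matrix construction run
once; tests must not mutate fixture objects.
"""

import numpy as np
import pytest

from nucpatterns import occupancy, peaks, synthetic


@pytest.fixture(scope="session")
def arch192():
    """100 promoters (25 per class), fibroblast-like spacing, default noise."""
    return synthetic.build_architectures(
        25, spacing=192.0, jitter_sd=15.0, footprint=147, seed=3
    )


@pytest.fixture(scope="session")
def reps192(arch192):
    return synthetic.sample_replicates(arch192, 0.1, (140, 180), seeds=(1, 2))


@pytest.fixture(scope="session")
def promoters192(arch192):
    return arch192.promoter_table()


@pytest.fixture(scope="session")
def matrices192(reps192, promoters192):
    a, b = reps192
    return (
        occupancy.promoter_matrix(a, promoters192),
        occupancy.promoter_matrix(b, promoters192),
    )


@pytest.fixture(scope="session")
def positions192(matrices192):
    out = []
    for mat in matrices192:
        profiles = {pid: mat.values[i] for i, pid in enumerate(mat.promoter_ids)}
        out.append(peaks.call_positions(profiles, exclusion_fraction=0.20))
    return tuple(out)


@pytest.fixture(scope="session")
def aux192(arch192):
    return synthetic.sample_aux_tracks(arch192, seed=5)


@pytest.fixture(scope="session")
def matrix_bounds(matrices192):
    n = len(matrices192[0].relative_positions)
    return {pid: (0, (n - 1) * 10) for pid in matrices192[0].promoter_ids}
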