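import numpy as np
import pandas as pd
import pytest

from hdimpute import (
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    SimConfig,
    simulate_dataset,
)
from hdimpute.model import PANEL_BOTH, PANEL_HD_ONLY, UNKNOWN_PARENT


def make_map(n_markers, spacing=10_000, chrom=1, shared_every=None):
    """Evenly spaced single-chromosome map; every k-th marker shared."""
    rows = []
    for j in range(n_markers):
        panel = PANEL_BOTH
        if shared_every is not None and j % shared_every != 0:
            panel = PANEL_HD_ONLY
        rows.append((f"m{j:04d}", chrom, (j + 1) * spacing, panel))
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp", "panel"]))


def make_pedigree(records):
    """records: (id, sire, dam, sex, year[, breed]) tuples; '0' = unknown."""
    rows = []
    for r in records:
        breed = r[5] if len(r) > 5 else "TEST"
        rows.append((r[0], r[1], r[2], r[3], r[4], breed))
    return Pedigree(
        pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id", "sex", "birth_year", "breed"])
    )


def make_genotypes(calls, animal_ids=None, marker_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if animal_ids is None:
        animal_ids = [f"a{i}" for i in range(n)]
    if marker_ids is None:
        marker_ids = [f"m{j:04d}" for j in range(m)]
    return GenotypeMatrix(np.asarray(animal_ids, dtype=object), np.asarray(marker_ids, dtype=object), calls)


@pytest.fixture(scope="session")
def small_dataset():
    """One small artifact-free breed used by several module tests."""
    cfg = SimConfig(
        n_founders=40,
        n_generations=2,
        n_chromosomes=1,
        markers_per_chromosome_hd=400,
        fraction_shared_50k=0.05,
        chromosome_length_bp=1_400_000,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_founders=40,
        n_generations=2,
        n_chromosomes=1,
        markers_per_chromosome_hd=400,
        fraction_shared_50k=0.05,
        chromosome_length_bp=1_400_000,
        seed=7,
    )


UNKNOWN = UNKNOWN_PARENT
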