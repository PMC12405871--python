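import numpy as np
import pytest

from digenic import reference
from digenic.genetic_design import DigenicGenotype
from digenic.model_fitting import reconstruct_replicates


@pytest.fixture
def il_gp_records():
    """One observation per homozygous class at the reference GP7 class means."""
    return [(DigenicGenotype(*key), gp) for key, gp in reference.IL_GP7_MEANS.items()]


def flavonoid_records(chemical):
    """(genotype, dpa, value) triplets reconstructed from the reference panel.

    Non-detectable cells enter as exact zeros (mean 0, SE 0).
    """
    rows = []
    for (rc, pb, dpa), chems in sorted(reference.FLAVONOID_PANEL.items()):
        cell = chems[chemical]
        mean, se = cell if cell is not None else (0.0, 0.0)
        for value in reconstruct_replicates(mean, se, 3):
            rows.append((DigenicGenotype(rc, pb), dpa, float(value)))
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
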