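import numpy as np
import pytest

from flavoromics.datasets import docynia_fruit
from flavoromics.model import Compound, PeakTable


@pytest.fixture(scope="session")
def docynia():
    """Curated D. delavayi young/mature fruit dataset (42 compounds)."""
    return docynia_fruit()


def make_peak_table(areas, groups=("A", "A", "B", "B"), classes=None, detected=None):
    """Small PeakTable from a plain matrix; one sample per group entry."""
    areas = np.asarray(areas, dtype=float)
    n_c, n_s = areas.shape
    assert n_s == len(groups)
    samples = [f"s{j}" for j in range(n_s)]
    compounds = [
        Compound(
            id=f"c{i}",
            name=f"cmp{i}",
            compound_class=(classes[i] if classes else "other"),
            rt_min=1.0 + i,
        )
        for i in range(n_c)
    ]
    return PeakTable(
        compounds=compounds,
        samples=samples,
        groups=dict(zip(samples, groups)),
        areas=areas,
        detected=detected,
    )


@pytest.fixture
def small_table():
    return make_peak_table(
        [[25.0, 10.0, 5.0, 8.0], [75.0, 90.0, 95.0, 92.0]]
    )
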