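import numpy as np
import pytest

from steptriage.descriptors import ColumnSchema, DescriptorTable
from steptriage.synthetic_data import LibrarySpec, generate_library


def make_numeric_table(values, binary_mask=None, ids=None, names=None):
    """Build a DescriptorTable from a plain matrix for learner/selection tests."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if binary_mask is None:
        binary_mask = [bool(set(np.unique(values[:, j])) <= {0.0, 1.0}) for j in range(k)]
    names = names or [f"f{j:02d}" for j in range(k)]
    cols = [
        ColumnSchema(names[j], "pharmacophore" if binary_mask[j] else "burden",
                     "binary" if binary_mask[j] else "continuous")
        for j in range(k)
    ]
    ids = ids or [f"c{i:04d}" for i in range(n)]
    return DescriptorTable(compound_ids=ids, columns=cols, values=values)


def overlapping_classes(n=400, active_fraction=0.1, shift=1.2, seed=0):
    """Two-feature Gaussian classes with tunable overlap; labels 1 = active."""
    rng = np.random.default_rng(seed)
    n_act = int(round(n * active_fraction))
    y = np.array([1] * n_act + [0] * (n - n_act))
    X = rng.normal(0.0, 1.0, size=(n, 2))
    X[y == 1] += shift
    return make_numeric_table(X), y


@pytest.fixture(scope="session")
def planted_library():
    """The desk-scale study library: n=2000, 5% actives, carboxylic acid x8."""
    spec = LibrarySpec(
        n_compounds=2000,
        active_fraction=0.05,
        enriched_fragments=[("Carboxylic acid", 8.0)],
        noise_sd=5.0,
        seed=1,
    )
    return generate_library(spec)
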