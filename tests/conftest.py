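import numpy as np
import pytest

import umitopo as ut


@pytest.fixture(scope="session")
def combined_model():
    return ut.build_fraction_model("combined")


@pytest.fixture(scope="session")
def small_z():
    """A scaled-down lineage population shared by workflow-level tests."""
    return ut.simulate_population_Z(np.random.default_rng(0), cells_per_state=120)


def make_two_gene_model(f=(1.0, 1.0), integral=True):
    """Minimal hand-built fraction model for closed-form spectra checks."""
    f = np.asarray(f, dtype=float)
    return ut.GeneFractionModel(
        n_genes=f.size,
        first_expressed_index=int(np.flatnonzero(f > 0)[0]) + 1 if (f > 0).any() else 1,
        kind="edited",
        f=f,
        p=f / f.sum(),
        params={},
        integral=integral,
        recipe=[],
    )
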