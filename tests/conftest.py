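import numpy as np
import pytest

from campop.core import MISSING, GenotypeMatrix
from campop.syndata import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def two_pop_panel():
    """Unadmixed two-population panel with clear structure (F = 0.3)."""
    cfg = SimConfig(
        n_pops=2,
        pop_sizes=(30, 30),
        n_loci=300,
        fst_target=0.3,
        admix_alpha=None,
        missing_rate=0.05,
        seed=20240901,
    )
    gm, vt, truth, meta = simulate_panel(cfg)
    return {"config": cfg, "gm": gm, "vt": vt, "truth": truth, "meta": meta}


@pytest.fixture
def toy_genotypes():
    """Hand-written 4-individual × 6-locus panel with one missing call."""
    dosages = np.array(
        [
            [0, 1, 2, 0, 1, 0],
            [0, 1, 2, 1, 1, 0],
            [1, 2, 2, 0, MISSING, 1],
            [2, 0, 1, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        dosages,
        ["i1", "i2", "i3", "i4"],
        [f"L{j}" for j in range(6)],
    )
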