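from pathlib import Path

import numpy as np
import pytest

from ssrpop import GenotypeTable, SimConfig, simulate_panel, to_allele_presence
from ssrpop.synthetic_data import SMALL_ORIGINS

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def mini_panel_path() -> Path:
    return DATA / "mini_panel.csv"


@pytest.fixture(scope="session")
def tiny_table() -> GenotypeTable:
    """Hand-built 3-sample, 2-locus tetraploid table with one MISSING."""
    calls = np.array(
        [
            [[173, 175, 175, 180], [200, 202, 0, 0]],
            [[173, 173, 173, 173], [0, 0, 0, 0]],
            [[175, 180, 0, 0], [202, 204, 206, 0]],
        ]
    )
    return GenotypeTable(
        ["S1", "S2", "S3"], ["P1", "P1", "P2"], ["LocA", "LocB"], 4, calls
    )


@pytest.fixture(scope="session")
def small_panel():
    """Deterministic N=60, 10-locus simulated panel + truth."""
    cfg = SimConfig(origins=SMALL_ORIGINS, n_loci=10, seed=42)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_binary(small_panel):
    table, _ = small_panel
    return to_allele_presence(table)
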