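import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tipmap.config import SimConfig
from tipmap.peaks import ProbeTrack


def make_track(
    intensities,
    spacing=100,
    chrom="chr1",
    masked=None,
    cell_line="CL01",
    family="L1",
    start0=0,
    probe_len=50,
):
    """Build a ProbeTrack from a flat intensity list."""
    n = len(intensities)
    starts = start0 + spacing * np.arange(n)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + probe_len,
            "intensity": np.asarray(intensities, dtype=float),
            "masked": masked if masked is not None else np.zeros(n, dtype=bool),
        }
    )
    return ProbeTrack(df, cell_line=cell_line, family=family)


@pytest.fixture
def small_config():
    return SimConfig(
        seed=7,
        n_cell_lines=8,
        n_genes=40,
        n_reference=6,
        n_known_poly=4,
        n_novel_poly=4,
        n_singleton=4,
    )


@pytest.fixture(scope="session")
def noise_free_panel():
    """Small noise-free panel shared by classification tests."""
    from tipmap.simulate import simulate_all

    cfg = SimConfig(
        seed=11,
        n_cell_lines=10,
        n_genes=100,
        baseline_sd=0.05,
        signal_sd=0.5,
        masked_probe_fraction=0.0,
    )
    return simulate_all(cfg, with_phenotypes=False)
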