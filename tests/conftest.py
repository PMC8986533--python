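import numpy as np
import pytest

import wgdscan as w


@pytest.fixture(scope="session")
def small_grid():
    """3 chromosomes x 100 bins of 1 Mb — fast enough for per-test calling."""
    return w.make_toy_genome(3, 100, 1_000_000)


@pytest.fixture(scope="session")
def medium_grid():
    """3 chromosomes x 1000 bins — the 3,000-bin human-scale tiling."""
    return w.make_toy_genome(3, 1000, 1_000_000)


@pytest.fixture(scope="session")
def clean_4n_cell(medium_grid):
    spec = w.KaryotypeSpec(4, [("chr2", 100, 160, 5)], label="4n G2/M")
    config = w.SimulationConfig(depth_per_copy=12.0, seed=42)
    return w.simulate_cell_counts(medium_grid, spec, config)


@pytest.fixture(scope="session")
def clean_4n_profiles(clean_4n_cell):
    return w.call_cell(clean_4n_cell, (3.5, 4.5))


def make_profile(grid, states, algorithm="changepoint", expected_ploidy=None, signal=None):
    """Build a CopyNumberProfile directly from a per-bin state vector."""
    import pandas as pd

    states = np.asarray(states, dtype=int)
    chroms = grid.chroms
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    rows = []
    lo = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[lo] or chroms[i] != chroms[lo]:
            rows.append(
                {
                    "chrom": chroms[lo],
                    "start": int(starts[lo]),
                    "end": int(ends[i - 1]),
                    "start_bin": lo,
                    "end_bin": i,
                    "mean": float(states[lo]) if signal is None else float(np.mean(signal[lo:i])),
                    "state": int(states[lo]),
                }
            )
            lo = i
    segments = pd.DataFrame(rows)
    return w.CopyNumberProfile(
        grid=grid,
        segments=segments,
        algorithm=algorithm,
        states=states,
        expected_ploidy=expected_ploidy,
        signal=np.asarray(signal, dtype=float) if signal is not None else states.astype(float),
    )
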