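import dataclasses

import numpy as np
import pytest

from protrudyn.simdendrite import SimulationConfig


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """A fast, fully specified simulation: 31 frames, 30 µm segment."""
    return SimulationConfig(
        segment_length_um=30.0,
        n_frames=31,
        n_initial_protrusions=8,
        formation_count=0,
        elimination_count=0,
        lability_count=0,
        labile_lifetime_range_min=(0.5, 1.0),
        length_sampling_range_um=(1.5, 5.0),
        motility_fraction=0.0,
        seed=3,
    )


@pytest.fixture
def noiseless_sim_config(small_sim_config) -> SimulationConfig:
    return dataclasses.replace(
        small_sim_config, shot_noise=False, read_noise_sigma=0.0
    )


def make_dendrite_mask(
    shape: tuple[int, int],
    shaft_rows: tuple[int, int],
    shaft_cols: tuple[int, int],
    spikes: list[tuple[int, int, int]] = (),
) -> np.ndarray:
    """Binary dendrite fixture: a rectangle plus vertical spikes.

    ``spikes`` entries are (column, length_px, width_px); each spike extends
    upward from the shaft's top edge.
    """
    mask = np.zeros(shape, dtype=bool)
    r0, r1 = shaft_rows
    c0, c1 = shaft_cols
    mask[r0:r1, c0:c1] = True
    for col, length, width in spikes:
        half = width // 2
        mask[r0 - length : r0, col - half : col + half + 1] = True
    return mask
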