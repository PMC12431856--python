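"""Shared fixtures: small synthetic datasets with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from condquant import segmentation as seg
from condquant.io_images import rescale_16bit
from condquant.synthetic_data import (
    SyntheticImageParams,
    SyntheticSelexParams,
    generate_image,
    generate_selex,
)


@pytest.fixture(scope="session")
def small_image():
    """One-nucleus stack with 10 well-separated bright puncta (SNR >> 10)."""
    params = SyntheticImageParams(
        stack_shape=(24, 192, 192),
        nuclei=[((12, 96, 96), (9.0, 72.0, 72.0), 3000.0)],
        n_puncta_per_nucleus=10,
        spot_amplitude=8000.0,
        noise_sd=50.0,
        coloc_fraction=1.0,
        min_center_distance=9.0,  # 6 sigma: spots stay resolvable
        seed=42,
    )
    stack, truth = generate_image(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def segmented(small_image):
    """Nuclei + puncta masks and PunctaSets for the small stack."""
    params, stack, truth = small_image
    nuclei = seg.segment_nuclei(stack.channel("dapi"))
    puncta_mask = seg.segment_puncta_builtin(
        rescale_16bit(stack.channel("reporter")), nuclei
    )
    sets = seg.extract_puncta(
        puncta_mask, nuclei, stack.channel("reporter"), params.voxel_size
    )
    return nuclei, puncta_mask, sets


@pytest.fixture(scope="session")
def selex_pool(tmp_path_factory):
    """A 3-round selection with planted GGCCCC and matched negative pool."""
    outdir = tmp_path_factory.mktemp("selex")
    params = SyntheticSelexParams(
        motif="GGCCCC",
        n_reads_per_round=4000,
        motif_fraction_by_round=(0.05, 0.15, 0.4),
        seed=7,
    )
    paths, truth = generate_selex(params, outdir)
    return params, paths, truth


def centered_delta(matrix: np.ndarray, central_size: int = 11) -> tuple[float, float]:
    """(central patch mean, edge ring mean) of one profile matrix."""
    n = matrix.shape[0]
    c, h = n // 2, central_size // 2
    central = matrix[c - h : c + h + 1, c - h : c + h + 1].mean()
    ring = np.concatenate(
        [matrix[0, :], matrix[-1, :], matrix[1:-1, 0], matrix[1:-1, -1]]
    ).mean()
    return float(central), float(ring)
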