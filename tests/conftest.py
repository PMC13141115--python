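from __future__ import annotations

import numpy as np
import pytest

from mifprep.model import ChannelRecord, ImagePlane, TileGrid
from mifprep.synthetic import make_scene, render_clean_plane, write_fixture


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def textured_plane(shape=(128, 128), seed=0, amplitude=2000.0) -> ImagePlane:
    """A nuclei-like textured image: smoothed random blobs, uint16."""
    from scipy.ndimage import gaussian_filter

    r = np.random.default_rng(seed)
    arr = gaussian_filter(r.random(shape), 2.0)
    arr = (arr - arr.min()) / (arr.max() - arr.min()) * amplitude
    return ImagePlane(np.clip(np.floor(arr + 0.5), 0, 65535).astype(np.uint16))


@pytest.fixture
def nuclei_plane() -> ImagePlane:
    """A clean synthetic nuclear (DAPI) image with 120 nuclei."""
    truth = make_scene(n_cells=120, seed=5, n_cycles=1)
    arr = render_clean_plane(truth, 1, truth.manifest[0])
    return ImagePlane(np.clip(np.floor(arr + 0.5), 0, 65535).astype(np.uint16))


def small_manifest(n_cycles: int = 2, markers_per_cycle: int = 1) -> list[ChannelRecord]:
    records = []
    for cyc in range(1, n_cycles + 1):
        records.append(
            ChannelRecord(cycle=cyc, channel_name="DAPI", marker="DAPI",
                          fluorophore="DAPI", exposure_ms=20, role="nuclear")
        )
        for m in range(markers_per_cycle):
            records.append(
                ChannelRecord(cycle=cyc, channel_name=f"ch{m}", marker=f"M{cyc}_{m}",
                              fluorophore="A488", exposure_ms=100, role="marker")
            )
    return records


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A small but complete on-disk acquisition (3 cycles, 150 cells)."""
    truth = make_scene(
        n_cells=150, seed=11, n_cycles=3,
        grid=TileGrid(rows=2, cols=2, tile_shape=(192, 192), overlap_fraction=0.125),
    )
    path = tmp_path_factory.mktemp("fixture") / "acq"
    write_fixture(truth, path)
    return path, truth
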