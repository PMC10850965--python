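import numpy as np
import pytest

import dicplate as dp


@pytest.fixture
def default_model():
    return dp.ResponseModel()


@pytest.fixture
def noiseless_model():
    return dp.ResponseModel().noiseless()


@pytest.fixture
def render_standards():
    """Render a one-row strip of standards and return (image, manifest, map, grid)."""

    def _render(model, levels, seed=0, qc_levels=()):
        plate_map = dp.standards_plate_map(levels, qc_levels=qc_levels)
        grid = dp.strip_grid(len(levels) + len(qc_levels))
        image, manifest = dp.render_plate(model, plate_map, grid, seed=seed)
        return image, manifest, plate_map, grid

    return _render


@pytest.fixture
def read_standards(render_standards):
    """Full extraction pipeline on rendered standards -> list of observations."""

    def _read(model, levels, seed=0, qc_levels=()):
        image, manifest, plate_map, grid = render_standards(
            model, levels, seed=seed, qc_levels=qc_levels
        )
        layout = dp.locate_wells(image, grid)
        return dp.read_plate(image, layout, plate_map), manifest

    return _read


@pytest.fixture
def uniform_roi():
    """An (N, 3) uniform ROI pixel block."""

    def _make(rgb, n=2000):
        return np.tile(np.asarray(rgb, dtype=float), (n, 1))

    return _make
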