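import numpy as np
import pytest

from gazeplan.observers import ModelSpec
from gazeplan.shapes import ShapeGrid, select_stimuli


def make_plus_grid() -> ShapeGrid:
    """Two crossing 25-cell arms on unit cells (49 cells total)."""
    mask = np.zeros((25, 25), dtype=np.uint8)
    mask[12, :] = 1
    mask[:, 12] = 1
    return ShapeGrid(mask=mask, cell_size_deg=1.0, x0=-12.0, y0=-12.0,
                     shape_id="plus")


def make_disc(radius_deg: float = 3.0, cell: float = 0.25) -> ShapeGrid:
    k = int(np.ceil(radius_deg / cell)) + 2
    xs = np.arange(-k, k + 1) * cell
    gx, gy = np.meshgrid(xs, xs)
    mask = (gx**2 + gy**2 < radius_deg**2).astype(np.uint8)
    return ShapeGrid(mask=mask, cell_size_deg=cell, x0=xs[0], y0=xs[0],
                     shape_id=f"disc{radius_deg}")


def make_two_lobes(sep: float = 18.0, lobe_radius: float = 4.0,
                   cell: float = 1.0) -> ShapeGrid:
    """Two discs centered at (+-sep/2, 0): a shape needing one fixation per lobe."""
    k = int(np.ceil((sep / 2 + lobe_radius) / cell)) + 1
    xs = np.arange(-k, k + 1) * cell
    gx, gy = np.meshgrid(xs, xs)
    left = (gx + sep / 2) ** 2 + gy**2 < lobe_radius**2
    right = (gx - sep / 2) ** 2 + gy**2 < lobe_radius**2
    return ShapeGrid(mask=(left | right).astype(np.uint8), cell_size_deg=cell,
                     x0=xs[0], y0=xs[0], shape_id="two-lobes")


@pytest.fixture
def plus_grid() -> ShapeGrid:
    return make_plus_grid()


@pytest.fixture
def disc_shape() -> ShapeGrid:
    return make_disc()


@pytest.fixture
def two_lobe_shape() -> ShapeGrid:
    return make_two_lobes()


@pytest.fixture(scope="session")
def base_spec() -> ModelSpec:
    return ModelSpec(policy="planned", horizon=2)


@pytest.fixture(scope="session")
def stimulus_set(base_spec):
    """Model-selected stimuli (2 divergent + 2 coincident), shared across the
    suite because selection re-solves many candidate shapes."""
    shapes, reports, log = select_stimuli(11, base_spec)
    return shapes, reports, log


@pytest.fixture(scope="session")
def divergent_shapes(stimulus_set):
    shapes, reports, _ = stimulus_set
    return [s for s, r in zip(shapes, reports) if r.category == "divergent"]


@pytest.fixture(scope="session")
def coincident_shapes(stimulus_set):
    shapes, reports, _ = stimulus_set
    return [s for s, r in zip(shapes, reports) if r.category == "coincident"]
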