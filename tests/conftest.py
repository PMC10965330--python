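import numpy as np
import pytest

from villimorph import phantoms
from villimorph.transport import TransporterParams, build_problem, solve_steady_state

# Annulus benchmark geometry: outer villus surface at 100 µm, one central
# capillary of radius 20 µm, so the simple-diffusion solution is the closed
# form c(r) = ln(r/20)/ln(5).
ANNULUS_R_OUTER = 100.0
ANNULUS_R_INNER = 20.0


def annulus_spec(pixel_size: float) -> phantoms.CrossSectionSpec:
    return phantoms.CrossSectionSpec(
        outer_radius=ANNULUS_R_OUTER, trophoblast_thickness=40.0,
        capillary_centers=((0.0, 0.0),), capillary_radius=ANNULUS_R_INNER,
        pixel_size=pixel_size)


def pixel_centres(cross):
    """Physical (y, x) coordinates of the raster's pixel centres."""
    n = cross.labels.shape[0]
    coords = (np.arange(n) + 0.5) * cross.pixel_size - n * cross.pixel_size / 2
    return np.meshgrid(coords, coords, indexing="ij")


@pytest.fixture(scope="session")
def annulus_cross_256():
    cross, truth = phantoms.make_cross_section(annulus_spec(2 * 103 / 256))
    return cross, truth


@pytest.fixture(scope="session")
def annulus_simple_field_256(annulus_cross_256):
    cross, _ = annulus_cross_256
    problem = build_problem(cross, TransporterParams(mode="simple"))
    return cross, problem, solve_steady_state(problem)


@pytest.fixture(scope="session")
def sphere48():
    spec = phantoms.PrimitiveSpec("sphere", radius=48.0, voxel_size=4.8)
    volume, truth = phantoms.make_primitive_label(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def equal_area_pair():
    """Invaginated cross-section and a smooth one of equal inner area."""
    invag_spec = phantoms.CrossSectionSpec(
        outer_radius=60.0, trophoblast_thickness=15.0,
        capillary_centers=((0.0, 10.0), (-10.0, -10.0), (10.0, -10.0)),
        capillary_radius=5.0, invagination_count=12,
        invagination_depth=20.0, invagination_width=8.0, pixel_size=0.5)
    smooth_spec = phantoms.matched_smooth_spec(invag_spec)
    invag, invag_truth = phantoms.make_cross_section(invag_spec)
    smooth, smooth_truth = phantoms.make_cross_section(smooth_spec)
    return {"invaginated": (invag_spec, invag, invag_truth),
            "smooth": (smooth_spec, smooth, smooth_truth)}
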