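import numpy as np
import pytest

import craniosim as cs
from craniosim import phantom as ph


@pytest.fixture(scope="session")
def ellipse():
    return cs.EllipseSpec(a=65.0, b=75.0)


@pytest.fixture(scope="session")
def sweeps(ellipse):
    """Default-protocol sweeps for the five clinical elevations."""
    return {
        k: cs.sweep_tangent_diameters(float(k), ellipse, n_grid=500, n_rect=2000)
        for k in (10, 20, 30, 40, 50)
    }


@pytest.fixture(scope="session")
def intact_stack():
    return ph.generate_stack(ph.preset("intact"))


@pytest.fixture(scope="session")
def medium_spec():
    return ph.preset("medium-defect")


@pytest.fixture(scope="session")
def medium_stack(medium_spec):
    return ph.generate_stack(medium_spec)


@pytest.fixture(scope="session")
def intact_mesh(intact_stack):
    layers = [
        cs.extract_outline(
            intact_stack.images[i], intact_stack.pixel_spacing, z=intact_stack.z(i)
        )
        for i in range(intact_stack.n_slices)
    ]
    return cs.build_mesh(layers, n_points=256)


@pytest.fixture(scope="session")
def medium_result(medium_stack):
    """Full pipeline run (default 20-step schedule) on the medium phantom."""
    return cs.run_pipeline(medium_stack)


@pytest.fixture(scope="session")
def preset_defect_areas():
    """Measured sagittal defect areas (cm²) for the three presets."""
    areas = {}
    for name in ("small-defect", "medium-defect", "large-defect"):
        spec = ph.preset(name)
        stack = ph.generate_stack(spec)
        contours = []
        for i in range(spec.defect.slice_range[0], spec.defect.slice_range[1]):
            c = cs.extract_outline(stack.images[i], stack.pixel_spacing, z=stack.z(i))
            if not c.closed:
                contours.append(c)
        areas[name] = cs.defect_area(contours, slab_halfwidth=spec.slice_thickness / 2)
    return areas
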