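import numpy as np
import pytest

from valvemorph.io import Unit, ValveOutline
from valvemorph.synthetic import (
    CohortSpec,
    SyntheticValveParams,
    default_cohort_spec,
    generate_cohort,
    generate_outline,
)


def ellipse_outline(a=30.0, b=4.0, n=60, phase=0.0, specimen_id="ellipse"):
    """Ellipse polygon sampled at uniform angles, CCW."""
    phi = 2 * np.pi * np.arange(n) / n + phase
    pts = np.column_stack([a * np.cos(phi), b * np.sin(phi)])
    return ValveOutline(specimen_id, pts, unit=Unit.micrometer)


@pytest.fixture
def ellipse():
    return ellipse_outline()


@pytest.fixture
def heteropolar_valve():
    params = SyntheticValveParams(length=60, width=8, h=0.6)
    outline, truth = generate_outline(params, "h06")
    return params, outline, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Small study-condition cohort without rendered images."""
    spec = default_cohort_spec(n_per_species=(12, 9, 6))
    return generate_cohort(spec, seed=11, render_images=False)
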