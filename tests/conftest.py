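import numpy as np
import pytest

from clemquant.model_geometry import CompartmentClass, ContourModel, ContourObject


def circle_contour(radius, z, n=90, center=(500.0, 500.0)):
    phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([
        center[0] + radius * np.cos(phi),
        center[1] + radius * np.sin(phi),
        np.full(n, float(z)),
    ])


def sphere_model(radius=200.0, n_slices=41, n_points=90, center=(500.0, 500.0, 500.0),
                 label=CompartmentClass.ILV):
    """Sphere sampled as circle contours on evenly spaced slices (slice
    planes at the z-bin centres), z snapped onto a uniform grid."""
    z_step = 2 * radius / n_slices
    contours = []
    for i in range(n_slices):
        dz = -radius + (i + 0.5) * z_step
        r = np.sqrt(max(radius**2 - dz**2, 0.0))
        if r <= 1e-6:
            continue
        contours.append(circle_contour(r, center[2] + dz, n=n_points, center=center[:2]))
    # snap slice z values onto multiples of z_step for the validator
    base = contours[0][0, 2]
    for c in contours:
        k = round((c[0, 2] - base) / z_step)
        c[:, 2] = base + k * z_step
    model = ContourModel(
        endosome_id="sphere",
        z_step=z_step,
        objects=[ContourObject(label=label, contours=contours, capped=True)],
    )
    # shift so the grid starts at a multiple of z_step
    offset = base - round(base / z_step) * z_step
    for c in contours:
        c[:, 2] -= offset
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def simple_three_class_model():
    """One BM cylinder ring stack, one ILV sphere, one RT sphere."""
    z_step = 20.0
    objects = [
        ContourObject(
            label=CompartmentClass.BM,
            contours=[circle_contour(300.0, z, center=(500.0, 500.0)) for z in
                      np.arange(400.0, 620.0, z_step)],
            capped=False,
        ),
        ContourObject(
            label=CompartmentClass.ILV,
            contours=[circle_contour(r, z, n=40, center=(450.0, 500.0)) for r, z in
                      [(30.0, 480.0), (50.0, 500.0), (30.0, 520.0)]],
        ),
        ContourObject(
            label=CompartmentClass.RT,
            contours=[circle_contour(r, z, n=40, center=(900.0, 500.0)) for r, z in
                      [(20.0, 480.0), (35.0, 500.0), (20.0, 520.0)]],
        ),
    ]
    return ContourModel(endosome_id="three-class", z_step=z_step, objects=objects)
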