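"""Ground-truth synthetic endosome scenes and section stacks.

The generator produces exactly the formats the analysis pipeline reads
(contour JSON, TIFF channel images, transform JSON) plus the ground-truth
per-class densities needed for recovery tests:

* an endosome as a truncated BM sphere (the tomographic section cuts the
  top and bottom), several ILV spheres strictly inside it and one
  recycling tubule attached to the BM surface, pointing outward;
* widefield-like channel renders: membrane area elements emit photons in
  proportion to their class density, are z-projected onto the FM pixel
  grid, blurred with a Gaussian PSF, offset by a background and corrupted
  with Poisson (or Gaussian) noise;
* vertically cut section-edge images with surface- or volume-confined
  labelling, and serial horizontal sections sharing (volume) or not
  sharing (surface) their signal between sections.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from clemquant.errors import ValidationError
from clemquant.intensity_assignment import ChannelImage
from clemquant.model_geometry import (
    CompartmentClass,
    ContourModel,
    ContourObject,
    _triangle_areas,
    mesh_object,
    write_contour_model,
)

CHANNELS = ("lipid", "Tf", "LDL")

#: Per-channel membrane densities (a.u. per nm^2) for the named presets.
#: ``sm_loaded`` reproduces a lipid pattern enriched in ILVs and depleted
#: in RTs, with Tf as the RT cargo standard and LDL as the ILV standard;
#: ``fa_loaded`` is the flatter fatty-acid pattern; ``uniform`` puts the
#: same density on every membrane.
DENSITY_PRESETS: dict[str, dict[str, dict[CompartmentClass, float]]] = {
    "sm_loaded": {
        "lipid": {CompartmentClass.BM: 0.9, CompartmentClass.ILV: 3.6, CompartmentClass.RT: 0.5},
        "Tf": {CompartmentClass.BM: 0.95, CompartmentClass.ILV: 0.4, CompartmentClass.RT: 2.1},
        "LDL": {CompartmentClass.BM: 0.7, CompartmentClass.ILV: 5.7, CompartmentClass.RT: 0.6},
    },
    "fa_loaded": {
        "lipid": {CompartmentClass.BM: 0.73, CompartmentClass.ILV: 2.52, CompartmentClass.RT: 1.23},
        "Tf": {CompartmentClass.BM: 0.95, CompartmentClass.ILV: 0.4, CompartmentClass.RT: 2.1},
        "LDL": {CompartmentClass.BM: 0.7, CompartmentClass.ILV: 5.7, CompartmentClass.RT: 0.6},
    },
    "uniform": {
        ch: {c: 1.0 for c in CompartmentClass} for ch in CHANNELS
    },
}


@dataclass
class SphereSpec:
    center: np.ndarray  # (3,) nm
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class TubeSpec:
    """A straight tubule: ``start`` on the BM surface, unit ``direction``
    pointing outward, circular cross-section of ``radius``, ``length``."""

    start: np.ndarray
    direction: np.ndarray
    radius: float
    length: float

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if norm <= 0:
            raise ValidationError("tube direction must be non-zero")
        self.direction = self.direction / norm


@dataclass
class SceneGeometry:
    bm_center: np.ndarray
    bm_radius: float
    bm_half_height: float  # half-thickness of the tomographic section
    ilvs: list[SphereSpec]
    tubule: TubeSpec

    def __post_init__(self) -> None:
        self.bm_center = np.asarray(self.bm_center, dtype=float)

    def validate(self) -> "SceneGeometry":
        for i, ilv in enumerate(self.ilvs):
            gap = self.bm_radius - (np.linalg.norm(ilv.center - self.bm_center) + ilv.radius)
            if gap <= 0:
                raise ValidationError(f"ILV {i} is not strictly inside the BM (gap {gap:.1f} nm)")
            if abs(ilv.center[2] - self.bm_center[2]) + ilv.radius >= self.bm_half_height:
                raise ValidationError(f"ILV {i} extends beyond the section truncation")
        radial = self.tubule.start - self.bm_center
        dist = np.linalg.norm(radial)
        if abs(dist - self.bm_radius) > 0.05 * self.bm_radius:
            raise ValidationError("tubule must start on the BM surface")
        if np.dot(self.tubule.direction, radial) <= 0:
            raise ValidationError("tubule must point outward from the BM")
        return self


@dataclass
class SyntheticScene:
    """Generator parameters + ground truth for one synthetic endosome."""

    geometry: SceneGeometry
    densities: dict[str, dict[CompartmentClass, float]]
    seed: int
    z_step_nm: float = 10.0
    pixel_size_nm: float = 65.0
    psf_sigma_nm: float = 150.0
    background: float = 50.0
    photon_scale: float = 1.0
    noise: str = "poisson"  # poisson | gaussian | none
    read_noise_sigma: float = 5.0
    image_shape: tuple[int, int] = (96, 96)
    #: true relative densities per channel/class, computed from the
    #: densities and the meshed membrane areas of the generated model
    truth_relative: dict[str, dict[CompartmentClass, float]] = field(default_factory=dict)
    truth_areas: dict[CompartmentClass, float] = field(default_factory=dict)

    def parameter_digest(self) -> str:
        payload = {
            "seed": self.seed,
            "z_step_nm": self.z_step_nm,
            "pixel_size_nm": self.pixel_size_nm,
            "psf_sigma_nm": self.psf_sigma_nm,
            "background": self.background,
            "photon_scale": self.photon_scale,
            "noise": self.noise,
            "densities": {
                ch: {c.value: v for c, v in dens.items()}
                for ch, dens in self.densities.items()
            },
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    def truth_json(self) -> dict:
        return {
            "seed": self.seed,
            "parameter_digest": self.parameter_digest(),
            "truth_relative": {
                ch: {c.value: v for c, v in dens.items()}
                for ch, dens in self.truth_relative.items()
            },
            "truth_areas": {c.value: v for c, v in self.truth_areas.items()},
        }


# ---------------------------------------------------------------------------
# Contour construction
# ---------------------------------------------------------------------------

def _circle(center_xy: np.ndarray, radius: float, z: float, n: int) -> np.ndarray:
    phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([
        center_xy[0] + radius * np.cos(phi),
        center_xy[1] + radius * np.sin(phi),
        np.full(n, z),
    ])


def _sphere_contours(
    center: np.ndarray, radius: float, z_step: float,
    n_points: int, z_min: float | None = None, z_max: float | None = None,
    min_ring_radius: float = 4.0,
) -> list[np.ndarray]:
    """Circle contours of a sphere on the global z grid (z multiples of
    z_step), optionally truncated to [z_min, z_max]."""
    lo = center[2] - radius if z_min is None else max(center[2] - radius, z_min)
    hi = center[2] + radius if z_max is None else min(center[2] + radius, z_max)
    k_lo = int(np.ceil(lo / z_step - 1e-9))
    k_hi = int(np.floor(hi / z_step + 1e-9))
    contours = []
    for k in range(k_lo, k_hi + 1):
        z = k * z_step
        dz = z - center[2]
        rsq = radius**2 - dz**2
        if rsq <= min_ring_radius**2:
            continue
        contours.append(_circle(center[:2], np.sqrt(rsq), z, n_points))
    return contours


def _tube_contours(tube: TubeSpec, z_step: float, n_points: int) -> list[np.ndarray]:
    """Elliptical z-plane cross-sections of a slanted circular tube."""
    u = tube.direction
    if abs(u[2]) < 0.2:
        raise ValidationError(
            "tube axis too close to horizontal for z-plane contouring "
            f"(|u_z| = {abs(u[2]):.2f} < 0.2)"
        )
    z0 = tube.start[2]
    z1 = tube.start[2] + tube.length * u[2]
    lo, hi = min(z0, z1), max(z0, z1)
    # in-plane ellipse axes: semi-major r/|u_z| along the horizontal
    # projection of the axis, semi-minor r perpendicular to it
    horiz = np.array([u[0], u[1], 0.0])
    h_norm = np.linalg.norm(horiz)
    e1 = horiz / h_norm if h_norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    e2 = np.array([-e1[1], e1[0], 0.0])
    a = tube.radius / abs(u[2])
    b = tube.radius

    contours = []
    phi = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    for k in range(int(np.ceil(lo / z_step - 1e-9)), int(np.floor(hi / z_step + 1e-9)) + 1):
        z = k * z_step
        s = (z - tube.start[2]) / u[2]
        if s < 0 or s > tube.length:
            continue
        c = tube.start + s * u
        pts = (
            c[None, :]
            + a * np.cos(phi)[:, None] * e1[None, :]
            + b * np.sin(phi)[:, None] * e2[None, :]
        )
        pts[:, 2] = z
        contours.append(pts)
    return contours


def generate_endosome_scene(
    preset: str = "sm_loaded",
    seed: int = 0,
    bm_radius_nm: float = 400.0,
    tubule_length_nm: float = 500.0,
    tubule_radius_nm: float = 30.0,
    **overrides,
) -> tuple[ContourModel, SyntheticScene]:
    """Build one classified contour model plus its ground-truth scene.

    Presets fix the per-class channel densities (see
    :data:`DENSITY_PRESETS`); the geometry (ILV placement, tubule
    azimuth) is jittered deterministically by ``seed``.  Keyword
    overrides replace any :class:`SyntheticScene` field of the same name.
    """
    if preset not in DENSITY_PRESETS:
        raise ValidationError(
            f"unknown preset {preset!r}; expected one of {sorted(DENSITY_PRESETS)}"
        )
    rng = np.random.default_rng(seed)
    z_step = float(overrides.pop("z_step_nm", 10.0))
    pixel_size = float(overrides.pop("pixel_size_nm", 65.0))
    image_shape = tuple(overrides.pop("image_shape", (96, 96)))

    # scene centred in the field of view, z chosen so all coords stay >= 0
    cx = image_shape[1] * pixel_size / 2.0
    cy = image_shape[0] * pixel_size / 2.0
    cz = 80 * z_step
    bm_center = np.array([cx, cy, cz])
    bm_radius = float(bm_radius_nm)
    half_height = min(150.0, 0.45 * bm_radius)

    ilvs = []
    for _ in range(3):
        radius = rng.uniform(30.0, 38.0)
        # keep ILVs near the projection centre so their masks clear the
        # blurred BM ring and retain an exclusive region
        rho = rng.uniform(40.0, 140.0)
        phi = rng.uniform(0.0, 2 * np.pi)
        z_off = rng.uniform(-0.5, 0.5) * (half_height - radius - 25.0)
        ilvs.append(
            SphereSpec(
                center=bm_center + np.array([rho * np.cos(phi), rho * np.sin(phi), z_off]),
                radius=radius,
            )
        )

    azimuth = rng.uniform(0.0, 2 * np.pi)
    elevation = np.deg2rad(45.0)
    # attachment point low on the truncated sphere so the tubule clears it
    attach_polar = np.deg2rad(-15.0)
    start = bm_center + bm_radius * np.array([
        np.cos(attach_polar) * np.cos(azimuth),
        np.cos(attach_polar) * np.sin(azimuth),
        np.sin(attach_polar),
    ])
    direction = np.array([
        np.cos(elevation) * np.cos(azimuth),
        np.cos(elevation) * np.sin(azimuth),
        np.sin(elevation),
    ])
    tubule = TubeSpec(
        start=start, direction=direction,
        radius=float(tubule_radius_nm), length=float(tubule_length_nm),
    )

    geometry = SceneGeometry(
        bm_center=bm_center,
        bm_radius=bm_radius,
        bm_half_height=half_height,
        ilvs=ilvs,
        tubule=tubule,
    ).validate()

    objects = [
        ContourObject(
            label=CompartmentClass.BM,
            contours=_sphere_contours(
                bm_center, bm_radius, z_step, n_points=96,
                z_min=cz - half_height, z_max=cz + half_height,
            ),
            capped=False,  # the section truncates the sphere
        )
    ]
    for ilv in ilvs:
        objects.append(
            ContourObject(
                label=CompartmentClass.ILV,
                contours=_sphere_contours(ilv.center, ilv.radius, z_step, n_points=48),
                capped=True,
            )
        )
    objects.append(
        ContourObject(
            label=CompartmentClass.RT,
            contours=_tube_contours(tubule, z_step, n_points=48),
            capped=True,
        )
    )
    model = ContourModel(
        endosome_id=f"synthetic-{preset}-seed{seed}",
        z_step=z_step,
        objects=objects,
        pixel_size_model=1.0,
    ).validate(require_all_classes=True)

    scene = SyntheticScene(
        geometry=geometry,
        densities={ch: dict(dens) for ch, dens in DENSITY_PRESETS[preset].items()},
        seed=seed,
        z_step_nm=z_step,
        pixel_size_nm=pixel_size,
        image_shape=image_shape,
        **overrides,
    )
    _attach_truth(model, scene)
    return model, scene


def _class_mesh(model: ContourModel) -> dict[CompartmentClass, np.ndarray]:
    meshes: dict[CompartmentClass, list[np.ndarray]] = {}
    for obj in model.objects:
        meshes.setdefault(obj.label, []).append(mesh_object(obj))
    return {label: np.concatenate(tris) for label, tris in meshes.items()}


def _attach_truth(model: ContourModel, scene: SyntheticScene) -> None:
    areas = {
        label: float(_triangle_areas(tris).sum())
        for label, tris in _class_mesh(model).items()
    }
    total = sum(areas.values())
    scene.truth_areas = areas
    scene.truth_relative = {}
    for channel, dens in scene.densities.items():
        mean_density = sum(dens[c] * areas[c] for c in areas) / total
        scene.truth_relative[channel] = {
            c: dens[c] / mean_density for c in areas
        }


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _deposit_bilinear(field: np.ndarray, rows: np.ndarray, cols: np.ndarray, weights: np.ndarray) -> None:
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr, cc = r0 + dr, c0 + dc
        ok = (rr >= 0) & (rr < field.shape[0]) & (cc >= 0) & (cc < field.shape[1])
        np.add.at(field, (rr[ok], cc[ok]), (weights * w)[ok])


def render_channels(
    model: ContourModel,
    scene: SyntheticScene,
) -> tuple[dict[str, ChannelImage], dict[str, np.ndarray], np.ndarray]:
    """Render all channels of a scene.

    Returns ``(images, expected, transform)``: noisy channel images, the
    noise-free expected images (background included) for oracle tests,
    and the 3x3 model-nm -> image-px transform (a pure scaling; the
    synthetic registration is exact by construction).
    """
    rng = np.random.default_rng(scene.seed)
    px = scene.pixel_size_nm
    shape = scene.image_shape
    psf_sigma_px = scene.psf_sigma_nm / px

    meshes = _class_mesh(model)
    images: dict[str, ChannelImage] = {}
    expected: dict[str, np.ndarray] = {}
    for channel in scene.densities:
        field2d = np.zeros(shape, dtype=float)
        for label, tris in meshes.items():
            areas = _triangle_areas(tris)
            centroids = tris.mean(axis=1)
            weights = scene.densities[channel][label] * areas * scene.photon_scale
            _deposit_bilinear(field2d, centroids[:, 1] / px, centroids[:, 0] / px, weights)
        clean = gaussian_filter(field2d, psf_sigma_px, mode="constant") + scene.background
        expected[channel] = clean
        if scene.noise == "poisson":
            noisy = rng.poisson(clean).astype(float)
        elif scene.noise == "gaussian":
            noisy = clean + rng.normal(0.0, scene.read_noise_sigma, size=shape)
        elif scene.noise == "none":
            noisy = clean.copy()
        else:
            raise ValidationError(f"unknown noise model {scene.noise!r}")
        images[channel] = ChannelImage(pixels=noisy, channel=channel, pixel_size_nm=px)

    transform = np.array([[1.0 / px, 0.0, 0.0], [0.0, 1.0 / px, 0.0], [0.0, 0.0, 1.0]])
    return images, expected, transform


def write_scene(
    model: ContourModel,
    scene: SyntheticScene,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write model JSON, per-channel TIFFs, truth JSON and transform JSON
    into ``out_dir``; returns the paths keyed by role."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, _expected, transform = render_channels(model, scene)
    paths: dict[str, Path] = {}

    model_path = out_dir / "model.json"
    write_contour_model(model, model_path)
    paths["model"] = model_path

    for channel, image in images.items():
        p = out_dir / f"channel_{channel}.tif"
        tifffile.imwrite(p, image.pixels.astype(np.float32))
        paths[f"channel:{channel}"] = p

    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(scene.truth_json(), fh, indent=2)
    paths["truth"] = truth_path

    transform_path = out_dir / "transform.json"
    with open(transform_path, "w") as fh:
        json.dump(
            {"matrix": transform.tolist(), "seed": scene.seed,
             "parameter_digest": scene.parameter_digest()},
            fh, indent=2,
        )
    paths["transform"] = transform_path
    return paths


# ---------------------------------------------------------------------------
# Section-penetration phantoms
# ---------------------------------------------------------------------------

def generate_edge_stack(
    labelling: str,
    section_thickness_nm: float = 1000.0,
    psf_sigma_nm: float = 150.0,
    seed: int = 0,
    pixel_size_nm: float = 65.0,
    shape: tuple[int, int] = (96, 160),
    surface_thickness_nm: float = 20.0,
    amplitude: float = 4000.0,
    background: float = 20.0,
    noise: str = "poisson",
) -> np.ndarray:
    """Single-plane image of a vertically cut section edge.

    ``labelling="surface"`` confines fluorophores to a slab much thinner
    than the PSF at the section edge; ``"volume"`` fills the full
    ``section_thickness_nm``.  Both are blurred with the PSF, offset and
    noised.  The edge runs vertically; profiles should be taken along x.
    """
    if labelling not in ("surface", "volume"):
        raise ValidationError(f"labelling must be 'surface' or 'volume', got {labelling!r}")
    rng = np.random.default_rng(seed)
    depth = surface_thickness_nm if labelling == "surface" else section_thickness_nm
    x_edge = shape[1] // 3 * pixel_size_nm

    cols = np.arange(shape[1], dtype=float)
    left = (cols - 0.5) * pixel_size_nm
    right = (cols + 0.5) * pixel_size_nm
    overlap = np.clip(np.minimum(right, x_edge + depth) - np.maximum(left, x_edge), 0.0, None)
    # equal total emission per unit edge length regardless of depth
    profile = amplitude * overlap / depth
    field2d = np.tile(profile, (shape[0], 1))
    clean = gaussian_filter(field2d, psf_sigma_nm / pixel_size_nm, mode="constant") + background
    return _apply_noise(clean, noise, rng)


def generate_serial_sections(
    labelling: str,
    n_sections: int,
    seed: int = 0,
    shape: tuple[int, int] = (100, 100),
    corr_length_px: float = 4.0,
    amplitude: float = 100.0,
    background: float = 10.0,
    noise: str = "poisson",
) -> list[np.ndarray]:
    """Registered serial-section images.

    ``volume`` labelling: all sections share one underlying structure
    (plus independent noise) -> high pairwise correlation.  ``surface``
    labelling: each section carries an independent label placement with
    the same statistics -> near-zero correlation.
    """
    if labelling not in ("surface", "volume"):
        raise ValidationError(f"labelling must be 'surface' or 'volume', got {labelling!r}")
    if n_sections < 2:
        raise ValidationError(f"need >= 2 sections, got {n_sections}")
    rng = np.random.default_rng(seed)

    def smooth_field() -> np.ndarray:
        raw = gaussian_filter(rng.standard_normal(shape), corr_length_px)
        raw -= raw.min()
        peak = raw.max()
        return amplitude * raw / peak if peak > 0 else raw

    shared = smooth_field()
    sections = []
    for _ in range(n_sections):
        structure = shared if labelling == "volume" else smooth_field()
        sections.append(_apply_noise(structure + background, noise, rng))
    return sections


def _apply_noise(clean: np.ndarray, noise: str, rng: np.random.Generator) -> np.ndarray:
    if noise == "poisson":
        return rng.poisson(clean).astype(float)
    if noise == "none":
        return clean.copy()
    if noise.startswith("gaussian"):
        return clean + rng.normal(0.0, 5.0, size=clean.shape)
    raise ValidationError(f"unknown noise model {noise!r}")
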