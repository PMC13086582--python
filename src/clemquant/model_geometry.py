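"""Classified membrane contour models: reading, validation, surface
measurement and projection into the fluorescence image plane.

Coordinate conventions
----------------------
Model coordinates are in nanometres, right-handed, all non-negative.
Image rasters use pixel centres at integer coordinates, origin at the
top-left, ``row = y`` and ``col = x``.  A registration transform maps
model ``(x, y)`` in nm to image pixel coordinates ``(col, row)``.

Contour files
-------------
Two dialects are read:

* ``json`` -- the native schema::

      {
        "endosome_id": "...",
        "z_step_nm": 10.0,
        "pixel_size_nm": 1.0,          # optional metadata
        "objects": [
          {"class": "BM", "capped": true,
           "contours": [[[x, y, z], ...], ...]},
          ...
        ]
      }

* ``imod_points`` -- whitespace-separated ``object contour x y z``
  records with 1-based object/contour indices, as produced by
  ``model2point`` with default options.  A mapping from object index to
  compartment class must be supplied.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.draw import line as _draw_line

from clemquant.errors import FormatError, GeometryError, ValidationError

logger = logging.getLogger(__name__)

#: Relative tolerance used when checking that contour z values sit on the
#: z-step grid.
_Z_GRID_RTOL = 1e-3


class CompartmentClass(str, Enum):
    """The three endosomal membrane compartment classes."""

    BM = "BM"   # globular boundary (outer) membrane
    ILV = "ILV"  # intraluminal vesicle
    RT = "RT"   # recycling tubule protruding outward from the BM

    @classmethod
    def coerce(cls, value: "CompartmentClass | str") -> "CompartmentClass":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ValidationError(
                f"unknown compartment class {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


@dataclass
class ContourObject:
    """One classified membrane object: a stack of ordered point contours.

    Parameters
    ----------
    label
        Compartment class of every contour in this object.
    contours
        List of ``(n_points, 3)`` float arrays, one per z-slice, ordered
        points, coordinates in nm.  All points of one contour share a
        single z value.
    capped
        Whether terminal contours are closed with a fan cap when the
        object is meshed.  ILV and RT objects are capped; for BM objects
        the flag records whether the tomographic section truncates the
        sphere (``False`` -> leave the truncation open).
    """

    label: CompartmentClass
    contours: list[np.ndarray]
    capped: bool = True

    def __post_init__(self) -> None:
        self.label = CompartmentClass.coerce(self.label)
        self.contours = [np.asarray(c, dtype=float) for c in self.contours]

    @property
    def z_values(self) -> np.ndarray:
        return np.array([float(c[0, 2]) for c in self.contours])


@dataclass
class ContourModel:
    """A classified per-compartment 3D contour stack with physical units."""

    endosome_id: str
    z_step: float
    objects: list[ContourObject]
    pixel_size_model: float | None = None

    def validate(self, require_all_classes: bool = False) -> "ContourModel":
        """Check all structural invariants, raising :class:`ValidationError`.

        With ``require_all_classes`` the model must additionally contain
        at least one object of each of BM, ILV and RT (the selection
        rule applied before quantification).
        """
        if self.z_step <= 0 or not np.isfinite(self.z_step):
            raise ValidationError(f"z_step must be positive, got {self.z_step}")
        if not self.objects:
            raise ValidationError("model contains no objects")
        for i_obj, obj in enumerate(self.objects):
            if not obj.contours:
                raise ValidationError(f"object {i_obj} ({obj.label.value}) is empty")
            for i_ct, contour in enumerate(obj.contours):
                where = f"object {i_obj} ({obj.label.value}), contour {i_ct}"
                if contour.ndim != 2 or contour.shape[1] != 3:
                    raise ValidationError(f"{where}: expected (n, 3) points")
                if contour.shape[0] < 3:
                    raise ValidationError(
                        f"{where}: has {contour.shape[0]} points, need >= 3"
                    )
                if not np.all(np.isfinite(contour)):
                    raise ValidationError(f"{where}: non-finite coordinates")
                if np.any(contour < 0):
                    raise ValidationError(f"{where}: negative coordinates")
                z = contour[:, 2]
                if np.ptp(z) > _Z_GRID_RTOL * self.z_step:
                    raise ValidationError(f"{where}: points do not share one z value")
                steps = z[0] / self.z_step
                if abs(steps - round(steps)) > _Z_GRID_RTOL:
                    raise ValidationError(
                        f"{where}: z={z[0]} is not a multiple of z_step={self.z_step}"
                    )
        if require_all_classes:
            present = {obj.label for obj in self.objects}
            missing = set(CompartmentClass) - present
            if missing:
                raise ValidationError(
                    "model is not analysable: missing classes "
                    f"{sorted(c.value for c in missing)}"
                )
        return self

    def classes(self) -> set[CompartmentClass]:
        return {obj.label for obj in self.objects}

    def objects_of(self, label: CompartmentClass) -> list[ContourObject]:
        return [o for o in self.objects if o.label is label]


@dataclass
class DomainMeasure:
    """Per-class membrane measure: surface area (nm^2, mode ``area3d``)
    or outline length (nm, mode ``length2d``)."""

    per_class: dict[CompartmentClass, float]
    mode: str

    @property
    def total(self) -> float:
        return float(sum(self.per_class.values()))

    def __getitem__(self, label: CompartmentClass) -> float:
        return self.per_class[CompartmentClass.coerce(label)]


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def read_contour_model(
    path: str | Path,
    dialect: str = "json",
    class_map: Mapping[int, CompartmentClass | str] | None = None,
    endosome_id: str | None = None,
    z_step: float | None = None,
) -> ContourModel:
    """Read and validate a classified contour model.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"json"`` for the native schema, ``"imod_points"`` for
        ``model2point``-style ASCII (``object contour x y z``).
    class_map
        Required for ``imod_points``: maps 1-based object index to
        compartment class.
    endosome_id, z_step
        For ``imod_points`` only; ``z_step`` defaults to the smallest
        positive z spacing found in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "json":
        model = _read_json(path)
    elif dialect == "imod_points":
        if class_map is None:
            raise ValidationError("imod_points dialect requires a class_map")
        model = _read_imod_points(path, class_map, endosome_id, z_step)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    return model.validate()


def _read_json(path: Path) -> ContourModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    try:
        objects = [
            ContourObject(
                label=CompartmentClass.coerce(entry["class"]),
                contours=[np.asarray(c, dtype=float) for c in entry["contours"]],
                capped=bool(entry.get("capped", True)),
            )
            for entry in payload["objects"]
        ]
        return ContourModel(
            endosome_id=str(payload["endosome_id"]),
            z_step=float(payload["z_step_nm"]),
            objects=objects,
            pixel_size_model=(
                float(payload["pixel_size_nm"]) if "pixel_size_nm" in payload else None
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed contour JSON ({exc})") from exc


def _read_imod_points(
    path: Path,
    class_map: Mapping[int, CompartmentClass | str],
    endosome_id: str | None,
    z_step: float | None,
) -> ContourModel:
    # records: (object, contour) -> list of points, insertion ordered
    records: dict[tuple[int, int], list[list[float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 fields "
                    f"'object contour x y z', got {len(fields)}"
                )
            try:
                i_obj, i_ct = int(fields[0]), int(fields[1])
                x, y, z = (float(v) for v in fields[2:])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable record ({exc})") from exc
            records.setdefault((i_obj, i_ct), []).append([x, y, z])
    if not records:
        raise FormatError(f"{path}: no point records found")

    by_object: dict[int, list[np.ndarray]] = {}
    for (i_obj, _i_ct), pts in records.items():
        by_object.setdefault(i_obj, []).append(np.asarray(pts, dtype=float))

    objects = []
    for i_obj in sorted(by_object):
        if i_obj not in class_map:
            raise ValidationError(f"object index {i_obj} missing from class_map")
        objects.append(
            ContourObject(
                label=CompartmentClass.coerce(class_map[i_obj]),
                contours=by_object[i_obj],
            )
        )

    if z_step is None:
        zs = np.unique(np.concatenate([o.z_values for o in objects]))
        dz = np.diff(np.sort(zs))
        dz = dz[dz > 0]
        z_step = float(dz.min()) if dz.size else 1.0
    return ContourModel(
        endosome_id=endosome_id or path.stem,
        z_step=z_step,
        objects=objects,
    )


def write_contour_model(model: ContourModel, path: str | Path) -> None:
    """Serialize a model to the native JSON dialect (units: nm)."""
    payload: dict = {
        "endosome_id": model.endosome_id,
        "z_step_nm": model.z_step,
        "objects": [
            {
                "class": obj.label.value,
                "capped": obj.capped,
                "contours": [c.tolist() for c in obj.contours],
            }
            for obj in model.objects
        ],
    }
    if model.pixel_size_model is not None:
        payload["pixel_size_nm"] = model.pixel_size_model
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------

def _closed_perimeter(xy: np.ndarray) -> float:
    d = np.diff(np.vstack([xy, xy[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _polygon_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _resample_closed(xy: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to ``n`` vertices equally spaced in arc
    length, preserving orientation and the starting point."""
    closed = np.vstack([xy, xy[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("degenerate contour: zero perimeter")
    t = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(t, s, closed[:, 0])
    out[:, 1] = np.interp(t, s, closed[:, 1])
    return out


def _signed_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0


def _align_ring(ref: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Cyclically roll ``ring`` to the offset minimizing the summed squared
    distance to ``ref`` (both (n, 2), same orientation)."""
    n = len(ring)
    best_shift, best_cost = 0, np.inf
    for shift in range(n):
        rolled = np.roll(ring, -shift, axis=0)
        cost = float(np.sum((rolled - ref) ** 2))
        if cost < best_cost:
            best_cost, best_shift = cost, shift
    return np.roll(ring, -best_shift, axis=0)


def _triangle_areas(tris: np.ndarray) -> np.ndarray:
    # tris: (m, 3, 3)
    a = tris[:, 1] - tris[:, 0]
    b = tris[:, 2] - tris[:, 0]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def mesh_object(
    obj: ContourObject,
    ring_points: int = 64,
    cap_override: bool | None = None,
) -> np.ndarray:
    """Triangulate one contour object into a surface mesh.

    Adjacent-slice triangulation: both contours are resampled to a common
    vertex count, oriented consistently, aligned by the minimum-distance
    cyclic offset, and joined by a triangle strip.  Terminal contours of
    capped objects are closed by a centroid fan.  Single-slice objects
    become flat discs (two cap faces) with a warning.

    Returns an ``(n_triangles, 3, 3)`` array of 3D triangles (nm).
    """
    capped = obj.capped if cap_override is None else cap_override
    order = np.argsort([c[0, 2] for c in obj.contours])
    contours = [obj.contours[i] for i in order]

    n = max(ring_points, max(len(c) for c in contours))
    rings, zs = [], []
    for contour in contours:
        ring = _resample_closed(contour[:, :2], n)
        if _signed_area(ring) < 0:  # enforce CCW
            ring = ring[::-1]
        rings.append(ring)
        zs.append(float(contour[0, 2]))

    tris: list[np.ndarray] = []

    def _fan(ring: np.ndarray, z: float) -> np.ndarray:
        centroid = np.append(ring.mean(axis=0), z)
        pts3 = np.column_stack([ring, np.full(len(ring), z)])
        nxt = np.roll(pts3, -1, axis=0)
        return np.stack([np.broadcast_to(centroid, pts3.shape), pts3, nxt], axis=1)

    if len(rings) == 1:
        warnings.warn(
            f"object of class {obj.label.value} spans a single slice; "
            "treating as a flat disc (two cap faces)",
            stacklevel=2,
        )
        cap = _fan(rings[0], zs[0])
        return np.concatenate([cap, cap])

    for (ra, za), (rb, zb) in zip(zip(rings, zs), zip(rings[1:], zs[1:])):
        rb = _align_ring(ra, rb)
        a3 = np.column_stack([ra, np.full(n, za)])
        b3 = np.column_stack([rb, np.full(n, zb)])
        a3n, b3n = np.roll(a3, -1, axis=0), np.roll(b3, -1, axis=0)
        tris.append(np.stack([a3, a3n, b3], axis=1))
        tris.append(np.stack([a3n, b3n, b3], axis=1))

    if capped:
        tris.append(_fan(rings[0], zs[0]))
        tris.append(_fan(rings[-1], zs[-1]))

    return np.concatenate(tris)


def compute_domain_measure(
    model: ContourModel,
    mode: str = "area3d",
    cap_bm: bool = True,
    ring_points: int = 64,
) -> DomainMeasure:
    """Measure each compartment class of a validated model.

    ``mode="area3d"`` returns triangulated-mesh surface areas in nm^2;
    ILV/RT objects are closed with fan caps, BM objects are capped only
    when both the object's ``capped`` flag and ``cap_bm`` allow it.
    ``mode="length2d"`` returns summed closed-polygon perimeters in nm
    and requires single-plane contours.
    """
    model.validate()
    per_class: dict[CompartmentClass, float] = {}
    if mode == "length2d":
        zs = np.unique(
            np.concatenate([c[:, 2] for o in model.objects for c in o.contours])
        )
        if np.ptp(zs) > _Z_GRID_RTOL * model.z_step:
            raise GeometryError("mode=length2d requires single-plane contours")
        for obj in model.objects:
            total = 0.0
            for contour in obj.contours:
                p = _closed_perimeter(contour[:, :2])
                if p <= 0:
                    raise GeometryError(
                        f"degenerate contour (zero perimeter) in {obj.label.value}"
                    )
                total += p
            per_class[obj.label] = per_class.get(obj.label, 0.0) + total
    elif mode == "area3d":
        for obj in model.objects:
            cap = obj.capped if obj.label is not CompartmentClass.BM else (obj.capped and cap_bm)
            tris = mesh_object(obj, ring_points=ring_points, cap_override=cap)
            area = float(_triangle_areas(tris).sum())
            if area <= 0:
                raise GeometryError(f"zero mesh area for {obj.label.value} object")
            per_class[obj.label] = per_class.get(obj.label, 0.0) + area
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return DomainMeasure(per_class=per_class, mode=mode)


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def _as_matrix(transform) -> np.ndarray:
    matrix = getattr(transform, "matrix", transform)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValidationError(f"expected a 3x3 homogeneous matrix, got {matrix.shape}")
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise GeometryError("registration transform is singular")
    return matrix


def project_outlines(
    model: ContourModel,
    transform,
    image_shape: tuple[int, int],
) -> dict[CompartmentClass, np.ndarray]:
    """Z-project every contour of each class onto one 2D outline raster.

    Each contour is transformed with the model->image affine and drawn as
    a closed 8-connected 1-px polyline.  All z-slices collapse onto one
    plane.  Out-of-bounds pixels are clipped (warning logged); if every
    pixel of the model is clipped, an error is raised.
    """
    matrix = _as_matrix(transform)
    rows, cols = int(image_shape[0]), int(image_shape[1])
    if rows <= 0 or cols <= 0:
        raise ValidationError(f"image_shape must be positive, got {image_shape}")

    rasters = {
        label: np.zeros((rows, cols), dtype=np.uint8) for label in model.classes()
    }
    n_total = n_clipped = 0
    for obj in model.objects:
        raster = rasters[obj.label]
        for contour in obj.contours:
            xy1 = np.column_stack([contour[:, 0], contour[:, 1], np.ones(len(contour))])
            px = (matrix @ xy1.T).T
            c = np.round(px[:, 0]).astype(int)  # col = x
            r = np.round(px[:, 1]).astype(int)  # row = y
            closed_r = np.append(r, r[0])
            closed_c = np.append(c, c[0])
            for i in range(len(r)):
                rr, cc = _draw_line(closed_r[i], closed_c[i], closed_r[i + 1], closed_c[i + 1])
                inside = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
                n_total += rr.size
                n_clipped += int((~inside).sum())
                raster[rr[inside], cc[inside]] = 1
    if n_total > 0 and n_clipped == n_total:
        raise GeometryError("model outside field of view: all projected pixels clipped")
    if n_clipped:
        logger.warning(
            "project_outlines: clipped %d/%d projected pixels outside %s",
            n_clipped, n_total, (rows, cols),
        )
    return rasters
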