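"""Landmark-based 2D registration: least-squares affine/similarity fits
and a leave-one-out correlation error map."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import SimilarityTransform

from clemquant.errors import GeometryError, ValidationError


@dataclass
class RegistrationTransform:
    """Homogeneous 3x3 affine mapping model/EM ``(x, y)`` coordinates to
    FM pixel coordinates ``(col, row)``."""

    matrix: np.ndarray
    ttype: str = "affine"  # similarity | affine | identity
    residuals: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValidationError(f"expected 3x3 matrix, got {self.matrix.shape}")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise GeometryError("registration matrix is singular")
        if self.residuals is not None:
            self.residuals = np.asarray(self.residuals, dtype=float)
            if np.any(self.residuals < 0):
                raise ValidationError("residuals must be non-negative")

    @classmethod
    def identity(cls) -> "RegistrationTransform":
        return cls(matrix=np.eye(3), ttype="identity")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        ones = np.ones((len(points), 1))
        return (self.matrix @ np.hstack([points, ones]).T).T[:, :2]

    def inverse(self) -> "RegistrationTransform":
        return RegistrationTransform(matrix=np.linalg.inv(self.matrix), ttype=self.ttype)

    def to_json(self, path: str | Path) -> None:
        payload = {"matrix": self.matrix.tolist(), "type": self.ttype}
        if self.residuals is not None:
            payload["residuals_px"] = self.residuals.tolist()
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegistrationTransform":
        payload = json.loads(Path(path).read_text())
        return cls(
            matrix=np.asarray(payload["matrix"], dtype=float),
            ttype=payload.get("type", "affine"),
            residuals=(
                np.asarray(payload["residuals_px"], dtype=float)
                if "residuals_px" in payload else None
            ),
        )


def _check_points(points_src: np.ndarray, points_dst: np.ndarray, minimum: int) -> tuple[np.ndarray, np.ndarray]:
    src = np.atleast_2d(np.asarray(points_src, dtype=float))
    dst = np.atleast_2d(np.asarray(points_dst, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValidationError(
            f"landmark arrays must match and be (n, 2); got {src.shape} and {dst.shape}"
        )
    if len(src) < minimum:
        raise ValidationError(f"need >= {minimum} landmark pairs, got {len(src)}")
    if len(np.unique(src.round(decimals=9), axis=0)) != len(src):
        raise ValidationError("duplicate source landmarks")
    return src, dst


def fit_landmark_affine(
    points_src: np.ndarray,
    points_dst: np.ndarray,
    ttype: str = "affine",
) -> RegistrationTransform:
    """Least-squares landmark transform (``affine`` or ``similarity``)
    minimizing the summed squared destination-space residual."""
    if ttype == "affine":
        src, dst = _check_points(points_src, points_dst, 3)
        # affine needs non-collinear sources
        centred = src - src.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-9) < 2:
            raise GeometryError("source landmarks are collinear; affine fit is degenerate")
        design = np.hstack([src, np.ones((len(src), 1))])
        coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
        matrix = np.eye(3)
        matrix[:2, :] = coef.T
    elif ttype == "similarity":
        src, dst = _check_points(points_src, points_dst, 2)
        if hasattr(SimilarityTransform, "from_estimate"):
            estimator = SimilarityTransform.from_estimate(src, dst)
            if not estimator:
                raise GeometryError("degenerate landmark configuration; fit failed")
        else:  # scikit-image < 0.26
            estimator = SimilarityTransform()
            if not estimator.estimate(src, dst):
                raise GeometryError("degenerate landmark configuration; fit failed")
        matrix = np.asarray(estimator.params, dtype=float)
    else:
        raise ValidationError(f"ttype must be 'affine' or 'similarity', got {ttype!r}")
    if not np.all(np.isfinite(matrix)):
        raise GeometryError("degenerate landmark configuration; fit failed")
    residuals = np.linalg.norm(
        (matrix @ np.hstack([src, np.ones((len(src), 1))]).T).T[:, :2] - dst, axis=1
    )
    return RegistrationTransform(matrix=matrix, ttype=ttype, residuals=residuals)


def correlation_error_map(
    points_src: np.ndarray,
    points_dst: np.ndarray,
    grid_shape: tuple[int, int],
    ttype: str = "affine",
    idw_exponent: float = 2.0,
) -> np.ndarray:
    """Predicted registration error over the image grid.

    Each landmark's error is its leave-one-out residual: the transform is
    refit without the landmark and evaluated at it.  The per-landmark
    errors are interpolated over the grid by inverse-distance weighting
    (exponent 2 by default); at a landmark position the field equals that
    landmark's residual exactly.
    """
    src, dst = _check_points(points_src, points_dst, 4)
    n = len(src)
    loo = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        t = fit_landmark_affine(src[keep], dst[keep], ttype=ttype)
        loo[i] = float(np.linalg.norm(t.apply(src[i : i + 1])[0] - dst[i]))

    rows, cols = int(grid_shape[0]), int(grid_shape[1])
    rr, cc = np.mgrid[0:rows, 0:cols]
    grid = np.stack([cc.ravel(), rr.ravel()], axis=1).astype(float)  # (x, y)
    d = np.linalg.norm(grid[:, None, :] - dst[None, :, :], axis=2)  # (px, n)

    out = np.empty(grid.shape[0])
    at_landmark = d.min(axis=1) < 1e-9
    if at_landmark.any():
        out[at_landmark] = loo[d[at_landmark].argmin(axis=1)]
    rest = ~at_landmark
    if rest.any():
        w = 1.0 / d[rest] ** idw_exponent
        out[rest] = (w * loo[None, :]).sum(axis=1) / w.sum(axis=1)
    return out.reshape(rows, cols)
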