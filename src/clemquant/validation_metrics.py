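"""Section-penetration validation: width-averaged line profiles, FWHM
estimation and serial-section Pearson correlation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import pearsonr

from clemquant.errors import AnalysisError, ValidationError


@dataclass
class LineProfile:
    """Intensity profile along a segment, averaged over a perpendicular
    width.  Positions are in micrometres at uniform (pixel-size) spacing."""

    positions: np.ndarray
    intensities: np.ndarray
    averaging_width_px: int
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.intensities.shape:
            raise ValidationError("positions and intensities must be matching 1D arrays")
        spacing = np.diff(self.positions)
        if np.any(spacing <= 0):
            raise ValidationError("positions must be strictly increasing")
        if spacing.size and not np.allclose(spacing, spacing[0], rtol=1e-6):
            raise ValidationError("positions must be uniformly spaced")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")

    @property
    def spacing_um(self) -> float:
        return float(self.positions[1] - self.positions[0])


def extract_line_profile(
    image: np.ndarray,
    pixel_size_um: float,
    start: tuple[float, float],
    end: tuple[float, float],
    width_px: int = 10,
) -> LineProfile:
    """Sample an intensity profile along a segment.

    ``start`` and ``end`` are ``(col, row)`` pixel coordinates.  Samples
    are taken at pixel-size spacing along the segment; each sample is the
    mean of ``width_px`` bilinear samples spread at unit spacing along the
    perpendicular (centred on the segment).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("expected a 2D image")
    if width_px < 1:
        raise ValidationError(f"width_px must be >= 1, got {width_px}")
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length <= 0:
        raise ValidationError("segment endpoints coincide")
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    n_samples = int(np.floor(length)) + 1
    t = np.arange(n_samples, dtype=float)
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0

    # sample grid: (n_samples, width_px, 2) in (col, row)
    grid = (
        p0[None, None, :]
        + t[:, None, None] * direction[None, None, :]
        + offsets[None, :, None] * normal[None, None, :]
    )
    cols, rows = grid[..., 0], grid[..., 1]
    if (
        rows.min() < 0 or cols.min() < 0
        or rows.max() > image.shape[0] - 1 or cols.max() > image.shape[1] - 1
    ):
        raise ValidationError(
            "line profile exits the image when widened; shorten the segment "
            "or reduce width_px"
        )
    samples = map_coordinates(image, [rows.ravel(), cols.ravel()], order=1, mode="nearest")
    intensities = samples.reshape(rows.shape).mean(axis=1)
    return LineProfile(
        positions=t * pixel_size_um,
        intensities=intensities,
        averaging_width_px=width_px,
        pixel_size_um=pixel_size_um,
    )


@dataclass
class FwhmResult:
    """Full width at half maximum of a single-peak profile."""

    fwhm: float
    baseline: float
    peak: float
    left: float
    right: float

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise AnalysisError(f"non-positive FWHM {self.fwhm}")
        if not self.left < self.right:
            raise AnalysisError("left crossing must precede right crossing")
        if not self.baseline < self.peak:
            raise AnalysisError("baseline must lie below the peak")


def _count_peaks(y: np.ndarray, level: float) -> int:
    above = y > level
    return int(np.sum(above[1:] & ~above[:-1]) + above[0])


def estimate_fwhm(profile: LineProfile) -> FwhmResult:
    """FWHM of the dominant peak.

    The baseline is the mean of the first and last 10% of samples; the
    half level sits midway between baseline and the global maximum.
    Crossings are located by linear interpolation between the bracketing
    samples, moving inward from each end of the profile (outermost
    crossings).  Raises ``AnalysisError("peak truncated...")`` when a
    crossing is missing on either side; warns when several peaks rise
    above the half level.
    """
    y = profile.intensities
    x = profile.positions
    n = y.size
    if n < 5:
        raise ValidationError("profile too short for FWHM estimation")
    tail = max(1, n // 10)
    baseline = float(np.concatenate([y[:tail], y[-tail:]]).mean())
    # peak from a 3-point moving average: negligible on clean profiles,
    # suppresses the max-of-noise bias on noisy ones
    smoothed = y.copy()
    smoothed[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    i_peak = int(np.argmax(smoothed))
    peak = float(smoothed[i_peak])
    if peak <= baseline:
        raise AnalysisError("no peak above the baseline")
    half = baseline + (peak - baseline) / 2.0

    if _count_peaks(y, half) > 1:
        warnings.warn(
            "multiple peaks above the half level; using the global maximum",
            stacklevel=2,
        )

    left = _crossing(x, y, half, side="left", i_peak=i_peak)
    right = _crossing(x, y, half, side="right", i_peak=i_peak)
    return FwhmResult(
        fwhm=right - left, baseline=baseline, peak=peak, left=left, right=right
    )


def _crossing(x: np.ndarray, y: np.ndarray, level: float, side: str, i_peak: int) -> float:
    if side == "left":
        indices = range(0, i_peak)
    else:
        indices = range(y.size - 2, i_peak - 1, -1)
    for i in indices:
        lo, hi = (i, i + 1) if side == "left" else (i + 1, i)
        if y[lo] < level <= y[hi]:
            frac = (level - y[i]) / (y[i + 1] - y[i])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    raise AnalysisError(f"peak truncated: no half-level crossing on the {side} side")


def summarize_fwhm(results: list[FwhmResult]) -> tuple[float, float]:
    """Mean and sample standard deviation of per-profile FWHM values."""
    values = np.array([r.fwhm for r in results], dtype=float)
    if values.size == 0:
        raise ValidationError("no FWHM results to summarize")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def serial_section_pearson(
    section_i: np.ndarray,
    section_j: np.ndarray,
    background: tuple[float, float] | float = 0.0,
) -> float:
    """Pearson correlation between two registered, background-corrected
    section images over all ROI pixels."""
    a = np.asarray(section_i, dtype=float)
    b = np.asarray(section_j, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"section shapes differ: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("sections must be finite")
    if np.isscalar(background):
        ba = bb = float(background)
    else:
        ba, bb = (float(v) for v in background)
    a = a - ba
    b = b - bb
    if a.std() == 0 or b.std() == 0:
        raise AnalysisError("Pearson undefined: zero variance in a section")
    r, _ = pearsonr(a.ravel(), b.ravel())
    return float(r)
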