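"""Intensity profiles along hyphal centerlines.

A centerline is an ordered polyline in pixel coordinates with the
growing tip first.  ``extract_profile`` resamples the image along the
centerline at a uniform arclength step (µm from the tip, 0 at the tip),
averaging bilinearly interpolated values over a short segment
perpendicular to the centerline — the digital analogue of averaging the
fluorescence across the hyphal width.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "Centerline",
    "IntensityProfile",
    "extract_profile",
    "subtract_background",
    "normalize_profile",
    "aggregate_profiles_loess",
]


@dataclass
class Centerline:
    """Ordered 2D polyline (px); ``tip_first`` marks the tip at index 0."""

    frame: int
    points: np.ndarray  # (n, 2) float, columns (x, y)
    pixel_size: float  # µm / px
    tip_first: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("centerline needs >= 2 (x, y) points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            bad = int(np.argmax(seg <= 0))
            raise ValueError(f"duplicate consecutive centerline points at index {bad}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def tip_ordered_points(self) -> np.ndarray:
        return self.points if self.tip_first else self.points[::-1]

    @property
    def arclength_um(self) -> float:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return float(seg.sum() * self.pixel_size)


@dataclass
class IntensityProfile:
    """Fluorescence vs arclength-from-tip for one hypha/frame/channel."""

    arclength: np.ndarray  # µm, uniform grid starting at 0
    intensity: np.ndarray
    frame: int = 0
    channel: str = ""
    hypha_id: int = 0
    region_id: str = "stem"

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.arclength) != len(self.intensity):
            raise ValueError("grid and intensity lengths differ")
        if len(self.arclength) >= 2:
            steps = np.diff(self.arclength)
            if np.any(steps <= 0):
                raise ValueError("arclength grid must be strictly increasing")
        if len(self.arclength) and abs(self.arclength[0]) > 1e-9:
            raise ValueError("arclength grid must start at 0 (the tip)")

    @property
    def step(self) -> float:
        return float(self.arclength[1] - self.arclength[0]) if len(self.arclength) > 1 else 0.0

    def copy_with(self, intensity: np.ndarray) -> "IntensityProfile":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


def _resample_polyline(points: np.ndarray, spacings: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Points and unit tangents at the requested arclengths (px units)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.clip(spacings, 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seg[idx]
    p = points[idx] + frac[:, None] * (points[idx + 1] - points[idx])
    tang = (points[idx + 1] - points[idx]) / seg[idx][:, None]
    return p, tang


def extract_profile(
    frame_image: np.ndarray,
    centerline: Centerline,
    half_width: int = 2,
    step: Optional[float] = None,
    *,
    frame: Optional[int] = None,
    channel: str = "",
    hypha_id: int = 0,
    region_id: str = "stem",
    interpolation: str = "bilinear",
) -> IntensityProfile:
    """Sample the image along the centerline, tip at arclength 0.

    For every arclength sample the intensity is the mean of the image
    (bilinearly interpolated, or nearest-neighbour for cross-checks) over
    the ``2*half_width + 1`` px segment perpendicular to the centerline.

    Parameters
    ----------
    step
        Arclength grid step in µm; defaults to one pixel.
    half_width
        Half-width in px of the perpendicular averaging segment.

    Raises
    ------
    ValueError
        If any sampling point falls outside the image; the message names
        the offending arclength sample index.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    img = np.asarray(frame_image, dtype=float)
    px = centerline.pixel_size
    if step is None:
        step = px
    pts = centerline.tip_ordered_points
    total_px = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    s_um = np.arange(0.0, total_px * px + step * 0.5, step)
    s_um = s_um[s_um <= total_px * px + 1e-9]
    centers, tang = _resample_polyline(pts, s_um / px)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(-half_width, half_width + 1, dtype=float)
    # (n_samples, n_offsets, 2)
    coords = centers[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    xs, ys = coords[..., 0], coords[..., 1]
    out = (xs < -1e-9) | (xs > img.shape[1] - 1 + 1e-9) | (ys < -1e-9) | (ys > img.shape[0] - 1 + 1e-9)
    if np.any(out):
        bad = int(np.argmax(np.any(out, axis=1)))
        raise ValueError(f"centerline sample {bad} falls outside the image")
    order = 1 if interpolation == "bilinear" else 0
    vals = ndimage.map_coordinates(img, [ys.ravel(), xs.ravel()], order=order, mode="nearest")
    vals = vals.reshape(xs.shape).mean(axis=1)
    return IntensityProfile(
        arclength=s_um,
        intensity=vals,
        frame=centerline.frame if frame is None else frame,
        channel=channel,
        hypha_id=hypha_id,
        region_id=region_id,
    )


def subtract_background(
    profile: IntensityProfile,
    method: str = "percentile",
    param: float = 10.0,
    external_values: Optional[Sequence[float]] = None,
) -> IntensityProfile:
    """Background-subtract a profile and clip at zero.

    ``percentile`` subtracts the ``param``-th percentile of the profile
    itself (default 10th, a robust floor estimate); ``external_region``
    subtracts the mean of ``external_values`` sampled off the hypha.
    """
    if method == "percentile":
        if not (0 <= param < 100):
            raise ValueError("percentile must be in [0, 100)")
        level = float(np.percentile(profile.intensity, param))
    elif method == "external_region":
        if external_values is None or len(external_values) == 0:
            raise ValueError("external_region subtraction needs external_values")
        level = float(np.mean(external_values))
    else:
        raise ValueError(f"unknown background method {method!r}")
    return profile.copy_with(np.clip(profile.intensity - level, 0.0, None))


def normalize_profile(profile: IntensityProfile) -> IntensityProfile:
    """Scale the profile so its maximum equals 100 (percent scale)."""
    peak = float(np.max(profile.intensity))
    if peak <= 0:
        raise ValueError("no signal: profile maximum is not positive")
    return profile.copy_with(profile.intensity * (100.0 / peak))


def aggregate_profiles_loess(
    profiles: Sequence[IntensityProfile],
    span: float = 0.3,
    *,
    n_boot: int = 200,
    grid: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Locally weighted (lowess) mean curve over an ensemble of profiles.

    All profiles are resampled to a common arclength grid (the overlap of
    their supports), pooled, and smoothed with statsmodels' lowess using
    fraction ``span``.  A pointwise 95% interval is estimated by
    bootstrap resampling of whole profiles, and the arclength of the
    curve maximum is reported (e.g. the modal tip distance of a
    partition-complex signal).

    Returns
    -------
    dict with keys ``grid``, ``curve``, ``ci_low``, ``ci_high``,
    ``argmax_um``.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if len(profiles) < 5:
        raise ValueError("need at least 5 profiles")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    max_common = min(p.arclength[-1] for p in profiles)
    step = float(np.median([p.step for p in profiles]))
    if grid is None:
        grid = np.arange(0.0, max_common + step * 0.5, step)
    resampled = np.vstack(
        [np.interp(grid, p.arclength, p.intensity) for p in profiles]
    )

    def _fit(mat: np.ndarray) -> np.ndarray:
        x = np.tile(grid, mat.shape[0])
        y = mat.ravel()
        return lowess(y, x, frac=span, return_sorted=False, xvals=grid)

    curve = _fit(resampled)
    boots = np.empty((n_boot, len(grid)))
    for b in range(n_boot):
        take = rng.integers(0, len(profiles), size=len(profiles))
        boots[b] = _fit(resampled[take])
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5], axis=0)
    return {
        "grid": grid,
        "curve": curve,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "argmax_um": float(grid[int(np.argmax(curve))]),
    }
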