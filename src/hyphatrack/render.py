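"""Render simulated hyphae as noisy multi-channel fluorescence stacks.

The stem lies along the image x axis with a fixed base; the tip advances
to the right.  Branches leave the stem at 45 degrees.  Each focus is an
isotropic Gaussian of s.d. ``psf_sigma`` centred at its exact (sub-pixel)
arclength position on its centerline; the hyphal tube itself contributes
a weak autofluorescence so profiles resemble real cells.  Centerlines are
emitted tip-end first, which is the convention every downstream module
assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .config import ImagingConfig
from .simulate import HyphaGroundTruth

__all__ = ["RenderedHypha", "render_frames", "CHANNELS"]

CHANNELS = ("fros", "parb", "replisome")

_MARGIN_PX = 12


@dataclass
class RenderedHypha:
    """Image stacks plus per-frame, per-region centerlines for one hypha."""

    hypha_id: int
    stacks: Dict[str, np.ndarray]  # channel -> (n_frames, ny, nx) uint16
    #: region_id -> frame -> (n_points, 2) float array of (x, y) px, tip first
    centerlines: Dict[str, Dict[int, np.ndarray]]
    imaging: ImagingConfig


def _stem_centerline(length_um: float, px: float, x_base: float, y0: float) -> np.ndarray:
    """Straight stem: tip at ``x_base + L/px`` running back to the base."""
    n_px = length_um / px
    s = np.arange(0.0, n_px, 1.0)
    if len(s) == 0 or s[-1] < n_px:
        s = np.append(s, n_px)
    x = x_base + n_px - s
    y = np.full_like(x, y0)
    return np.column_stack([x, y])


def _branch_centerline(length_um: float, px: float, x_att: float, y0: float) -> np.ndarray:
    """Branch at 45 degrees, tip first, ending at the stem attachment."""
    n_px = length_um / px
    s = np.arange(0.0, n_px, 1.0)
    if len(s) == 0 or s[-1] < n_px:
        s = np.append(s, n_px)
    u = (n_px - s) / math.sqrt(2.0)
    return np.column_stack([x_att + u, y0 - u])


def _frame_geometry(truth: HyphaGroundTruth, imaging: ImagingConfig):
    """Image size and stem anchor chosen from the final-frame extents."""
    px = imaging.pixel_size
    L_max = float(truth.lengths[-1])
    x_base = float(_MARGIN_PX)
    x_reach = x_base + L_max / px
    branch_rise = 0.0
    for b in truth.branches:
        final = np.nanmax(b.lengths) if np.any(~np.isnan(b.lengths)) else 0.0
        run = final / px / math.sqrt(2.0)  # 45-degree branches
        branch_rise = max(branch_rise, run)
        x_reach = max(x_reach, x_base + b.stem_position_um / px + run)
    nx = int(math.ceil(x_reach)) + _MARGIN_PX
    y0 = float(_MARGIN_PX + int(math.ceil(branch_rise)))
    ny = int(y0) + _MARGIN_PX
    return nx, ny, x_base, y0


def _point_at_arclength(line: np.ndarray, s_px: float) -> np.ndarray:
    """Point at arclength ``s_px`` (pixels) from the tip end of a polyline."""
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = min(max(s_px, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg) - 1) if len(seg) else 0
    if len(seg) == 0:
        return line[0]
    frac = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    return line[i] + frac * (line[i + 1] - line[i])


def _stamp_gaussian(img: np.ndarray, x: float, y: float, amp: float, sigma_px: float) -> None:
    r = max(int(math.ceil(4.0 * sigma_px)), 2)
    x0, x1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
    y0, y1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, img.shape[1])
    y0c, y1c = max(y0, 0), min(y1, img.shape[0])
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    gx = np.exp(-0.5 * ((xs - x) / sigma_px) ** 2)
    gy = np.exp(-0.5 * ((ys - y) / sigma_px) ** 2)
    img[y0c:y1c, x0c:x1c] += amp * np.outer(gy, gx)


def _stamp_tube(img: np.ndarray, line: np.ndarray, radius_px: float, intensity: float) -> None:
    """Draw a tube by stamping discs along the polyline (1 px spacing)."""
    if intensity <= 0:
        return
    ny, nx = img.shape
    r = int(math.ceil(radius_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disc = (xx ** 2 + yy ** 2) <= radius_px ** 2
    mask = np.zeros_like(img, dtype=bool)
    for p in line:
        cx, cy = int(round(p[0])), int(round(p[1]))
        x0, x1 = cx - r, cx + r + 1
        y0, y1 = cy - r, cy + r + 1
        if x0 < 0 or y0 < 0 or x1 > nx or y1 > ny:
            continue
        mask[y0:y1, x0:x1] |= disc
    img[mask] += intensity


def render_frames(truth: HyphaGroundTruth, imaging: ImagingConfig, seed: int) -> RenderedHypha:
    """Render every frame and channel of one simulated hypha.

    Deterministic given ``seed``; the three channels use independent
    noise streams derived from ``(seed, hypha_id, channel_index)``.
    """
    px = imaging.pixel_size
    n_frames = len(truth.lengths)
    nx, ny, x_base, y0 = _frame_geometry(truth, imaging)
    sigma_px = imaging.psf_sigma / px
    radius = imaging.hypha_width / 2.0

    # -- centerlines (shared across channels) -----------------------------
    centerlines: Dict[str, Dict[int, np.ndarray]] = {"stem": {}}
    for t in range(n_frames):
        centerlines["stem"][t] = _stem_centerline(float(truth.lengths[t]), px, x_base, y0)
    for b in truth.branches:
        region = f"branch_{b.branch_id}"
        centerlines[region] = {}
        x_att = x_base + b.stem_position_um / px
        for t in range(b.emergence_frame, n_frames):
            lb = b.lengths[t]
            if np.isnan(lb):
                continue
            centerlines[region][t] = _branch_centerline(float(lb), px, x_att, y0)

    # -- per-frame focus lists per channel ---------------------------------
    truth_table = truth.to_table()
    foci_by = {
        ch: {t: [] for t in range(n_frames)} for ch in CHANNELS
    }  # channel -> frame -> [(region, arclength_um)]
    for row in truth_table.itertuples(index=False):
        foci_by[row.channel][row.frame].append((row.region_id, row.arclength_um))

    stacks: Dict[str, np.ndarray] = {}
    for c_i, channel in enumerate(CHANNELS):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, int(truth.hypha_id), c_i])
        amp = float(imaging.spot_amplitude.get(channel, 0.0))
        stack = np.empty((n_frames, ny, nx), dtype=np.uint16)
        for t in range(n_frames):
            img = np.zeros((ny, nx), dtype=float)
            for region, frames in centerlines.items():
                if t in frames:
                    _stamp_tube(img, frames[t], radius, imaging.tube_intensity)
            for region, s_um in foci_by[channel][t]:
                line = centerlines.get(region, {}).get(t)
                if line is None:
                    continue
                seg = np.linalg.norm(np.diff(line, axis=0), axis=1).sum()
                if s_um / px > seg + 1.0:
                    raise ValueError(
                        f"focus at {s_um:.2f} um beyond region {region!r} "
                        f"length at frame {t}"
                    )
                p = _point_at_arclength(line, s_um / px)
                _stamp_gaussian(img, p[0], p[1], amp, sigma_px)
            img += imaging.background_level
            if imaging.poisson_noise:
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if imaging.read_noise_sd > 0:
                img += rng.normal(0.0, imaging.read_noise_sd, size=img.shape)
            stack[t] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        stacks[channel] = stack

    return RenderedHypha(truth.hypha_id, stacks, centerlines, imaging)
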