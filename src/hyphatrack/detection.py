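"""Focus detection on intensity profiles.

Detection follows the classic spectroscopy recipe: smooth the profile
with a Markov-chain (stationary-vector) smoother, take local maxima of
the smoothed curve, discard maxima whose raw intensity falls below a
threshold (by default half of the brightest signal in the profile), merge
maxima closer than a minimum separation, and refine positions to
sub-pixel precision by three-point parabolic interpolation on the raw
profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks
from scipy.special import logsumexp

from .config import DetectionConfig
from .profiles import IntensityProfile

__all__ = ["Focus", "markov_smooth", "detect_foci", "resolve_doublet"]


@dataclass
class Focus:
    """A detected intensity maximum on one profile."""

    hypha_id: int
    frame: int
    channel: str
    position: float  # µm from tip
    amplitude: float  # raw background-subtracted intensity at the peak
    region_id: str = "stem"
    width_estimate: Optional[float] = None


def markov_smooth(profile: IntensityProfile, window: int = 3) -> IntensityProfile:
    """Markov-chain smoothing of an intensity profile.

    Adjacent arclength bins are treated as states of a birth/death Markov
    chain whose forward/backward transition weights compare the bin
    intensity with its neighbours up to ``window`` bins away, each
    comparison contributing ``exp((I_far - I_near) / sqrt(I_far +
    I_near))`` (intensities regularized by +1 so empty bins are valid).
    The smoothed profile is the stationary vector of this chain, computed
    by the standard product-of-ratios recurrence in log space and
    rescaled so its maximum equals the input maximum.
    """
    y = np.asarray(profile.intensity, dtype=float)
    n = len(y)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window >= n:
        raise ValueError("window must be smaller than the profile length")
    if np.all(y <= 0):
        raise ValueError("empty profile: no positive intensities")
    z = y - min(float(y.min()), 0.0) + 1.0  # +1 regularization, nonnegative

    i = np.arange(n - 1)
    fwd_terms = np.empty((window, n - 1))
    bwd_terms = np.empty((window, n - 1))
    for l in range(1, window + 1):
        a_fwd = z[np.minimum(i + l, n - 1)]
        fwd_terms[l - 1] = (a_fwd - z[i]) / np.sqrt(a_fwd + z[i])
        a_bwd = z[np.maximum(i - l + 1, 0)]
        bwd_terms[l - 1] = (a_bwd - z[i + 1]) / np.sqrt(a_bwd + z[i + 1])
    log_ratio = logsumexp(fwd_terms, axis=0) - logsumexp(bwd_terms, axis=0)
    log_pi = np.concatenate([[0.0], np.cumsum(log_ratio)])
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    pi *= float(y.max()) / float(pi.max())
    return profile.copy_with(pi)


def _merge_close(
    indices: np.ndarray, amplitudes: np.ndarray, positions: np.ndarray, min_separation: float
) -> List[int]:
    """Greedy merge: among maxima closer than ``min_separation`` keep the higher."""
    order = np.argsort(-amplitudes, kind="stable")  # strongest first
    kept: List[int] = []
    for k in order:
        if all(abs(positions[k] - positions[j]) >= min_separation for j in kept):
            kept.append(k)
    kept.sort(key=lambda k: positions[k])
    return kept


def _parabolic_refine(y: np.ndarray, i: int, grid: np.ndarray) -> Tuple[float, float]:
    """Sub-pixel peak position/height by a parabola through 3 raw samples."""
    if i <= 0 or i >= len(y) - 1:
        return float(grid[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(grid[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = grid[1] - grid[0] if len(grid) > 1 else 1.0
    height = y1 - 0.25 * (y0 - y2) * delta
    return float(grid[i] + delta * step), float(height)


def detect_foci(
    profile: IntensityProfile,
    cfg: Optional[DetectionConfig] = None,
    *,
    reference_max: Optional[float] = None,
) -> List[Focus]:
    """Detect foci on a background-subtracted profile.

    Parameters
    ----------
    reference_max
        Intensity used as the 100% reference for the fractional
        threshold.  Defaults to the profile's own maximum; for the
        per-hypha rule pass the maximum over all frames of the hypha.

    Returns foci sorted tip-proximal first.  An all-zero profile yields
    an empty list rather than an error.
    """
    cfg = cfg or DetectionConfig()
    y = np.asarray(profile.intensity, dtype=float)
    if len(y) <= max(2, cfg.smoothing_window) or np.all(y <= 0):
        return []
    smoothed = markov_smooth(profile, cfg.smoothing_window).intensity
    # zero-pad so a focus at the profile end (e.g. right at the tip) still
    # registers as a maximum; background-subtracted profiles decay to ~0
    cand, _ = find_peaks(np.concatenate([[0.0], smoothed, [0.0]]))
    cand = cand - 1
    if len(cand) == 0:
        return []
    if cfg.threshold_mode == "fraction_of_max":
        ref = float(y.max()) if reference_max is None else float(reference_max)
        threshold = cfg.threshold_value * ref
    else:
        threshold = float(cfg.threshold_value)
    if cfg.noise_floor_sigmas > 0 and len(y) > 1:
        # robust noise scale from successive differences (median-based, so
        # insensitive to sparse peaks; 0 on noiseless flat-background profiles)
        sigma = 1.4826 * float(np.median(np.abs(np.diff(y)))) / np.sqrt(2.0)
        threshold = max(threshold, cfg.noise_floor_sigmas * sigma)

    # snap each smoothed maximum to the nearest raw local maximum (+/- 1 bin)
    raw_idx = []
    for i in cand:
        lo, hi = max(i - 1, 0), min(i + 2, len(y))
        raw_idx.append(lo + int(np.argmax(y[lo:hi])))
    raw_idx = np.asarray(sorted(set(raw_idx)))
    amps = y[raw_idx]
    keepmask = amps > threshold
    raw_idx, amps = raw_idx[keepmask], amps[keepmask]
    if len(raw_idx) == 0:
        return []
    positions = profile.arclength[raw_idx]
    kept = _merge_close(raw_idx, amps, positions, cfg.min_separation)

    foci = []
    for k in kept:
        pos, height = _parabolic_refine(y, int(raw_idx[k]), profile.arclength)
        foci.append(
            Focus(
                hypha_id=profile.hypha_id,
                frame=profile.frame,
                channel=profile.channel,
                position=pos,
                amplitude=height,
                region_id=profile.region_id,
            )
        )
    foci.sort(key=lambda f: f.position)
    return foci


def resolve_doublet(
    profile: IntensityProfile,
    region: Tuple[float, float],
    cfg: Optional[DetectionConfig] = None,
) -> List[Focus]:
    """Decide whether an arclength interval holds one focus or two.

    Two foci are returned iff the smoothed profile restricted to the
    region has two local maxima at least ``min_separation`` apart with an
    intervening minimum at least ``dip_fraction`` below the lower
    maximum; otherwise a single focus at the region maximum.
    """
    cfg = cfg or DetectionConfig()
    lo, hi = region
    mask = (profile.arclength >= lo) & (profile.arclength <= hi)
    if mask.sum() < 3:
        raise ValueError("degenerate region: fewer than 3 samples")
    sub = IntensityProfile(
        arclength=profile.arclength[mask] - profile.arclength[mask][0],
        intensity=profile.intensity[mask],
        frame=profile.frame,
        channel=profile.channel,
        hypha_id=profile.hypha_id,
        region_id=profile.region_id,
    )
    offset = profile.arclength[mask][0]
    y = sub.intensity
    smoothed = markov_smooth(sub, cfg.smoothing_window).intensity if np.any(y > 0) else y

    def _single() -> List[Focus]:
        i = int(np.argmax(y))
        pos, height = _parabolic_refine(y, i, sub.arclength)
        return [
            Focus(profile.hypha_id, profile.frame, profile.channel,
                  pos + offset, height, profile.region_id)
        ]

    cand, _ = find_peaks(smoothed)
    if len(cand) < 2:
        return _single()
    # two strongest smoothed maxima, tip-proximal first
    top2 = cand[np.argsort(-smoothed[cand], kind="stable")[:2]]
    i1, i2 = int(min(top2)), int(max(top2))
    sep = sub.arclength[i2] - sub.arclength[i1]
    valley = float(np.min(smoothed[i1:i2 + 1]))
    lower = min(smoothed[i1], smoothed[i2])
    if sep >= cfg.min_separation and valley <= (1.0 - cfg.dip_fraction) * lower:
        out = []
        for i in (i1, i2):
            lo_i, hi_i = max(i - 1, 0), min(i + 2, len(y))
            j = lo_i + int(np.argmax(y[lo_i:hi_i]))
            pos, height = _parabolic_refine(y, j, sub.arclength)
            out.append(
                Focus(profile.hypha_id, profile.frame, profile.channel,
                      pos + offset, height, profile.region_id)
            )
        return out
    return _single()
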