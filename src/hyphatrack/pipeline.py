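"""End-to-end pipeline: images + centerlines -> foci -> tracks -> statistics.

Stages are plain functions over DataFrames so each can be re-run from the
saved intermediate of the previous one:

* :func:`detect_stage` — profiles and focus detection for every
  (hypha, frame, region, channel);
* :func:`track_stage` — linking, tip indices, duplications, replisome
  association and branch scoring;
* :func:`stats_stage` — the population-level statistics.

:func:`run_pipeline` composes the three and writes CSV tables plus a
JSON stats report; outputs are a pure function of (inputs, config,
seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError, DetectionConfig, timelapse_detection_config
from .datasets import read_centerlines, read_manifest, read_stack
from .detection import Focus, detect_foci
from .profiles import Centerline, extract_profile, subtract_background
from .stats import (
    colocalization_fraction,
    correlation_by_index,
    compute_velocity_pairs,
    duplication_fraction_timecourse,
    tip_distance_summary,
)
from .tracking import (
    BranchRecord,
    DuplicationEvent,
    FocusTrack,
    assign_tip_indices,
    associate_replisome,
    detect_duplications,
    link_tracks,
    score_branch_population,
)

logger = logging.getLogger("hyphatrack")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "validate_inputs",
    "detect_stage",
    "track_stage",
    "stats_stage",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    data_dir: str
    out_dir: str
    detection: DetectionConfig = field(default_factory=timelapse_detection_config)
    gate: float = 1.5
    assoc_radius: float = 1.5
    channels: Dict[str, str] = field(
        default_factory=lambda: {"fros": "fros", "parb": "parb", "replisome": "replisome"}
    )
    pixel_size: Optional[float] = None  # µm/px; default from manifest
    frame_interval: Optional[float] = None  # minutes; default from manifest
    half_width: int = 2
    coloc_cutoff: float = 1.0
    stall_min_minutes: float = 60.0
    stall_tol: float = 0.2
    time_bins: Sequence[float] = (10.0, 20.0, 30.0, 40.0)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        labels = list(self.channels.values())
        if len(set(labels)) != len(labels):
            raise ConfigurationError("channel labels must be unique")

    def config_hash(self) -> str:
        # analysis parameters only: paths and logging do not affect results
        payload = {
            k: v for k, v in self.__dict__.items()
            if k not in ("data_dir", "out_dir", "log_level")
        }
        payload["detection"] = self.detection.to_dict()
        payload["time_bins"] = list(self.time_bins)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    foci: pd.DataFrame
    tracks: pd.DataFrame
    events: pd.DataFrame
    branches: pd.DataFrame
    stats: dict
    track_objects: Dict[tuple, List[FocusTrack]] = field(default_factory=dict)
    event_objects: Dict[int, List[DuplicationEvent]] = field(default_factory=dict)
    branch_objects: List[BranchRecord] = field(default_factory=list)
    lengths: Dict[int, Dict[int, float]] = field(default_factory=dict)


def validate_inputs(data_dir) -> pd.DataFrame:
    """Check readability and consistency of a dataset; one row per hypha."""
    data_dir = Path(data_dir)
    rows = []
    try:
        manifest = read_manifest(data_dir)
    except FileNotFoundError:
        return pd.DataFrame(
            [{"hypha": -1, "ok": False, "problems": "manifest.json missing"}]
        )
    for hid in manifest["hyphae"]:
        problems: List[str] = []
        stacks = {}
        for channel in manifest["channels"]:
            try:
                stacks[channel] = read_stack(data_dir, hid, channel)
            except Exception as exc:  # noqa: BLE001 - report, don't raise
                problems.append(f"unreadable stack {channel}: {exc}")
        try:
            centerlines = read_centerlines(data_dir, hid)
        except Exception as exc:  # noqa: BLE001
            problems.append(f"unreadable centerlines: {exc}")
            centerlines = {}
        if stacks and centerlines:
            n_frames = {ch: s.shape[0] for ch, s in stacks.items()}
            if len(set(n_frames.values())) > 1:
                problems.append(f"channel frame counts differ: {n_frames}")
            nf = max(n_frames.values())
            stem = centerlines.get("stem", {})
            missing = [t for t in range(nf) if t not in stem]
            if missing:
                problems.append(f"stem centerline missing for frames {missing[:5]}")
            for region, frames in centerlines.items():
                for frame, pts in frames.items():
                    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                    if np.any(seg <= 0):
                        bad = int(np.argmax(seg <= 0))
                        problems.append(
                            f"duplicate centerline point {region}/frame {frame} index {bad}"
                        )
        px = (manifest.get("imaging") or {}).get("pixel_size")
        if px is None:
            problems.append("pixel_size missing from manifest")
        rows.append({"hypha": hid, "ok": not problems, "problems": "; ".join(problems)})
    return pd.DataFrame(rows)


def detect_stage(cfg: PipelineConfig) -> pd.DataFrame:
    """Extract profiles and detect foci for the whole dataset."""
    data_dir = Path(cfg.data_dir)
    manifest = read_manifest(data_dir)
    px = cfg.pixel_size or (manifest.get("imaging") or {}).get("pixel_size")
    if px is None:
        raise ConfigurationError("pixel_size not given and absent from manifest")
    missing = [c for c in cfg.channels.values() if c not in manifest["channels"]]
    if missing:
        raise ConfigurationError(f"channels missing from dataset: {missing}")
    rows = []
    for hid in manifest["hyphae"]:
        centerlines = read_centerlines(data_dir, hid)
        for role, channel in cfg.channels.items():
            stack = read_stack(data_dir, hid, channel)
            profiles = []
            for region, frames in sorted(centerlines.items()):
                for frame in sorted(frames):
                    pts = frames[frame]
                    if len(pts) < 2 or frame >= stack.shape[0]:
                        continue
                    cl = Centerline(frame=frame, points=pts, pixel_size=px)
                    profile = extract_profile(
                        stack[frame], cl, half_width=cfg.half_width,
                        channel=role, hypha_id=hid, region_id=region,
                    )
                    profiles.append(subtract_background(profile))
            if not profiles:
                continue
            # "highest signal in the particular hypha": the fractional
            # threshold references the hypha-wide maximum of this channel
            hypha_max = max(float(p.intensity.max()) for p in profiles)
            for profile in profiles:
                    region = profile.region_id
                    frame = profile.frame
                    if len(profile.intensity) < 3 or np.all(profile.intensity <= 0):
                        continue
                    for focus in detect_foci(profile, cfg.detection,
                                             reference_max=hypha_max):
                        rows.append(
                            {
                                "hypha": hid,
                                "frame": frame,
                                "region_id": region,
                                "channel": role,
                                "position_um": focus.position,
                                "amplitude": focus.amplitude,
                            }
                        )
        logger.info("hypha %d: %d foci", hid, sum(1 for r in rows if r["hypha"] == hid))
    return pd.DataFrame(
        rows, columns=["hypha", "frame", "region_id", "channel", "position_um", "amplitude"]
    )


def _region_lengths(data_dir, manifest, px) -> Dict[int, Dict[str, Dict[int, float]]]:
    """Arclength (µm) of every centerline: hypha -> region -> frame -> length."""
    out: Dict[int, Dict[str, Dict[int, float]]] = {}
    for hid in manifest["hyphae"]:
        centerlines = read_centerlines(data_dir, hid)
        out[hid] = {}
        for region, frames in centerlines.items():
            out[hid][region] = {}
            for frame, pts in frames.items():
                seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                out[hid][region][frame] = float(seg.sum() * px)
    return out


def track_stage(cfg: PipelineConfig, foci: pd.DataFrame):
    """Link foci, index, and derive duplication events and branch records."""
    data_dir = Path(cfg.data_dir)
    manifest = read_manifest(data_dir)
    px = cfg.pixel_size or (manifest.get("imaging") or {}).get("pixel_size")
    interval = cfg.frame_interval or (manifest.get("config") or {}).get("frame_interval", 10.0)
    lengths_all = _region_lengths(data_dir, manifest, px)

    track_objects: Dict[tuple, List[FocusTrack]] = {}
    event_objects: Dict[int, List[DuplicationEvent]] = {}
    branch_objects: List[BranchRecord] = []
    next_track_id = 0
    for hid in manifest["hyphae"]:
        regions = lengths_all.get(hid, {})
        for region in sorted(regions):
            for role in cfg.channels:
                sel = foci[
                    (foci["hypha"] == hid)
                    & (foci["region_id"] == region)
                    & (foci["channel"] == role)
                ]
                by_frame: Dict[int, List[Focus]] = {}
                for row in sel.itertuples(index=False):
                    by_frame.setdefault(int(row.frame), []).append(
                        Focus(hid, int(row.frame), role, float(row.position_um),
                              float(row.amplitude), region)
                    )
                tracks = link_tracks(
                    by_frame, gate=cfg.gate,
                    min_persistence_frames=cfg.detection.min_persistence_frames,
                    start_track_id=next_track_id,
                )
                if tracks:
                    next_track_id = max(t.track_id for t in tracks) + 1
                assign_tip_indices(tracks)
                track_objects[(hid, region, role)] = tracks

        # duplications on the stem FROS channel
        fros_tracks = track_objects.get((hid, "stem", "fros"), [])
        events = detect_duplications(
            fros_tracks, assoc_radius=cfg.assoc_radius,
            min_persistence_frames=cfg.detection.min_persistence_frames,
            frame_interval=interval,
        )
        rep_tracks = track_objects.get((hid, "stem", "replisome"), [])
        associate_replisome(events, rep_tracks, radius=cfg.assoc_radius,
                            frame_interval=interval)
        event_objects[hid] = events

        for region in sorted(regions):
            if not region.startswith("branch"):
                continue
            frames = regions[region]
            try:
                branch_id = int(region.split("_", 1)[1])
            except (IndexError, ValueError):
                branch_id = -1
            record = BranchRecord(
                branch_id=branch_id,
                hypha_id=hid,
                emergence_frame=min(frames),
                lengths={int(f): v for f, v in frames.items()},
            )
            score_branch_population(
                record,
                track_objects.get((hid, region, "fros"), []),
                stem_events=events,
                frame_interval=interval,
                stall_min_minutes=cfg.stall_min_minutes,
                stall_tol=cfg.stall_tol,
            )
            branch_objects.append(record)
        logger.info(
            "hypha %d: %d stem tracks, %d duplications", hid,
            len(fros_tracks), len(events),
        )

    stem_lengths = {
        hid: lengths_all[hid].get("stem", {}) for hid in manifest["hyphae"]
    }
    return track_objects, event_objects, branch_objects, stem_lengths


def stats_stage(
    cfg: PipelineConfig,
    track_objects: Dict[tuple, List[FocusTrack]],
    event_objects: Dict[int, List[DuplicationEvent]],
    branch_objects: List[BranchRecord],
    stem_lengths: Dict[int, Dict[int, float]],
    foci: pd.DataFrame,
) -> dict:
    """Population-level statistics over all hyphae."""
    manifest = read_manifest(Path(cfg.data_dir))
    interval = cfg.frame_interval or (manifest.get("config") or {}).get("frame_interval", 10.0)
    stats: dict = {}
    fros_tracks = [
        t for (hid, region, role), ts in track_objects.items()
        if region == "stem" and role == "fros" for t in ts
    ]
    try:
        summary = tip_distance_summary(fros_tracks, tip_index=1)
        stats["oric1_tip_distance"] = {
            "mean_um": summary["mean"], "sd_um": summary["sd"], "n": summary["n"],
        }
    except ValueError as exc:
        stats["oric1_tip_distance"] = {"error": str(exc)}

    pairs = compute_velocity_pairs(fros_tracks, stem_lengths)
    corr = correlation_by_index(pairs)
    stats["correlation_by_index"] = {
        str(idx): {
            "r": res.estimate, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "n": res.n[0],
        }
        for idx, res in corr["per_index"].items()
    }
    stats["r_trend_slope"] = corr["r_trend_slope"]

    fros_foci = [
        Focus(int(r.hypha), int(r.frame), "fros", float(r.position_um),
              float(r.amplitude), str(r.region_id))
        for r in foci[foci["channel"] == "fros"].itertuples(index=False)
    ]
    parb_foci = [
        Focus(int(r.hypha), int(r.frame), "parb", float(r.position_um),
              float(r.amplitude), str(r.region_id))
        for r in foci[foci["channel"] == "parb"].itertuples(index=False)
    ]
    if fros_foci and parb_foci:
        stats["colocalization"] = colocalization_fraction(
            fros_foci, parb_foci, cutoff=cfg.coloc_cutoff
        )

    all_events = [e for es in event_objects.values() for e in es]
    hyphae_with_rep = sorted(
        hid for (hid, region, role), ts in track_objects.items()
        if region == "stem" and role == "replisome" and ts
    )
    if hyphae_with_rep:
        stats["duplication_timecourse"] = duplication_fraction_timecourse(
            all_events, len(hyphae_with_rep), cfg.time_bins,
            frame_interval=interval,
        )
    stats["n_duplications"] = len(all_events)
    lags = [e.lag_minutes for e in all_events if e.lag_minutes is not None]
    stats["mean_duplication_lag_minutes"] = float(np.mean(lags)) if lags else None

    if branch_objects:
        populated = [b for b in branch_objects if b.length_at_first_focus is not None]
        stats["branches"] = {
            "n": len(branch_objects),
            "n_populated": len(populated),
            "mean_length_at_first_focus_um": (
                float(np.mean([b.length_at_first_focus for b in populated]))
                if populated else None
            ),
            "n_stalled": sum(1 for b in branch_objects if b.stalled),
            "stalled_fraction": sum(1 for b in branch_objects if b.stalled)
            / len(branch_objects),
        }
    return stats


def _tables(track_objects, event_objects, branch_objects):
    track_rows = []
    for (hid, region, role), tracks in sorted(track_objects.items()):
        for t in tracks:
            for i, frame in enumerate(t.frames):
                track_rows.append(
                    {
                        "hypha": hid, "region_id": region, "channel": role,
                        "track_id": t.track_id, "frame": frame,
                        "position_um": t.positions[i], "amplitude": t.amplitudes[i],
                        "tip_index": t.tip_index.get(frame, -1),
                        "parent_track_id": -1 if t.parent_track_id is None else t.parent_track_id,
                    }
                )
    tracks_df = pd.DataFrame(
        track_rows,
        columns=["hypha", "region_id", "channel", "track_id", "frame",
                 "position_um", "amplitude", "tip_index", "parent_track_id"],
    )
    event_rows = []
    for hid, events in sorted(event_objects.items()):
        for e in events:
            event_rows.append(
                {
                    "hypha": hid, "split_frame": e.split_frame,
                    "parent_track_id": e.parent_track_id,
                    "daughter_proximal_id": e.daughter_proximal_id,
                    "daughter_distal_id": e.daughter_distal_id,
                    "replisome_track_id": -1 if e.replisome_track_id is None else e.replisome_track_id,
                    "replisome_appear_frame": -1 if e.replisome_appear_frame is None else e.replisome_appear_frame,
                    "lag_minutes": np.nan if e.lag_minutes is None else e.lag_minutes,
                }
            )
    events_df = pd.DataFrame(
        event_rows,
        columns=["hypha", "split_frame", "parent_track_id", "daughter_proximal_id",
                 "daughter_distal_id", "replisome_track_id", "replisome_appear_frame",
                 "lag_minutes"],
    )
    branch_rows = []
    for b in branch_objects:
        branch_rows.append(
            {
                "hypha": b.hypha_id, "branch_id": b.branch_id,
                "emergence_frame": b.emergence_frame,
                "first_focus_frame": -1 if b.first_focus_frame is None else b.first_focus_frame,
                "length_at_first_focus_um": (
                    np.nan if b.length_at_first_focus is None else b.length_at_first_focus
                ),
                "stalled": b.stalled,
                "stall_length_class": b.stall_length_class or "",
                "had_focus_when_stalled": b.had_focus_when_stalled,
                "duplication_in_stem_before": (
                    "" if b.duplication_in_stem_before is None
                    else str(bool(b.duplication_in_stem_before))
                ),
            }
        )
    branches_df = pd.DataFrame(
        branch_rows,
        columns=["hypha", "branch_id", "emergence_frame", "first_focus_frame",
                 "length_at_first_focus_um", "stalled", "stall_length_class",
                 "had_focus_when_stalled", "duplication_in_stem_before"],
    )
    return tracks_df, events_df, branches_df


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run detection, tracking and statistics; write all output tables."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    report = validate_inputs(cfg.data_dir)
    if report.empty or not report["ok"].any():
        raise ConfigurationError(
            f"no analyzable hyphae in {cfg.data_dir}: "
            + "; ".join(report["problems"].tolist())
        )
    foci = detect_stage(cfg)
    track_objects, event_objects, branch_objects, stem_lengths = track_stage(cfg, foci)
    stats = stats_stage(cfg, track_objects, event_objects, branch_objects,
                        stem_lengths, foci)
    tracks_df, events_df, branches_df = _tables(track_objects, event_objects, branch_objects)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_info = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    stats_out = {"run_info": run_info, "stats": stats}
    for name, df in [
        ("foci", foci), ("tracks", tracks_df), ("events", events_df),
        ("branches", branches_df),
    ]:
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# config_hash={run_info['config_hash']} seed={run_info['seed']}\n")
            df.to_csv(fh, index=False, float_format="%.6f")
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2, sort_keys=True, default=_json_default)
    _write_summary(out / "summary.txt", run_info, foci, tracks_df, events_df,
                   branches_df, stats)
    return PipelineResult(foci, tracks_df, events_df, branches_df, stats,
                          track_objects, event_objects, branch_objects, stem_lengths)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_summary(path, run_info, foci, tracks, events, branches, stats) -> None:
    lines = [
        f"hyphatrack run (config_hash={run_info['config_hash']}, seed={run_info['seed']})",
        f"foci detected:      {len(foci)}",
        f"track points:       {len(tracks)}",
        f"duplication events: {len(events)}",
        f"branches scored:    {len(branches)}",
    ]
    td = stats.get("oric1_tip_distance", {})
    if "mean_um" in td:
        lines.append(
            f"oriC1 tip distance: {td['mean_um']:.2f} +/- {td['sd_um']:.2f} um (n={td['n']})"
        )
    coloc = stats.get("colocalization")
    if coloc:
        lines.append(
            f"FROS/ParB colocalization: {100 * coloc['fraction']:.1f}% (n={coloc['n']})"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
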