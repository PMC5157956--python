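"""Ground-truth simulator for apically growing hyphae.

One hypha is a tube that elongates at its tip.  The tip-proximal
chromosome origin (oriC 1) is anchored: its distance to the tip follows a
discrete-time mean-reverting (AR(1)) process with a stationary mean
``anchor_offset`` and stationary s.d. ``anchor_sd``.  Trailing origins
are only partially coupled to tip displacement: origin ``j`` receives a
fraction ``coupling_base**j`` of each tip advance, so its tip distance
drifts backwards over time, the faster the larger ``j``.

Replication events insert a replisome next to a chosen origin; after the
scheduled duration the origin splits.  The tip-proximal daughter stays in
the anchored (or coupled) process of its parent, while the tip-distal
daughter co-moves with the replisome, which is stationary in the material
frame of the hypha (its tip distance grows with every tip advance).

Branch events spawn sub-hyphae on the stem; after ``populate_delay``
frames a chromosome focus enters the branch and becomes anchored to the
branch tip.  Stalling branches stop elongating a few frames after
emergence and never resume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig

__all__ = [
    "Event",
    "OriCTruth",
    "ReplisomeTruth",
    "BranchTruth",
    "HyphaGroundTruth",
    "simulate_hypha",
    "simulate_dataset",
]

#: extra frames a replisome remains visible after the focus split
_REPLISOME_LINGER = 6


@dataclass
class Event:
    type: str  # replisome_appear | oriC_split | branch_emerge | focus_enter_branch | stall
    frame: int
    payload: dict = field(default_factory=dict)


@dataclass
class OriCTruth:
    """One chromosome origin; ``positions[t]`` is µm from the tip (NaN before birth)."""

    object_id: int
    birth_frame: int
    parent_id: Optional[int]
    anchored: bool
    positions: np.ndarray
    replisome_id: Optional[int] = None

    def alive(self, frame: int) -> bool:
        return frame >= self.birth_frame


@dataclass
class ReplisomeTruth:
    object_id: int
    appear_frame: int
    disappear_frame: int  # exclusive
    positions: np.ndarray
    parent_id: Optional[int] = None
    split_frame: Optional[int] = None

    def alive(self, frame: int) -> bool:
        return self.appear_frame <= frame < self.disappear_frame


@dataclass
class BranchTruth:
    branch_id: int
    emergence_frame: int
    stem_position_um: float
    lengths: np.ndarray  # NaN before emergence
    populate_frame: Optional[int]
    focus_positions: np.ndarray  # arclength from branch tip; NaN where absent
    stalled: bool
    stall_frame: Optional[int]


@dataclass
class HyphaGroundTruth:
    """Simulator output for one hypha: the oracle the pipeline is scored against."""

    hypha_id: int
    config: SimulationConfig
    lengths: np.ndarray  # tip length L(t), µm
    oriCs: List[OriCTruth]
    replisomes: List[ReplisomeTruth]
    branches: List[BranchTruth]
    events: List[Event]

    # -- convenience views -------------------------------------------------
    def oric_positions(self, frame: int) -> np.ndarray:
        """Tip distances of stem origins alive at ``frame``, tip-ordered."""
        pos = [o.positions[frame] for o in self.oriCs if o.alive(frame)]
        return np.sort(np.asarray(pos))

    def to_table(self) -> pd.DataFrame:
        """Long-format ground truth: one row per (frame, object, channel).

        Chromosome origins appear in both the ``fros`` and ``parb``
        channels (a partition-protein focus forms on every origin);
        replisomes in the ``replisome`` channel.  Branch-resident foci
        carry the branch region id, stem objects ``region_id='stem'``.
        """
        rows = []
        for o in self.oriCs:
            for t in range(o.birth_frame, len(self.lengths)):
                for channel in ("fros", "parb"):
                    rows.append(
                        (self.hypha_id, t, o.object_id, channel, "stem", float(o.positions[t]))
                    )
        for r in self.replisomes:
            for t in range(r.appear_frame, r.disappear_frame):
                rows.append(
                    (self.hypha_id, t, r.object_id, "replisome", "stem", float(r.positions[t]))
                )
        for b in self.branches:
            if b.populate_frame is None:
                continue
            for t in range(b.populate_frame, len(self.lengths)):
                if np.isnan(b.focus_positions[t]):
                    continue
                oid = 10_000 + b.branch_id
                region = f"branch_{b.branch_id}"
                for channel in ("fros", "parb"):
                    rows.append(
                        (self.hypha_id, t, oid, channel, region, float(b.focus_positions[t]))
                    )
        return pd.DataFrame(
            rows,
            columns=["hypha", "frame", "object_id", "channel", "region_id", "arclength_um"],
        )


def _hypha_rng(config: SimulationConfig, hypha_id: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, int(hypha_id)])


def simulate_hypha(config: SimulationConfig, hypha_id: int) -> HyphaGroundTruth:
    """Simulate one hypha; deterministic given ``(config.seed, hypha_id)``."""
    config.validate()
    rng = _hypha_rng(config, hypha_id)
    n = config.n_frames

    # --- tip length -------------------------------------------------------
    v_h = config.extension_rate_mean + (
        rng.normal(0.0, config.extension_rate_sd) if config.extension_rate_sd > 0 else 0.0
    )
    v_h = max(v_h, 0.0)
    L = np.empty(n)
    L[0] = config.default_initial_length
    for t in range(1, n):
        eps = rng.normal(0.0, config.extension_noise_sd) if config.extension_noise_sd > 0 else 0.0
        L[t] = L[t - 1] + max(0.0, v_h + eps)
    dL = np.diff(L, prepend=L[0])  # dL[t] = L[t] - L[t-1], dL[0] = 0

    events: List[Event] = []
    oriCs: List[OriCTruth] = []
    replisomes: List[ReplisomeTruth] = []

    # --- initial chromosomes ---------------------------------------------
    kappa = config.anchor_relaxation
    sd_eta = config.anchor_sd * np.sqrt(1.0 - (1.0 - kappa) ** 2)

    def _anchor_step(d: float) -> float:
        eta = rng.normal(0.0, sd_eta) if sd_eta > 0 else 0.0
        return d + kappa * (config.anchor_offset - d) + eta

    d1_0 = config.anchor_offset + (rng.normal(0.0, config.anchor_sd) if config.anchor_sd > 0 else 0.0)
    first = OriCTruth(0, 0, None, True, np.full(n, np.nan))
    first.positions[0] = np.clip(d1_0, 0.1, L[0])
    oriCs.append(first)
    for j in range(2, config.n_chromosomes_initial + 1):
        o = OriCTruth(j - 1, 0, None, False, np.full(n, np.nan))
        o.positions[0] = min(config.anchor_offset + (j - 1) * config.initial_spacing, L[0])
        oriCs.append(o)

    schedule = {}
    for idx, start, duration in config.replication_schedule:
        schedule.setdefault(start, []).append((idx, duration))
    pending_splits = {}  # frame -> list of (parent OriCTruth, replisome)

    branch_specs = sorted(config.branch_schedule, key=lambda b: b[0])
    branches: List[BranchTruth] = []
    branch_rates: List[float] = []
    next_object_id = len(oriCs)

    def _tip_ordered_alive(frame: int) -> List[OriCTruth]:
        alive = [o for o in oriCs if o.alive(frame)]
        return sorted(alive, key=lambda o: o.positions[frame])

    # replisome appearances at frame 0
    def _fire_replisomes(t: int) -> None:
        nonlocal next_object_id
        for idx, duration in schedule.get(t, []):
            ordered = _tip_ordered_alive(t)
            if idx > len(ordered):
                raise ConfigurationError(
                    f"replication schedule references oriC index {idx}, "
                    f"only {len(ordered)} present at frame {t}"
                )
            parent = ordered[idx - 1]
            rep = ReplisomeTruth(
                next_object_id,
                t,
                min(n, t + duration + _REPLISOME_LINGER),
                np.full(n, np.nan),
                parent_id=parent.object_id,
                split_frame=t + duration,
            )
            next_object_id += 1
            rep.positions[t] = np.clip(
                parent.positions[t] + abs(rng.normal(0.0, config.replisome_jitter)),
                0.1,
                L[t],
            )
            replisomes.append(rep)
            events.append(
                Event("replisome_appear", t, dict(oriC_index=idx, parent_id=parent.object_id,
                                                  replisome_id=rep.object_id))
            )
            pending_splits.setdefault(t + duration, []).append((parent, rep))

    _fire_replisomes(0)

    for t in range(1, n):
        oric_by_id = {o.object_id: o for o in oriCs}
        # 1. origins governed by their own process (anchored / coupled)
        for o in oriCs:
            if not o.alive(t - 1) or o.replisome_id is not None:
                continue
            prev = o.positions[t - 1]
            if o.anchored:
                o.positions[t] = _anchor_step(prev)
            else:
                j = o.object_id + 1  # tip index at birth, 1-based
                c_j = config.coupling_base ** j
                eta = rng.normal(0.0, config.trailing_noise_sd) if config.trailing_noise_sd > 0 else 0.0
                o.positions[t] = prev + (1.0 - c_j) * dL[t] + eta
            o.positions[t] = np.clip(o.positions[t], 0.1, L[t])
        # 2. replisomes: co-localized with the replicating origin until the
        #    split, thereafter stationary in the material frame
        for r in replisomes:
            if not r.alive(t) or r.appear_frame >= t:
                continue
            jit = rng.normal(0.0, config.replisome_jitter) if config.replisome_jitter > 0 else 0.0
            if r.split_frame is not None and t < r.split_frame:
                # track the replicating origin (previous frame: origins with
                # their own replisome are propagated after this block)
                base = oric_by_id[r.parent_id].positions[t - 1] + abs(jit)
            else:
                base = r.positions[t - 1] + dL[t] + jit
            r.positions[t] = np.clip(base, 0.1, L[t])
        rep_by_id = {r.object_id: r for r in replisomes}
        # 3. tip-distal daughters co-move with their replisome
        for o in oriCs:
            if not o.alive(t - 1) or o.replisome_id is None:
                continue
            rep = rep_by_id[o.replisome_id]
            jit = rng.normal(0.0, config.replisome_jitter) if config.replisome_jitter > 0 else 0.0
            if rep.alive(t):
                o.positions[t] = rep.positions[t] + jit
            else:  # replisome gone: keep moving in the material frame
                o.positions[t] = o.positions[t - 1] + dL[t] + jit
            o.positions[t] = np.clip(o.positions[t], 0.1, L[t])

        # splits scheduled for this frame
        for parent, rep in pending_splits.get(t, []):
            daughter = OriCTruth(
                next_object_id, t, parent.object_id, False, np.full(n, np.nan),
                replisome_id=rep.object_id,
            )
            next_object_id += 1
            # the distal daughter is born on the replisome, which has just
            # dropped off the tip anchor; enforce a minimal resolvable offset
            daughter.positions[t] = np.clip(
                max(rep.positions[t],
                    parent.positions[t] + config.initial_split_separation),
                0.1,
                L[t],
            )
            oriCs.append(daughter)
            events.append(
                Event("oriC_split", t, dict(parent_id=parent.object_id,
                                            daughter_id=daughter.object_id,
                                            replisome_id=rep.object_id))
            )

        _fire_replisomes(t)

    # --- branches ---------------------------------------------------------
    for b_i, (fb, stem_pos, delay, stall) in enumerate(branch_specs):
        lengths = np.full(n, np.nan)
        lengths[fb] = 0.0
        v_b = max(
            config.branch_extension_factor
            * (config.extension_rate_mean
               + (rng.normal(0.0, config.extension_rate_sd) if config.extension_rate_sd > 0 else 0.0)),
            0.0,
        )
        stall_frame = fb + config.stall_growth_frames if stall else None
        for t in range(fb + 1, n):
            if stall and t > stall_frame:
                lengths[t] = lengths[t - 1]
            else:
                eps = rng.normal(0.0, config.extension_noise_sd) if config.extension_noise_sd > 0 else 0.0
                lengths[t] = lengths[t - 1] + max(0.0, v_b + eps)
        events.append(Event("branch_emerge", fb, dict(branch_id=b_i, stem_position_um=stem_pos)))
        if stall:
            events.append(Event("stall", stall_frame, dict(branch_id=b_i)))

        focus = np.full(n, np.nan)
        populate_frame: Optional[int] = None
        fp = fb + delay
        if fp < n and not np.isnan(lengths[fp]):
            populate_frame = fp
            d = float(min(lengths[fp], config.anchor_offset))
            focus[fp] = max(d, 0.0)
            for t in range(fp + 1, n):
                focus[t] = float(np.clip(_anchor_step(focus[t - 1]), 0.0, lengths[t]))
            events.append(Event("focus_enter_branch", fp, dict(branch_id=b_i)))
        branches.append(
            BranchTruth(b_i, fb, float(stem_pos), lengths, populate_frame, focus,
                        bool(stall), stall_frame)
        )
        branch_rates.append(v_b)

    truth = HyphaGroundTruth(hypha_id, config, L, oriCs, replisomes, branches, events)
    _check_invariants(truth)
    return truth


def _check_invariants(truth: HyphaGroundTruth) -> None:
    L = truth.lengths
    if np.any(np.diff(L) < -1e-9):
        raise AssertionError("hypha length decreased")  # pragma: no cover
    for o in truth.oriCs:
        p = o.positions[o.birth_frame:]
        if np.any(np.isnan(p)):
            raise AssertionError("NaN position after birth")  # pragma: no cover
        if np.any(p < 0) or np.any(p > L[o.birth_frame:] + 1e-9):
            raise AssertionError("oriC position outside hypha")  # pragma: no cover


def simulate_dataset(config: SimulationConfig) -> List[HyphaGroundTruth]:
    """Simulate ``config.n_hyphae`` independent hyphae."""
    return [simulate_hypha(config, h) for h in range(config.n_hyphae)]


def ground_truth_tracks(truths):
    """Noise-free tracks straight from simulator truth (stem FROS channel).

    Bypasses rendering and detection: one track per chromosome origin
    with tip indices assigned per frame.  Returns ``(tracks,
    tip_lengths)`` in the same shapes the tracking/statistics layers use,
    so simulated dynamics can feed the statistics directly.
    """
    from .tracking import FocusTrack, assign_tip_indices

    tracks = []
    lengths = {}
    for truth in truths:
        lengths[truth.hypha_id] = {
            t: float(truth.lengths[t]) for t in range(len(truth.lengths))
        }
        per_hypha = []
        for o in truth.oriCs:
            frames = list(range(o.birth_frame, len(truth.lengths)))
            per_hypha.append(
                FocusTrack(
                    track_id=len(tracks) + len(per_hypha),
                    channel="fros",
                    frames=frames,
                    positions=[float(o.positions[f]) for f in frames],
                    amplitudes=[1.0] * len(frames),
                    hypha_id=truth.hypha_id,
                    parent_track_id=o.parent_id,
                )
            )
        assign_tip_indices(per_hypha)
        tracks.extend(per_hypha)
    return tracks, lengths
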