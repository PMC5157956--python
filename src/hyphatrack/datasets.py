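"""On-disk layout for simulated datasets.

```
out_dir/
  manifest.json                 # config, imaging, seed, hypha ids
  hypha_000/
    fros.tif parb.tif replisome.tif    # (n_frames, ny, nx) uint16 stacks
    centerlines.csv             # region_id, frame, point_index, x_px, y_px
    truth.csv                   # hypha, frame, object_id, channel, region_id, arclength_um
```

Centerline points are ordered tip-end first.  Floats are written with a
fixed decimal format so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import ImagingConfig, SimulationConfig
from .render import CHANNELS, RenderedHypha
from .simulate import HyphaGroundTruth

__all__ = ["write_dataset", "read_manifest", "read_centerlines", "read_stack", "read_truth"]

_FLOAT_FMT = "%.6f"


def _hypha_dir(out_dir: Path, hypha_id: int) -> Path:
    return Path(out_dir) / f"hypha_{hypha_id:03d}"


def write_dataset(
    truths: Sequence[HyphaGroundTruth],
    rendered: Sequence[RenderedHypha],
    out_dir,
    config: Optional[SimulationConfig] = None,
    imaging: Optional[ImagingConfig] = None,
    seed: Optional[int] = None,
) -> Path:
    """Write TIFF stacks, centerline/truth CSVs and a JSON manifest."""
    if len(truths) != len(rendered):
        raise ValueError("truths and rendered stacks differ in length")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for truth, rh in zip(truths, rendered):
        if truth.hypha_id != rh.hypha_id:
            raise ValueError("truth/render hypha id mismatch")
        hdir = _hypha_dir(out, truth.hypha_id)
        hdir.mkdir(parents=True, exist_ok=True)
        for channel, stack in rh.stacks.items():
            tifffile.imwrite(hdir / f"{channel}.tif", stack, photometric="minisblack")
        rows = []
        for region, by_frame in sorted(rh.centerlines.items()):
            for frame in sorted(by_frame):
                pts = by_frame[frame]
                for i, (x, y) in enumerate(pts):
                    rows.append((region, frame, i, x, y))
        cl = pd.DataFrame(rows, columns=["region_id", "frame", "point_index", "x_px", "y_px"])
        cl.to_csv(hdir / "centerlines.csv", index=False, float_format=_FLOAT_FMT)
        truth.to_table().to_csv(hdir / "truth.csv", index=False, float_format=_FLOAT_FMT)

    manifest = {
        "hyphae": [t.hypha_id for t in truths],
        "channels": list(CHANNELS),
        "seed": seed,
        "config": config.to_dict() if config is not None else None,
        "imaging": imaging.to_dict() if imaging is not None else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def read_manifest(data_dir) -> dict:
    with open(Path(data_dir) / "manifest.json") as fh:
        return json.load(fh)


def read_stack(data_dir, hypha_id: int, channel: str) -> np.ndarray:
    path = _hypha_dir(Path(data_dir), hypha_id) / f"{channel}.tif"
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def read_centerlines(data_dir, hypha_id: int) -> Dict[str, Dict[int, np.ndarray]]:
    """``{region_id: {frame: (n, 2) float array}}``, tip-end first."""
    path = _hypha_dir(Path(data_dir), hypha_id) / "centerlines.csv"
    df = pd.read_csv(path)
    out: Dict[str, Dict[int, np.ndarray]] = {}
    for (region, frame), grp in df.groupby(["region_id", "frame"], sort=True):
        grp = grp.sort_values("point_index")
        out.setdefault(str(region), {})[int(frame)] = grp[["x_px", "y_px"]].to_numpy(float)
    return out


def read_truth(data_dir, hypha_id: int) -> pd.DataFrame:
    return pd.read_csv(_hypha_dir(Path(data_dir), hypha_id) / "truth.csv")
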