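"""File formats: NIfTI-1 images, CSV tables, YAML study designs.

Frame stacks are stored as NIfTI-1 with shape (x, y, 1, t) — float data for
expected counts, integers for Poisson counts — with the frame duration (s)
in the fourth pixel dimension.  ROI label maps are integer NIfTI-1 images
with a JSON legend mapping names to labels.  All tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import Arm, StudyDesign
from .errors import ParameterError
from .kinetics import FrameSchedule
from .phantom import FrameStack, ROISet
from .tac import TAC, Renogram

__all__ = [
    "write_frames",
    "read_frames",
    "write_roiset",
    "read_roiset",
    "tacs_to_frame",
    "write_tacs",
    "read_tacs",
    "design_to_yaml",
    "design_from_yaml",
]


def write_frames(stack: FrameStack, path: str | Path) -> None:
    """Save a dynamic acquisition as NIfTI-1 (x, y, 1, t)."""
    # counts are (t, y, x); NIfTI wants spatial-first
    data = np.transpose(stack.counts, (2, 1, 0))[:, :, None, :]
    if stack.noise == "poisson":
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, stack.schedule.frame_duration_s))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_frames(path: str | Path, noise: str | None = None) -> FrameStack:
    """Load a NIfTI-1 frame stack; schedule comes from shape and pixdim."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[2] != 1:
        raise ParameterError(
            f"expected a (x, y, 1, t) dynamic stack, got shape {data.shape}"
        )
    frame_s = float(img.header.get_zooms()[3]) or 1.0
    counts = np.transpose(data[:, :, 0, :], (2, 1, 0))
    if noise is None:
        noise = "poisson" if np.issubdtype(counts.dtype, np.integer) else "none"
    schedule = FrameSchedule(n_frames=counts.shape[0], frame_duration_s=frame_s)
    return FrameStack(counts.astype(float if noise == "none" else np.int64),
                      schedule, noise=noise)


def write_roiset(rois: ROISet, image_path: str | Path, legend_path: str | Path) -> None:
    img = nib.Nifti1Image(rois.labels.T[:, :, None].astype(np.int16), np.eye(4))
    nib.save(img, str(image_path))
    Path(legend_path).write_text(json.dumps(rois.legend, indent=2))


def read_roiset(image_path: str | Path, legend_path: str | Path) -> ROISet:
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[:, :, 0]
    legend = json.loads(Path(legend_path).read_text())
    return ROISet(labels=data.T.astype(np.int16), legend={k: int(v) for k, v in legend.items()})


def tacs_to_frame(
    tacs: dict[str, TAC] | list[TAC],
    mouse_id: str = "",
    renograms: dict[str, Renogram] | None = None,
) -> pd.DataFrame:
    """Long-format table: mouse_id, roi, t_min, rate_cps [, pct_ia]."""
    items = tacs.values() if isinstance(tacs, dict) else tacs
    frames = []
    for tac in items:
        df = pd.DataFrame(
            {
                "mouse_id": mouse_id,
                "roi": tac.roi_name,
                "t_min": tac.times_min,
                "rate_cps": tac.rate_cps,
            }
        )
        if renograms and tac.roi_name in renograms:
            df["pct_ia"] = renograms[tac.roi_name].pct_ia
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_tacs(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_tacs(path: str | Path) -> dict[str, TAC]:
    """Read a TAC table back into per-ROI curves (lossless for rates)."""
    df = pd.read_csv(path)
    out: dict[str, TAC] = {}
    for roi, sub in df.groupby("roi", sort=False):
        out[roi] = TAC(
            roi_name=str(roi),
            times_min=sub["t_min"].to_numpy(),
            rate_cps=sub["rate_cps"].to_numpy(),
            area_px=int(sub["area_px"].iloc[0]) if "area_px" in sub else 0,
        )
    return out


def design_to_yaml(design: StudyDesign, path: str | Path) -> None:
    doc = {
        "name": design.name,
        "baseline_group": design.baseline_group,
        "baseline_day": design.baseline_day,
        "arms": [
            {
                "name": a.name,
                "n_mice": a.n_mice,
                "sd": float(a.sd),
                "fur_mean_by_day": {int(d): float(v) for d, v in a.fur_mean_by_day.items()},
            }
            for a in design.arms
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def design_from_yaml(path: str | Path) -> StudyDesign:
    doc = yaml.safe_load(Path(path).read_text())
    arms = tuple(
        Arm(
            name=a["name"],
            n_mice=int(a["n_mice"]),
            sd=float(a["sd"]),
            fur_mean_by_day={int(d): float(v) for d, v in a["fur_mean_by_day"].items()},
        )
        for a in doc["arms"]
    )
    return StudyDesign(
        name=doc.get("name", Path(path).stem),
        arms=arms,
        baseline_group=doc.get("baseline_group", "baseline"),
        baseline_day=int(doc.get("baseline_day", 0)),
    )
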