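"""On-disk cohort layout: NIfTI cines and masks, JSON sidecars, CSV manifest.

Each subject-setpoint scan is stored as
  <subject>_<setpoint>_cine.nii   float32, (rows, cols, phases)
  <subject>_<setpoint>_mask.nii   uint8, (rows, cols)
  <subject>_<setpoint>_meta.json  rr_interval (s), pixel_spacing (cm),
                                  phase_times (s), sign convention
plus a cohort-level ``manifest.csv`` (subject_id, group, limb, setpoint and
the three relative paths) and a ``cohort.yaml`` config snapshot.
Uncompressed .nii keeps writes byte-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .qflow import ROIMask, VelocityCine

MANIFEST_COLUMNS = ["subject_id", "group", "limb", "setpoint",
                    "cine", "mask", "sidecar"]


@dataclass(eq=False)
class ScanRef:
    """Lazy handle on one stored scan; files are read only on load()."""

    subject_id: str
    group: str
    limb: str
    setpoint: str
    cine_path: Path
    mask_path: Path
    sidecar_path: Path
    cine: Optional[VelocityCine] = None  # duck-type parity with ScanRecord
    roi: Optional[ROIMask] = None

    def load(self) -> tuple[VelocityCine, ROIMask]:
        with open(self.sidecar_path) as fh:
            meta = json.load(fh)
        img = nib.load(self.cine_path)
        data = np.asarray(img.dataobj, dtype=float)  # (rows, cols, phases)
        cine = VelocityCine(
            data=np.moveaxis(data, -1, 0),
            phase_times=np.asarray(meta["phase_times"], dtype=float),
            rr_interval=float(meta["rr_interval"]),
            pixel_spacing=float(meta["pixel_spacing"]),
            sign_convention=meta.get("sign_convention",
                                     "toward-head-positive"))
        mask = np.asarray(nib.load(self.mask_path).dataobj) > 0
        roi = ROIMask(mask=mask, pixel_area=cine.pixel_area)
        return cine, roi


def _affine(pixel_spacing: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_spacing
    return aff


def save_cohort(cohort, out_dir) -> Path:
    """Write a rendered cohort to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.iter_records():
        if rec.cine is None:
            raise ValueError("cannot save a cohort generated with render=False")
        stem = f"{rec.subject_id}_{rec.setpoint}"
        cine_p, mask_p = f"{stem}_cine.nii", f"{stem}_mask.nii"
        side_p = f"{stem}_meta.json"
        aff = _affine(rec.cine.pixel_spacing)
        nib.save(nib.Nifti1Image(
            np.moveaxis(rec.cine.data, 0, -1).astype(np.float32), aff),
            out / cine_p)
        nib.save(nib.Nifti1Image(
            rec.roi.mask.astype(np.uint8), aff), out / mask_p)
        meta = {"rr_interval": rec.cine.rr_interval,
                "pixel_spacing": rec.cine.pixel_spacing,
                "phase_times": rec.cine.phase_times.tolist(),
                "sign_convention": rec.cine.sign_convention,
                "subject_id": rec.subject_id, "setpoint": rec.setpoint}
        with open(out / side_p, "w") as fh:
            json.dump(meta, fh, sort_keys=True, indent=2)
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "limb": rec.limb, "setpoint": rec.setpoint,
                     "cine": cine_p, "mask": mask_p, "sidecar": side_p})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    cohort.config.to_yaml(out / "cohort.yaml")
    return manifest


def load_cohort(manifest_path) -> list[ScanRef]:
    """Read a manifest CSV into lazy scan references."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    return [ScanRef(subject_id=r.subject_id, group=r.group, limb=r.limb,
                    setpoint=r.setpoint, cine_path=base / r.cine,
                    mask_path=base / r.mask, sidecar_path=base / r.sidecar)
            for r in df.itertuples()]


def labels_from_manifest(manifest_path) -> dict[str, int]:
    """Subject labels (reflux limb 1, control limb 0) from a manifest."""
    from .simulate import GROUP_REFLUX
    df = pd.read_csv(manifest_path)
    return {sid: int(grp == GROUP_REFLUX)
            for sid, grp in zip(df["subject_id"], df["group"])}
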