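"""File formats: TIFF frames/volumes, YAML geometry/calibration, CSV tables.

Generated artifacts are written next to their machine-readable ground-truth
tables so a directory is self-contained: frames as single-page 32-bit float
TIFFs plus ``truth.csv`` and ``geometry.yaml``; microCT volumes as multi-page
TIFF stacks; mechanical records as CSV with documented headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import AcquisitionGeometry
from .mechanics import MechanicalRecord
from .saxd import DetectorFrame
from .synth import MicroCTVolume, QbseImage, SaxdSequence

__all__ = [
    "write_saxd_sequence",
    "read_saxd_sequence",
    "write_mech_record",
    "read_mech_record",
    "write_qbse_image",
    "read_qbse_image",
    "write_microct_volume",
    "read_microct_volume",
]


def write_saxd_sequence(seq: SaxdSequence, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for frame in seq.frames:
        tifffile.imwrite(
            out / f"frame_{frame.frame_index:04d}.tif",
            frame.intensity.astype(np.float32),
        )
    seq.truth.to_csv(out / "truth.csv", index=False)
    seq.geometry.to_yaml(out / "geometry.yaml")
    return out


def read_saxd_sequence(in_dir: str | Path):
    """Load frames + geometry; attaches tissue strain from truth.csv if present.

    Returns (frames, geometry, truth_or_None).
    """
    src = Path(in_dir)
    geometry = AcquisitionGeometry.from_yaml(src / "geometry.yaml")
    truth = None
    truth_path = src / "truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
    frames = []
    for k, path in enumerate(sorted(src.glob("frame_*.tif"))):
        eps_t = float(truth.tissue_strain.iloc[k]) if truth is not None else np.nan
        frames.append(DetectorFrame(tifffile.imread(path), k, eps_t))
    return frames, geometry, truth


_MECH_COLUMNS = ["time_s", "load_n", "marker1_mm", "marker2_mm"]


def write_mech_record(
    record: MechanicalRecord, path: str | Path, truth: pd.DataFrame | None = None
) -> Path:
    """Mechanical record CSV: time_s, load_n, marker1_mm, marker2_mm.

    Cross-section and porosity go into a YAML sidecar ``<stem>.meta.yaml``;
    the ground-truth table (if given) into ``<stem>.truth.csv``.
    """
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": record.time,
            "load_n": record.load,
            "marker1_mm": record.marker_positions[:, 0],
            "marker2_mm": record.marker_positions[:, 1],
        }
    ).to_csv(path, index=False)
    meta = {
        "cross_section_mm": [float(record.cross_section[0]), float(record.cross_section[1])],
        "porosity": float(record.porosity),
    }
    with open(path.with_suffix(".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)
    if truth is not None:
        t = truth.copy()
        meta_truth = {k: float(v) for k, v in truth.attrs.items()}
        with open(path.with_suffix(".truth.yaml"), "w") as fh:
            yaml.safe_dump(meta_truth, fh)
        t.to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


def read_mech_record(path: str | Path) -> MechanicalRecord:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _MECH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mechanical record missing columns: {missing}")
    with open(path.with_suffix(".meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    return MechanicalRecord(
        time=df["time_s"].to_numpy(),
        load=df["load_n"].to_numpy(),
        marker_positions=df[["marker1_mm", "marker2_mm"]].to_numpy(),
        cross_section=tuple(meta["cross_section_mm"]),
        porosity=meta["porosity"],
    )


def write_qbse_image(img: QbseImage, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "image.tif", img.image)
    calib = {
        "gray_carbon": float(img.calibration.gray_carbon),
        "gray_aluminum": float(img.calibration.gray_aluminum),
        "ca_at_carbon": float(img.calibration.ca_at_carbon),
        "ca_at_aluminum": float(img.calibration.ca_at_aluminum),
        "pixel_size_um": float(img.pixel_size_um),
        "roi_centers": [[int(r), int(c)] for r, c in img.roi_centers],
        "patches": {
            name: [[sl[0].start, sl[0].stop], [sl[1].start, sl[1].stop]]
            for name, sl in img.patches.items()
        },
        "truth": {k: float(v) for k, v in img.truth.items()},
    }
    with open(out / "calibration.yaml", "w") as fh:
        yaml.safe_dump(calib, fh)
    return out


def read_qbse_image(in_dir: str | Path) -> QbseImage:
    from .qbse import GrayCalibration

    src = Path(in_dir)
    image = tifffile.imread(src / "image.tif")
    with open(src / "calibration.yaml") as fh:
        d = yaml.safe_load(fh)
    calibration = GrayCalibration(
        d["gray_carbon"], d["gray_aluminum"], d["ca_at_carbon"], d["ca_at_aluminum"]
    )
    patches = {
        name: (slice(r[0], r[1]), slice(c[0], c[1]))
        for name, (r, c) in d["patches"].items()
    }
    return QbseImage(
        image=image,
        calibration=calibration,
        patches=patches,
        roi_centers=[tuple(rc) for rc in d["roi_centers"]],
        pixel_size_um=d["pixel_size_um"],
        truth=d.get("truth", {}),
    )


def write_microct_volume(vol: MicroCTVolume, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "volume.tif", vol.volume)  # multi-page stack (z pages)
    vol.truth.to_csv(out / "truth.csv", index=False)
    meta = {
        "voxel_size_um": float(vol.voxel_size),
        "achieved_porosity": float(vol.achieved_porosity),
        "achieved_cavity_vf": float(vol.achieved_cavity_vf),
        "bone_mask_voxels": int(vol.bone_mask_voxels),
    }
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return out


def read_microct_volume(in_dir: str | Path) -> MicroCTVolume:
    src = Path(in_dir)
    volume = tifffile.imread(src / "volume.tif")
    truth = pd.read_csv(src / "truth.csv")
    with open(src / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    return MicroCTVolume(
        volume=volume,
        voxel_size=meta["voxel_size_um"],
        truth=truth,
        achieved_porosity=meta["achieved_porosity"],
        achieved_cavity_vf=meta["achieved_cavity_vf"],
        bone_mask_voxels=meta["bone_mask_voxels"],
    )
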