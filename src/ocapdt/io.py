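"""Readers, writers and format validation for the pipeline's artifact dialects.

Volumes travel as HDF5 (datasets ``real``/``imag`` for complex volumes,
``oca`` for flow-contrast magnitude, optional ``mask3d``; attributes carry
the voxel size and a JSON snapshot of generation parameters) or as paired
multi-page TIFFs.  Masks are single-page 0/255 PNG or TIFF; en-face images
are float32 TIFF; cohorts are long-format CSV with the header
``animal_id,outcome,region,timepoint,pvd_percent``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import imageio.v3 as iio
import joblib
import numpy as np
import pandas as pd
import tifffile

from .angiography import OCAVolume
from .cohort import COHORT_CSV_COLUMNS, OUTCOMES, REGIONS, TIMEPOINTS
from .phantom import ComplexOCTVolume, PhantomSpec, VesselGroundTruth, VesselSegment
from .quantify import OCAImage
from .segmentation import SegmentationModel

__all__ = [
    "write_volume_h5",
    "read_volume_h5",
    "write_oca_h5",
    "read_oca_h5",
    "write_volume_tiff_pair",
    "read_volume_tiff_pair",
    "write_mask",
    "read_mask",
    "write_oca_image",
    "read_oca_image",
    "save_segmentation_model",
    "load_segmentation_model",
    "ValidationReport",
    "validate_formats",
]


def _spec_to_json(spec: PhantomSpec) -> str:
    d = dataclasses.asdict(spec)
    d["vessel_tree"] = [dataclasses.asdict(s) for s in spec.vessel_tree]
    return json.dumps(d)


def _spec_from_json(text: str) -> PhantomSpec:
    d = json.loads(text)
    d["vessel_tree"] = [
        VesselSegment(tuple(s["start"]), tuple(s["end"]), s["radius"])
        for s in d["vessel_tree"]
    ]
    d["grid_size"] = tuple(d["grid_size"])
    d["voxel_size"] = tuple(d["voxel_size"])
    return PhantomSpec(**d)


def write_volume_h5(
    path: str | Path,
    vol: ComplexOCTVolume,
    ground_truth: VesselGroundTruth | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=vol.data.real, track_times=False)
        f.create_dataset("imag", data=vol.data.imag, track_times=False)
        if ground_truth is not None:
            f.create_dataset(
                "mask3d", data=ground_truth.mask3d.astype(np.uint8), track_times=False
            )
        f.attrs["voxel_size"] = vol.voxel_size
        spec = vol.meta.get("spec")
        if isinstance(spec, PhantomSpec):
            f.attrs["phantom_spec"] = _spec_to_json(spec)


def read_volume_h5(path: str | Path) -> tuple[ComplexOCTVolume, VesselGroundTruth | None]:
    with h5py.File(path, "r") as f:
        if "real" not in f or "imag" not in f:
            raise ValueError(f"{path}: complex volume requires 'real' and 'imag' datasets")
        data = f["real"][()] + 1j * f["imag"][()]
        meta: dict = {}
        if "phantom_spec" in f.attrs:
            meta["spec"] = _spec_from_json(f.attrs["phantom_spec"])
        vol = ComplexOCTVolume(
            data=data, voxel_size=tuple(f.attrs["voxel_size"]), meta=meta
        )
        truth = None
        if "mask3d" in f:
            mask3d = f["mask3d"][()].astype(bool)
            truth = VesselGroundTruth(mask3d=mask3d, mask2d=mask3d.any(axis=0))
    return vol, truth


def write_oca_h5(path: str | Path, vol: OCAVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("oca", data=vol.data, track_times=False)
        f.attrs["voxel_size"] = vol.voxel_size


def read_oca_h5(path: str | Path) -> OCAVolume:
    with h5py.File(path, "r") as f:
        if "oca" not in f:
            raise ValueError(f"{path}: missing 'oca' dataset")
        return OCAVolume(data=f["oca"][()], voxel_size=tuple(f.attrs["voxel_size"]))


def write_volume_tiff_pair(
    real_path: str | Path, imag_path: str | Path, vol: ComplexOCTVolume
) -> None:
    """Paired multi-page TIFFs (one page per depth index), float32."""
    tifffile.imwrite(real_path, vol.data.real.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(imag_path, vol.data.imag.astype(np.float32), photometric="minisblack")


def read_volume_tiff_pair(
    real_path: str | Path,
    imag_path: str | Path,
    voxel_size: tuple[float, float, float],
) -> ComplexOCTVolume:
    real = tifffile.imread(real_path)
    imag = tifffile.imread(imag_path)
    if real.shape != imag.shape:
        raise ValueError("real/imag TIFF pair shapes differ")
    return ComplexOCTVolume(data=real + 1j * imag, voxel_size=voxel_size)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Binary mask as 0/255 single-page PNG or TIFF."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_oca_image(path: str | Path, img: OCAImage) -> None:
    tifffile.imwrite(
        path,
        img.data.astype(np.float32),
        metadata={"pixel_size_mm": img.pixel_size},
    )


def read_oca_image(path: str | Path, pixel_size: float | None = None) -> OCAImage:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if pixel_size is None:
            meta = tf.shaped_metadata or []
            for m in meta:
                if "pixel_size_mm" in m:
                    pixel_size = float(m["pixel_size_mm"])
    if pixel_size is None:
        raise ValueError(f"{path}: pixel size not stored; pass pixel_size explicitly")
    return OCAImage(data=np.asarray(data, dtype=float), pixel_size=pixel_size)


def save_segmentation_model(path: str | Path, model: SegmentationModel) -> None:
    """Persist bases, feature spec, forest and config snapshot (joblib archive)."""
    joblib.dump(
        {
            "normal_basis": model.bases.normal_basis,
            "tumour_basis": model.bases.tumour_basis,
            "spec": dataclasses.asdict(model.spec),
            "classifier": model.classifier,
            "heldout_accuracy": model.heldout_accuracy,
            "log_scale": model.log_scale,
        },
        path,
    )


def load_segmentation_model(path: str | Path) -> SegmentationModel:
    from .segmentation import ClassBases, ProfileFeatureSpec

    d = joblib.load(path)
    return SegmentationModel(
        bases=ClassBases(d["normal_basis"], d["tumour_basis"]),
        spec=ProfileFeatureSpec(**d["spec"]),
        classifier=d["classifier"],
        heldout_accuracy=d["heldout_accuracy"],
        log_scale=d["log_scale"],
    )


@dataclass
class ValidationReport:
    path: str
    ok: bool = True
    issues: list[str] = field(default_factory=list)

    def add(self, issue: str) -> None:
        self.ok = False
        self.issues.append(issue)

    def __str__(self) -> str:
        status = "OK" if self.ok else "FAIL"
        lines = [f"{self.path}: {status}"] + [f"  - {i}" for i in self.issues]
        return "\n".join(lines)


def _validate_cohort_csv(path: Path, report: ValidationReport) -> None:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        report.add(f"unreadable CSV: {exc}")
        return
    missing = [c for c in COHORT_CSV_COLUMNS if c not in df.columns]
    if missing:
        report.add(f"missing columns: {missing}")
        return
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        if row["outcome"] not in OUTCOMES:
            report.add(f"row {rownum}: unknown outcome {row['outcome']!r}")
        if row["region"] not in REGIONS:
            report.add(f"row {rownum}: unknown region {row['region']!r}")
        if row["timepoint"] not in TIMEPOINTS:
            report.add(f"row {rownum}: unknown timepoint {row['timepoint']!r}")
        try:
            pvd = float(row["pvd_percent"])
        except (TypeError, ValueError):
            report.add(f"row {rownum}: non-numeric pvd_percent {row['pvd_percent']!r}")
            continue
        if not 0.0 <= pvd <= 100.0:
            report.add(f"row {rownum}: pvd_percent {pvd} outside [0, 100]")


def _validate_h5(path: Path, report: ValidationReport) -> None:
    try:
        with h5py.File(path, "r") as f:
            names = set(f.keys())
            if "oca" in names:
                data = f["oca"]
                if np.any(np.asarray(data[0]) < 0):
                    report.add("'oca' dataset contains negative values")
            elif {"real", "imag"} <= names:
                if f["real"].shape != f["imag"].shape:
                    report.add("'real' and 'imag' shapes differ")
            else:
                report.add(
                    f"expected datasets 'real'+'imag' or 'oca', found {sorted(names)}"
                )
            if "voxel_size" not in f.attrs:
                report.add("missing 'voxel_size' attribute")
    except OSError as exc:
        report.add(f"unreadable HDF5 (truncated or not HDF5): {exc}")


def _validate_image(path: Path, report: ValidationReport) -> None:
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imread(path)
        else:
            iio.imread(path)
    except Exception as exc:
        report.add(f"unreadable image: {exc}")


def validate_formats(path: str | Path) -> ValidationReport:
    """Check a file against the dialect its extension implies."""
    path = Path(path)
    report = ValidationReport(path=str(path))
    if not path.exists():
        report.add("file does not exist")
        return report
    suffix = path.suffix.lower()
    if suffix == ".csv":
        _validate_cohort_csv(path, report)
    elif suffix in {".h5", ".hdf5"}:
        _validate_h5(path, report)
    elif suffix in {".png", ".tif", ".tiff"}:
        _validate_image(path, report)
    else:
        report.add(f"unknown artifact extension {suffix!r}")
    return report
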