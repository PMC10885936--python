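"""Readers and writers: NIfTI (canonical interchange) and DICOM ingestion.

A study on disk is a directory with one 4-D NIfTI per station
(``station00.nii.gz`` ...) whose sidecar JSON (``station00.json``) lists the
b-values; masks and parameter maps are plain 3-D NIfTI.  Arrays are stored
as (row, col, slice[, b]) with voxel spacing and the superior slice offset in
the affine.  DICOM series are read-only ingestion: slices are grouped by the
diffusion b-value tag (0018,9087) and position.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import nibabel as nib
import numpy as np

from .types import DWIStudy, StationVolume

__all__ = [
    "write_study", "read_study", "write_volume", "read_volume",
    "write_mask", "read_mask", "read_dicom_series",
]


def _affine(spacing: tuple[float, float, float], z0: float) -> np.ndarray:
    aff = np.diag([spacing[1], spacing[2], spacing[0], 1.0])
    aff[2, 3] = z0
    return aff


def write_volume(array: np.ndarray, path: str | Path,
                 spacing: tuple[float, float, float], z0: float = 0.0,
                 dtype=np.float32) -> None:
    """Write a (slice, row, col) volume as NIfTI."""
    data = np.asarray(array, dtype=dtype).transpose(1, 2, 0)
    nib.save(nib.Nifti1Image(data, _affine(spacing, z0)), str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    spacing = (float(abs(aff[2, 2])), float(abs(aff[0, 0])), float(abs(aff[1, 1])))
    vol = data.transpose(2, 0, 1)
    return vol, spacing, float(aff[2, 3])


def write_mask(mask: np.ndarray, path: str | Path,
               spacing: tuple[float, float, float], z0: float = 0.0) -> None:
    write_volume(mask.astype(np.uint8), path, spacing, z0, dtype=np.uint8)


def read_mask(path: str | Path) -> np.ndarray:
    vol, _, _ = read_volume(path)
    return vol > 0.5


def write_study(study: DWIStudy, out_dir: str | Path) -> None:
    """Write one 4-D NIfTI + JSON sidecar per station."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, st in enumerate(study.stations):
        data = st.signal.transpose(2, 3, 1, 0).astype(np.float32)  # row,col,slice,b
        img = nib.Nifti1Image(data, _affine(st.spacing, float(st.slice_positions[0])))
        nib.save(img, str(out / f"station{k:02d}.nii.gz"))
        sidecar = {
            "bval": list(st.b_values),
            "spacing_mm": list(st.spacing),
            "slice_positions_mm": [float(p) for p in st.slice_positions],
        }
        (out / f"station{k:02d}.json").write_text(json.dumps(sidecar, indent=2))
    meta = {"patient_id": study.patient_id, "scan_label": study.scan_label,
            "n_stations": len(study.stations)}
    (out / "study.json").write_text(json.dumps(meta, indent=2))


def read_study(path: str | Path) -> DWIStudy:
    """Read a study directory; stations are re-ordered superior -> inferior
    by their first slice position regardless of file order."""
    root = Path(path)
    nifti_files = sorted(root.glob("station*.nii*"))
    if not nifti_files:
        raise FileNotFoundError(f"no station NIfTI files found in {root}")
    stations = []
    for f in nifti_files:
        sidecar = f.with_name(re.sub(r"\.nii(\.gz)?$", ".json", f.name))
        if not sidecar.exists():
            raise FileNotFoundError(f"missing b-value sidecar {sidecar} for {f}")
        meta = json.loads(sidecar.read_text())
        if "bval" not in meta:
            raise ValueError(f"sidecar {sidecar} lists no 'bval' array")
        img = nib.load(str(f))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 4:
            raise ValueError(f"{f} is not a 4-D station volume")
        signal = data.transpose(3, 2, 0, 1)  # b, slice, row, col
        spacing = tuple(meta.get("spacing_mm")) if "spacing_mm" in meta else (
            float(abs(img.affine[2, 2])), float(abs(img.affine[0, 0])),
            float(abs(img.affine[1, 1])))
        if "slice_positions_mm" in meta:
            positions = np.asarray(meta["slice_positions_mm"], dtype=float)
        else:
            positions = img.affine[2, 3] + spacing[0] * np.arange(signal.shape[1])
        stations.append(StationVolume(signal=signal, b_values=tuple(meta["bval"]),
                                      spacing=tuple(spacing),
                                      slice_positions=positions))
    stations.sort(key=lambda st: st.slice_positions[0])
    meta_file = root / "study.json"
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    return DWIStudy(stations=stations, patient_id=meta.get("patient_id", ""),
                    scan_label=meta.get("scan_label", ""))


def read_dicom_series(path: str | Path) -> DWIStudy:
    """Ingest an axial diffusion DICOM series as a single-station study.

    Slices are grouped by the diffusion b-value attribute (0018,9087) and
    sorted by position along the patient axis.
    """
    import pydicom

    files = sorted(Path(path).glob("*.dcm")) or sorted(
        p for p in Path(path).iterdir() if p.is_file())
    groups: dict[float, list] = {}
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        bval = ds.get((0x0018, 0x9087), None)
        if bval is None:
            raise ValueError(f"{f} carries no diffusion b-value (0018,9087)")
        groups.setdefault(float(bval.value), []).append(ds)
    if len(groups) < 2:
        raise ValueError("DICOM series holds fewer than 2 distinct b-values")
    b_values = sorted(groups)
    for b in b_values:
        groups[b].sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    ref = groups[b_values[0]]
    positions = np.array([float(ds.ImagePositionPatient[2]) for ds in ref])
    signal = np.stack([np.stack([ds.pixel_array.astype(np.float64)
                                 for ds in groups[b]]) for b in b_values])
    spacing = (float(ref[0].SliceThickness),
               float(ref[0].PixelSpacing[0]), float(ref[0].PixelSpacing[1]))
    return DWIStudy(stations=[StationVolume(signal=signal,
                                            b_values=tuple(b_values),
                                            spacing=spacing,
                                            slice_positions=positions)],
                    patient_id=str(ref[0].get("PatientID", "")))
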