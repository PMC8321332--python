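"""Reading and writing MR magnitude/phase series, masks and derived maps.

Two on-disk layouts are supported:

* **NIfTI pairs** — two 3D/4D volumes (magnitude + phase, or real + imaginary)
  with an optional JSON sidecar carrying timing metadata that NIfTI headers
  cannot express (echo time, field strength, frame interval).
* **DICOM series** — one single-frame file per (frame, component), with the
  component flagged in ImageType (``M``/``P`` or ``R``/``I``). Integer-scaled
  phase is rescaled to radians via RescaleSlope/RescaleIntercept on load.

Phase is normalised to radians in (−π, π] on load, whatever the storage.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import ImageSeries, ROILabelMap, wrap_phase
from .errors import GeometryError, MetadataError

_SIDE_CAR_KEYS = ("echo_time", "field_strength", "frame_interval")

# phase stored as uint16 over (−π, π] with this many quantisation steps
_PHASE_STEPS = 4094


def _complex_to_mag_phase(real: np.ndarray, imag: np.ndarray):
    z = np.asarray(real, dtype=float) + 1j * np.asarray(imag, dtype=float)
    return np.abs(z), wrap_phase(np.angle(z))


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def write_series_nifti(series: ImageSeries, out_dir, basename: str = "series"):
    """Write a series as <basename>_mag.nii + <basename>_phase.nii + sidecar.

    Arrays are stored with the frame axis last (NIfTI convention: time is the
    trailing dimension) in little-endian float32. Returns the (mag, phase)
    paths; the JSON sidecar sits next to the magnitude volume.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mag_path = out_dir / f"{basename}_mag.nii"
    phase_path = out_dir / f"{basename}_phase.nii"

    spacing = series.pixel_spacing
    affine = np.diag(list(spacing) + [1.0] * (4 - len(spacing)))
    for arr, path in ((series.magnitude, mag_path), (series.phase, phase_path)):
        data = np.moveaxis(arr, 0, -1).astype("<f4")
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(tuple(spacing) + (1.0,) * (data.ndim - len(spacing)))
        nib.save(img, path)

    sidecar = {
        "echo_time": series.echo_time,
        "field_strength": series.field_strength,
        "frame_interval": series.frame_interval,
        "pixel_spacing": list(spacing),
    }
    if series.slice_locations is not None:
        sidecar["slice_locations"] = [float(s) for s in series.slice_locations]
    (out_dir / f"{basename}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return mag_path, phase_path


def _load_nifti_pair(path_a, path_b, layout: str) -> ImageSeries:
    img_a, img_b = nib.load(str(path_a)), nib.load(str(path_b))
    a = np.asarray(img_a.dataobj, dtype=float)
    b = np.asarray(img_b.dataobj, dtype=float)
    if a.shape != b.shape:
        raise GeometryError(f"component volumes disagree in shape: {a.shape} vs {b.shape}")
    # frame axis: trailing on disk -> leading in memory; 3D volumes = 1 frame
    if a.ndim == 2:
        a, b = a[..., None], b[..., None]
    a = np.moveaxis(a, -1, 0)
    b = np.moveaxis(b, -1, 0)

    sidecar_path = Path(str(path_a)).with_suffix("").with_suffix("")  # strip .nii[.gz]
    sidecar_path = sidecar_path.parent / (sidecar_path.name.replace("_mag", "").replace("_real", "") + ".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())

    if layout == "real-imaginary":
        mag, phase = _complex_to_mag_phase(a, b)
    elif layout == "magnitude-phase":
        mag, phase = a, wrap_phase(b)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    zooms = img_a.header.get_zooms()
    spacing = meta.get("pixel_spacing", list(zooms[: mag.ndim - 1]))
    if "echo_time" not in meta:
        raise MetadataError("echo_time", "NIfTI pair has no sidecar stating echo_time")
    return ImageSeries(
        magnitude=mag,
        phase=phase,
        frame_interval=float(meta.get("frame_interval", 3.0)),
        echo_time=float(meta["echo_time"]),
        field_strength=float(meta.get("field_strength", 1.5)),
        pixel_spacing=tuple(spacing),
        slice_locations=meta.get("slice_locations"),
    )


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def write_series_dicom(series: ImageSeries, out_dir) -> list:
    """Write a 2D series as single-frame secondary-capture DICOM files.

    One magnitude and one phase file per frame; phase is quantised to uint16
    with RescaleSlope/Intercept mapping back onto (−π, π]. Returns the file
    paths (magnitude files first within each frame).
    """
    if series.magnitude.ndim != 3:
        raise GeometryError("DICOM writer supports 2D frames only")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study_uid, series_uid = generate_uid(), generate_uid()
    mag_max = float(series.magnitude.max()) or 1.0
    mag_slope = mag_max / 65535.0
    phase_slope = 2.0 * np.pi / _PHASE_STEPS
    paths = []
    for t in range(series.n_frames):
        for comp, arr in (("M", series.magnitude[t]), ("P", series.phase[t])):
            if comp == "M":
                stored = np.round(arr / mag_slope).astype(np.uint16)
                slope, intercept = mag_slope, 0.0
            else:
                stored = np.round((arr + np.pi) / phase_slope).astype(np.uint16)
                slope, intercept = phase_slope, -np.pi
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
            ds.SOPClassUID = meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.StudyInstanceUID, ds.SeriesInstanceUID = study_uid, series_uid
            ds.Modality = "MR"
            ds.ImageType = ["ORIGINAL", "PRIMARY", comp]
            ds.InstanceNumber = t + 1
            ds.Rows, ds.Columns = stored.shape
            ds.PixelSpacing = [str(series.pixel_spacing[0]), str(series.pixel_spacing[1])]
            ds.EchoTime = series.echo_time * 1e3  # DICOM stores ms
            ds.MagneticFieldStrength = series.field_strength
            ds.TemporalResolution = series.frame_interval * 1e3  # ms
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.RescaleSlope = slope
            ds.RescaleIntercept = intercept
            ds.PixelData = stored.tobytes()
            path = out_dir / f"frame{t:04d}_{comp}.dcm"
            ds.save_as(path, enforce_file_format=True)
            paths.append(path)
    return paths


def _load_dicom_series(files, layout: str) -> ImageSeries:
    datasets = [pydicom.dcmread(str(f)) for f in files]
    comp_codes = {"magnitude-phase": ("M", "P"), "real-imaginary": ("R", "I")}[layout]
    groups = {c: [] for c in comp_codes}
    for ds in datasets:
        image_type = list(getattr(ds, "ImageType", []))
        code = next((c for c in comp_codes if c in image_type), None)
        if code is None:
            raise MetadataError("ImageType", f"cannot classify component from ImageType {image_type}")
        if "InstanceNumber" not in ds:
            raise MetadataError("InstanceNumber")
        groups[code].append(ds)
    counts = {c: len(g) for c, g in groups.items()}
    if len(set(counts.values())) != 1 or 0 in counts.values():
        raise MetadataError("ImageType", f"unbalanced component counts per frame: {counts}")
    for g in groups.values():
        g.sort(key=lambda ds: int(ds.InstanceNumber))

    ref = groups[comp_codes[0]][0]
    for attr in ("EchoTime", "PixelSpacing"):
        if attr not in ref:
            raise MetadataError(attr)
    shape = (int(ref.Rows), int(ref.Columns))
    spacing = tuple(float(s) for s in ref.PixelSpacing)

    def pixels(ds):
        if (int(ds.Rows), int(ds.Columns)) != shape or tuple(float(s) for s in ds.PixelSpacing) != spacing:
            raise GeometryError("mixed geometries within one series")
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept

    a = np.stack([pixels(ds) for ds in groups[comp_codes[0]]])
    b = np.stack([pixels(ds) for ds in groups[comp_codes[1]]])
    if layout == "real-imaginary":
        mag, phase = _complex_to_mag_phase(a, b)
    else:
        mag, phase = np.maximum(a, 0.0), wrap_phase(b)

    interval = float(getattr(ref, "TemporalResolution", 3000.0)) * 1e-3
    return ImageSeries(
        magnitude=mag,
        phase=phase,
        frame_interval=interval,
        echo_time=float(ref.EchoTime) * 1e-3,
        field_strength=float(getattr(ref, "MagneticFieldStrength", 1.5)),
        pixel_spacing=spacing,
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def load_series(source, layout: str = "magnitude-phase") -> ImageSeries:
    """Load an :class:`ImageSeries` from disk.

    Parameters
    ----------
    source
        Either a pair of NIfTI paths ``(component_a, component_b)``, a
        directory containing a DICOM series, or an explicit list of DICOM
        files.
    layout
        ``"magnitude-phase"`` (default) or ``"real-imaginary"``; the latter is
        converted to magnitude + wrapped phase on load.
    """
    if layout not in ("magnitude-phase", "real-imaginary"):
        raise ValueError(f"unknown layout {layout!r}")
    if isinstance(source, (tuple, list)) and len(source) == 2 and all(
        str(p).endswith((".nii", ".nii.gz")) for p in source
    ):
        return _load_nifti_pair(source[0], source[1], layout)
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        files = sorted(Path(source).glob("*.dcm"))
        if not files:
            raise FileNotFoundError(f"no DICOM files in {source}")
        return _load_dicom_series(files, layout)
    if isinstance(source, (tuple, list)):
        return _load_dicom_series(list(source), layout)
    raise ValueError(f"cannot interpret source {source!r}")


# ---------------------------------------------------------------------------
# masks and derived products
# ---------------------------------------------------------------------------

def write_label_map(rois: ROILabelMap, out_dir, basename: str = "labels"):
    """Write the label image (+ inner/outer overlays) as integer NIfTI files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    items = [("labels", rois.labels)]
    if rois.inner_roi is not None:
        items.append(("inner_roi", rois.inner_roi.astype(np.int16)))
    if rois.outer_roi is not None:
        items.append(("outer_roi", rois.outer_roi.astype(np.int16)))
    for name, arr in items:
        path = out_dir / f"{basename}_{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype="<i2"), np.eye(4)), path)
        paths[name] = path
    (out_dir / f"{basename}_registry.json").write_text(
        json.dumps(rois.registry, indent=2, sort_keys=True)
    )
    return paths


def read_label_map(out_dir, basename: str = "labels") -> ROILabelMap:
    out_dir = Path(out_dir)
    labels = np.asarray(nib.load(str(out_dir / f"{basename}_labels.nii")).dataobj).astype(int)
    registry = json.loads((out_dir / f"{basename}_registry.json").read_text())
    kwargs = {}
    for name in ("inner_roi", "outer_roi"):
        path = out_dir / f"{basename}_{name}.nii"
        if path.exists():
            kwargs[name] = np.asarray(nib.load(str(path)).dataobj).astype(bool)
    return ROILabelMap(labels=labels, registry=registry, **kwargs)


def write_temperature_map(tmap, path_base):
    """Write a temperature map as NIfTI (ΔT + validity) with a JSON sidecar."""
    path_base = Path(path_base)
    path_base.parent.mkdir(parents=True, exist_ok=True)
    delta = np.where(tmap.validity, tmap.delta_T, np.nan).astype("<f4")
    nib.save(nib.Nifti1Image(delta, np.eye(4)), path_base.with_suffix(".nii"))
    sidecar = {
        "method": tmap.method,
        "frame_index": tmap.frame_index,
        "time_s": tmap.time_s,
        "params": {
            "alpha": tmap.params.alpha,
            "gamma": tmap.params.gamma,
            "field_strength": tmap.params.field_strength,
            "echo_time": tmap.params.echo_time,
        },
        "extras": {k: v for k, v in tmap.extras.items() if np.isscalar(v)},
    }
    path_base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path_base.with_suffix(".nii")
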