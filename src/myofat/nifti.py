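"""NIfTI-1 reading and writing for volumes, masks and multi-echo series.

Conventions
-----------
* Quantitative maps are written as float32, masks as uint8, with the affine
  carrying the voxel spacing on its diagonal (identity orientation by
  default).
* A multi-echo complex series is stored as a single 4D float32 volume of
  shape ``(nx, ny, nz, 2 * n_echoes)`` with channels ordered
  ``re(e1), im(e1), re(e2), im(e2), ...``, plus a JSON sidecar
  ``<stem>_protocol.json`` holding the acquisition protocol.
* Maps and masks entering a joint computation must share their affine to a
  tolerance of 1e-4; a mismatch is a hard error that prints both affines.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .masks import MuscleMask
from .protocol import AcquisitionProtocol
from .waterfat import EchoSeries

__all__ = [
    "spacing_to_affine",
    "read_nifti_volume",
    "write_nifti_volume",
    "read_mask",
    "write_mask",
    "write_echo_series",
    "read_echo_series",
    "check_affines_match",
]

AFFINE_TOL = 1e-4


def spacing_to_affine(spacing) -> np.ndarray:
    """Diagonal affine from a (dx, dy, dz) spacing in mm."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def check_affines_match(a: np.ndarray, b: np.ndarray, what: str = "volumes") -> None:
    """Raise with both affines printed if they differ beyond tolerance."""
    if not np.allclose(a, b, atol=AFFINE_TOL):
        raise ValueError(
            f"affine mismatch between {what} (tolerance {AFFINE_TOL}):\n"
            f"first:\n{np.array2string(a, precision=6)}\n"
            f"second:\n{np.array2string(b, precision=6)}"
        )


def _require(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    return p


def read_nifti_volume(path) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (data, affine, voxel spacing in mm)."""
    img = nib.load(_require(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine), spacing


def write_nifti_volume(data: np.ndarray, path, affine=None, spacing=None, dtype=np.float32) -> Path:
    """Write a volume as NIfTI-1; give either an affine or a spacing."""
    if affine is None:
        affine = spacing_to_affine(spacing if spacing is not None else (1.0, 1.0, 1.0))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


def write_mask(mask: MuscleMask, path) -> Path:
    """Write a MuscleMask as a uint8 NIfTI with its axis annotation in a sidecar."""
    path = write_nifti_volume(
        mask.voxels.astype(np.uint8), path,
        spacing=mask.voxel_spacing, dtype=np.uint8,
    )
    sidecar = path.with_name(path.name.split(".")[0] + "_mask.json")
    sidecar.write_text(json.dumps({
        "axis": mask.axis, "proximal_end": mask.proximal_end, "name": mask.name,
    }, indent=2))
    return path


def read_mask(path, axis: int | None = None, proximal_end: str | None = None) -> MuscleMask:
    """Read a uint8 NIfTI mask, taking axis annotations from the sidecar if present."""
    data, affine, spacing = read_nifti_volume(path)
    meta = {"axis": 2, "proximal_end": "low", "name": ""}
    sidecar = Path(path).with_name(Path(path).name.split(".")[0] + "_mask.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if axis is not None:
        meta["axis"] = axis
    if proximal_end is not None:
        meta["proximal_end"] = proximal_end
    return MuscleMask(
        data.astype(bool), spacing,
        axis=int(meta["axis"]), proximal_end=str(meta["proximal_end"]), name=str(meta["name"]),
    )


def write_echo_series(series: EchoSeries, path) -> Path:
    """Write a complex multi-echo series (real/imag channel pairs + protocol sidecar)."""
    sig = series.signal  # (N, x, y, z)
    n = sig.shape[0]
    stacked = np.empty(sig.shape[1:] + (2 * n,), dtype=np.float32)
    for e in range(n):
        stacked[..., 2 * e] = sig[e].real
        stacked[..., 2 * e + 1] = sig[e].imag
    path = write_nifti_volume(stacked, path, spacing=series.protocol.voxel_spacing)
    proto = series.protocol
    sidecar = path.with_name(path.name.split(".")[0] + "_protocol.json")
    sidecar.write_text(json.dumps({
        "n_echoes": proto.n_echoes,
        "te1": proto.te1,
        "delta_te": proto.delta_te,
        "field_strength": proto.field_strength,
        "voxel_spacing": list(proto.voxel_spacing),
        "bipolar": proto.bipolar,
    }, indent=2))
    return path


def read_echo_series(path) -> EchoSeries:
    """Read a complex multi-echo series written by :func:`write_echo_series`."""
    data, affine, spacing = read_nifti_volume(path)
    sidecar = Path(path).with_name(Path(path).name.split(".")[0] + "_protocol.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing protocol sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    protocol = AcquisitionProtocol(
        n_echoes=int(meta["n_echoes"]),
        te1=float(meta["te1"]),
        delta_te=float(meta["delta_te"]),
        field_strength=float(meta["field_strength"]),
        voxel_spacing=tuple(float(s) for s in meta["voxel_spacing"]),
        bipolar=bool(meta["bipolar"]),
    )
    n = protocol.n_echoes
    if data.shape[-1] != 2 * n:
        raise ValueError(f"expected {2 * n} real/imag channels, found {data.shape[-1]}")
    sig = np.empty((n,) + data.shape[:-1], dtype=complex)
    for e in range(n):
        sig[e] = data[..., 2 * e] + 1j * data[..., 2 * e + 1]
    return EchoSeries(signal=sig, protocol=protocol)
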