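"""Muscle masks and the volumetric / fat-fraction measurements taken on them.

A segmentation is a 3D binary mask annotated with the voxel spacing and with
which array axis runs inferior-superior (the muscle's long axis) and which end
of that axis is proximal.  From a PDFF map and a mask the package extracts the
study's core record: mean PDFF over the (T2*-filtered) mask, total muscle
volume, fat volume ``= meanPDFF x total volume`` and contractile tissue volume
``= total - fat``.

The T2* filter removes voxels from the PDFF average only (bone or artefact
voxels with implausibly short or long T2*); volumes are always computed on the
full mask, so the filter never changes the measured muscle size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MuscleMask",
    "MuscleMetrics",
    "apply_t2star_filter",
    "compute_metrics",
    "compute_contractile_volume",
]


@dataclass(frozen=True)
class MuscleMask:
    """Binary 3D segmentation mask with anatomical axis annotation.

    Parameters
    ----------
    voxels : bool array, 3D
        True inside the muscle.
    voxel_spacing : tuple of float
        Voxel size (dx, dy, dz) in millimetres, matching the array axes.
    axis : int
        Which array axis (0, 1 or 2) runs inferior-superior.
    proximal_end : {"low", "high"}
        Whether the proximal (origin) end of the muscle sits at low or high
        slice indices along ``axis``.
    name : str
        Optional label for the muscle ("psoas", "erector", ...).
    """

    voxels: np.ndarray
    voxel_spacing: tuple[float, float, float]
    axis: int = 2
    proximal_end: str = "low"
    name: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {vox.shape}")
        if vox.dtype != bool:
            object.__setattr__(self, "voxels", vox.astype(bool))
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be 3 positive values, got {self.voxel_spacing}")
        if self.axis not in (0, 1, 2):
            raise ValueError(f"axis must be 0, 1 or 2, got {self.axis}")
        if self.proximal_end not in ("low", "high"):
            raise ValueError(f"proximal_end must be 'low' or 'high', got {self.proximal_end!r}")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.voxel_spacing
        return dx * dy * dz / 1000.0

    @property
    def volume_ml(self) -> float:
        """Total mask volume in mL: voxel count times voxel volume, exactly."""
        return self.n_voxels * self.voxel_volume_ml

    def with_voxels(self, voxels: np.ndarray) -> "MuscleMask":
        """Copy of this mask with a different voxel array, annotations kept."""
        return replace(self, voxels=voxels.astype(bool))

    def occupied_slices(self) -> np.ndarray:
        """Indices of slices along ``axis`` containing at least one mask voxel."""
        other = tuple(a for a in range(3) if a != self.axis)
        return np.nonzero(self.voxels.any(axis=other))[0]


@dataclass(frozen=True)
class MuscleMetrics:
    """Measurement record for one muscle (whole or one lengthwise section).

    ``contractile_volume_ml + fat_volume_ml == total_volume_ml`` by
    construction.  ``n_voxels_pdff_valid`` counts voxels surviving the T2*
    filter; the PDFF mean is taken over those voxels only, while the volume
    uses the full mask.
    """

    mean_pdff: float
    total_volume_ml: float
    fat_volume_ml: float
    contractile_volume_ml: float
    n_voxels_total: int
    n_voxels_pdff_valid: int
    muscle: str = ""
    section: str = "total"


def apply_t2star_filter(
    mask: MuscleMask,
    t2star_map: np.ndarray,
    low: float = 5.0,
    high: float = 100.0,
) -> MuscleMask:
    """Remove voxels with T2* outside ``[low, high]`` ms from a mask.

    The study's post-processing step: voxels with T2* below 5 ms (bone,
    susceptibility artefact) or above 100 ms (fluid) are excluded from the
    PDFF analysis.  The bounds are inclusive: a voxel at exactly 5 ms or
    100 ms is retained.  Voxels with invalid (NaN) T2* are removed.

    Returns a new mask; the input is untouched.  The result may be empty,
    which downstream metric computation treats as "mean PDFF undefined".
    """
    t2s = np.asarray(t2star_map, dtype=float)
    if t2s.shape != mask.voxels.shape:
        raise ValueError(f"t2star map shape {t2s.shape} does not match mask shape {mask.voxels.shape}")
    if low > high:
        raise ValueError(f"low ({low}) must not exceed high ({high})")
    with np.errstate(invalid="ignore"):
        keep = mask.voxels & np.isfinite(t2s) & (t2s >= low) & (t2s <= high)
    return mask.with_voxels(keep)


def compute_contractile_volume(total_ml: float, fat_ml: float) -> float:
    """Contractile tissue volume: total muscle volume minus muscle fat volume."""
    if not (0 <= fat_ml <= total_ml):
        raise ValueError(f"need 0 <= fat ({fat_ml}) <= total ({total_ml})")
    return total_ml - fat_ml


def compute_metrics(
    pdff_map: np.ndarray,
    mask: MuscleMask,
    filtered_mask: MuscleMask | None = None,
    muscle: str = "",
    section: str = "total",
    volume_from_filtered: bool = False,
) -> MuscleMetrics:
    """Extract mean PDFF and volumes for one mask.

    Parameters
    ----------
    pdff_map : array
        PDFF volume in percent, congruent with the mask.
    mask : MuscleMask
        Full segmentation; defines total volume.
    filtered_mask : MuscleMask, optional
        T2*-filtered subset of ``mask`` over which mean PDFF is averaged.
        Defaults to the full mask.
    volume_from_filtered : bool
        If True, the volume factor also uses the filtered mask (alternative
        reading of the filtering step); default False uses the full mask.

    Returns
    -------
    MuscleMetrics with
    ``total = n_voxels * voxel_volume``, ``fat = meanPDFF/100 * total`` and
    ``contractile = total - fat``.

    Raises
    ------
    ValueError
        If the mask is empty, the filtered mask is not a subset, or the
        filtered mask is empty (mean PDFF undefined).
    """
    pdff = np.asarray(pdff_map, dtype=float)
    if pdff.shape != mask.voxels.shape:
        raise ValueError(f"pdff map shape {pdff.shape} does not match mask shape {mask.voxels.shape}")
    if mask.n_voxels == 0:
        raise ValueError("empty mask: no metrics defined")
    if filtered_mask is None:
        filtered_mask = mask
    if np.any(filtered_mask.voxels & ~mask.voxels):
        raise ValueError("filtered_mask must be a subset of mask")
    n_valid = filtered_mask.n_voxels
    if n_valid == 0:
        raise ValueError("T2* filter removed every voxel: mean PDFF undefined")

    mean_pdff = float(np.mean(pdff[filtered_mask.voxels]))
    vol_mask = filtered_mask if volume_from_filtered else mask
    total = vol_mask.volume_ml
    fat = mean_pdff / 100.0 * total
    contractile = total - fat
    return MuscleMetrics(
        mean_pdff=mean_pdff,
        total_volume_ml=total,
        fat_volume_ml=fat,
        contractile_volume_ml=contractile,
        n_voxels_total=mask.n_voxels,
        n_voxels_pdff_valid=n_valid,
        muscle=muscle or mask.name,
        section=section,
    )
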