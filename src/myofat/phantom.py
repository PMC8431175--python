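"""Digital phantoms with known ground truth for the muscle-PDFF pipeline.

The phantom emulates the anatomy the pipeline measures: two tubular "muscles"
running along the slice (inferior-superior) axis of the volume.  The
psoas-like muscle is a single elliptical strand; the erector-like muscle is a
pair of adjacent strands joined by a thin bridge of intermuscular fat,
mimicking the fatty streaks seen between paraspinal muscle groups.  Each
muscle's fat fraction is prescribed per lengthwise third (proximal, middle,
distal) and the generator recentres the in-mask values so the mask-mean PDFF
of every third equals its target exactly; a smooth zero-mean variation is
superimposed so the maps are not piecewise constant.

``simulate_signal`` forward-models the multi-echo complex gradient-echo
signal from the ground truth, including the multi-peak fat spectrum, B0
field map, common R2* decay, initial phase and (for bipolar readouts) an
echo-parity eddy-current phase, with optional complex Gaussian noise pinned
to a prescribed SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .masks import MuscleMask
from .protocol import AcquisitionProtocol, FatSpectrum, make_default_spectrum
from .regional import split_thirds
from .waterfat import EchoSeries

__all__ = ["GroundTruth", "generate_phantom", "simulate_signal", "DEFAULT_PDFF_PROFILES"]

#: Default per-third PDFF targets (%, proximal/middle/distal) for the two
#: simulated muscles: psoas-like fat decreases distally, erector-like fat is
#: markedly higher in the distal third.
DEFAULT_PDFF_PROFILES: dict[str, tuple[float, float, float]] = {
    "psoas": (11.2, 10.0, 9.5),
    "erector": (14.1, 15.2, 22.5),
}


@dataclass(frozen=True)
class GroundTruth:
    """Voxel-wise ground truth for a simulated acquisition.

    ``water`` and ``fat`` are non-negative signal magnitudes (arbitrary
    units) sharing the initial phase ``init_phase``; ``fieldmap_hz`` is the
    B0 off-resonance, ``r2star`` the common decay rate (1/s), ``eddy_phase``
    a global scalar applied with alternating sign across echoes.
    """

    water: np.ndarray
    fat: np.ndarray
    fieldmap_hz: np.ndarray
    r2star: np.ndarray
    init_phase: np.ndarray
    eddy_phase: float
    masks: dict[str, MuscleMask]
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = self.water.shape
        for name in ("fat", "fieldmap_hz", "r2star", "init_phase"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != water shape {shape}")
        if np.any(self.water < 0) or np.any(self.fat < 0):
            raise ValueError("water and fat magnitudes must be non-negative")
        if np.any(self.r2star < 0):
            raise ValueError("r2star must be non-negative")

    @property
    def pdff(self) -> np.ndarray:
        """True PDFF in percent: ``100 F / (W + F)``, 0 where W + F = 0."""
        tot = self.water + self.fat
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, 100.0 * self.fat / np.where(tot > 0, tot, 1.0), 0.0)

    @property
    def union_mask(self) -> np.ndarray:
        """Boolean union of all muscle masks."""
        out = np.zeros(self.water.shape, dtype=bool)
        for m in self.masks.values():
            out |= m.voxels
        return out


def _tube_mask(shape, cx, cy, rx, ry, taper=0.15):
    """Elliptical tube along axis 2 with a mid-length belly (fractional coords)."""
    nx, ny, nz = shape
    x = (np.arange(nx) + 0.5) / nx
    y = (np.arange(ny) + 0.5) / ny
    z = (np.arange(nz) + 0.5) / nz
    scale = 1.0 - taper * (2.0 * (z - 0.5)) ** 2  # widest at mid-length
    dx = (x[:, None, None] - cx) / rx
    dy = (y[None, :, None] - cy) / ry
    return (dx**2 + dy**2) <= scale[None, None, :] ** 2


def _smooth_field(shape, rng, sigma):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def generate_phantom(
    shape: tuple[int, int, int] = (32, 32, 18),
    protocol: AcquisitionProtocol | None = None,
    pdff_profile: "dict[str, tuple] | tuple | None" = None,
    seed: int = 0,
    fieldmap_max_hz: float = 60.0,
    r2star_muscle: float = 35.0,
    r2star_background: float = 45.0,
    eddy_phase: float = 0.0,
    streak_pdff_boost: float = 45.0,
    variation_pp: float = 1.5,
) -> GroundTruth:
    """Generate a two-muscle digital phantom with prescribed regional PDFF.

    Parameters
    ----------
    shape : (nx, ny, nz)
        Volume dimensions; at least (16, 16, 9).  Axis 2 is the
        inferior-superior (slice) axis; low indices are proximal.
    protocol : AcquisitionProtocol, optional
        Supplies the voxel spacing (default protocol: 3 x 3 x 6 mm).
    pdff_profile : dict or 3-tuple, optional
        Per-third PDFF targets in percent, proximal/middle/distal.  A dict
        maps muscle name ("psoas", "erector") to a 3-tuple; a bare 3-tuple
        applies to both muscles.  Defaults to :data:`DEFAULT_PDFF_PROFILES`.
    seed : int
        Seeds every random component; same seed gives a bit-identical
        phantom.
    fieldmap_max_hz : float
        Peak |B0 off-resonance| of the smooth simulated field map.
    eddy_phase : float
        Ground-truth echo-parity phase theta (radians); 0 by default.
    streak_pdff_boost : float
        Extra PDFF (pp) on the intermuscular bridge voxels of the
        erector-like muscle.
    variation_pp : float
        Amplitude of the smooth within-section PDFF variation.  The
        variation is recentred so each third's mask-mean equals its target
        exactly; it is shrunk near the 0 and 100 limits (a target of 0 gives
        pure water exactly).

    Returns
    -------
    GroundTruth
        Masks are single 6-connected components; mask-mean PDFF per
        lengthwise third equals the prescribed profile.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < m for s, m in zip(shape, (16, 16, 9))):
        raise ValueError(f"shape must be at least (16, 16, 9), got {shape}")
    if protocol is None:
        protocol = AcquisitionProtocol()
    if pdff_profile is None:
        profiles = dict(DEFAULT_PDFF_PROFILES)
    elif isinstance(pdff_profile, dict):
        profiles = {k: tuple(float(v) for v in vals) for k, vals in pdff_profile.items()}
    else:
        prof = tuple(float(v) for v in pdff_profile)
        profiles = {"psoas": prof, "erector": prof}
    for name, prof in profiles.items():
        if len(prof) != 3 or any(not (0.0 <= v <= 100.0) for v in prof):
            raise ValueError(f"pdff_profile for {name!r} must be 3 values in [0, 100], got {prof}")

    rng = np.random.default_rng(seed)
    spacing = tuple(float(s) for s in protocol.voxel_spacing)
    nx, ny, nz = shape

    masks: dict[str, MuscleMask] = {}
    streak = np.zeros(shape, dtype=bool)
    if "psoas" in profiles:
        vox = _tube_mask(shape, 0.30, 0.40, 0.14, 0.16)
        masks["psoas"] = MuscleMask(vox, spacing, axis=2, proximal_end="low", name="psoas")
    if "erector" in profiles:
        strand_a = _tube_mask(shape, 0.70, 0.30, 0.105, 0.115)
        strand_b = _tube_mask(shape, 0.70, 0.58, 0.105, 0.115)
        x = (np.arange(nx) + 0.5) / nx
        y = (np.arange(ny) + 0.5) / ny
        bridge = (
            (np.abs(x[:, None, None] - 0.70) <= 0.6 / nx)
            & (y[None, :, None] >= 0.30)
            & (y[None, :, None] <= 0.58)
            & np.ones((1, 1, nz), dtype=bool)
        )
        vox = strand_a | strand_b | bridge
        streak = bridge & ~(strand_a | strand_b)
        masks["erector"] = MuscleMask(vox, spacing, axis=2, proximal_end="low", name="erector")
    for extra in set(profiles) - {"psoas", "erector"}:
        raise ValueError(f"unknown muscle {extra!r} in pdff_profile (expected psoas/erector)")

    # PDFF field: background plus per-third targets with smooth, recentred
    # variation inside each muscle.
    pdff = np.full(shape, 3.0)
    variation = variation_pp * _smooth_field(shape, rng, sigma=3.0)
    for name, mask in masks.items():
        targets = profiles[name]
        split = split_thirds(mask)
        for target, sec in zip(targets, (split.proximal, split.middle, split.distal)):
            sel = sec.voxels
            if not sel.any():
                continue
            amp_scale = min(1.0, target / (2.0 * variation_pp + 1e-12),
                            (100.0 - target) / (2.0 * variation_pp + 1e-12))
            vals = target + amp_scale * variation[sel]
            if name == "erector" and streak_pdff_boost > 0:
                boost = np.where(streak[sel], streak_pdff_boost, 0.0)
                if target + streak_pdff_boost <= 95.0 and target > 0:
                    vals = vals + boost
            vals += target - vals.mean()  # mask-mean of the third == target
            pdff[sel] = np.clip(vals, 0.0, 100.0)

    amp = np.full(shape, 0.5)
    union = np.zeros(shape, dtype=bool)
    for m in masks.values():
        union |= m.voxels
    amp[union] = 1.0
    fat = amp * pdff / 100.0
    water = amp - fat

    fieldmap = (
        0.6 * ((np.arange(nx)[:, None, None] + 0.5) / nx - 0.5)
        + 0.4 * ((np.arange(ny)[None, :, None] + 0.5) / ny - 0.5)
        + 0.3 * ((np.arange(nz)[None, None, :] + 0.5) / nz - 0.5)
        + 0.5 * _smooth_field(shape, rng, sigma=5.0)
    )
    fieldmap = fieldmap / max(np.abs(fieldmap).max(), 1e-12) * fieldmap_max_hz

    r2star = np.full(shape, float(r2star_background))
    r2star[union] = r2star_muscle
    r2star = np.clip(r2star + 4.0 * _smooth_field(shape, rng, sigma=4.0), 5.0, None)

    init_phase = 0.4 * _smooth_field(shape, rng, sigma=5.0)

    return GroundTruth(
        water=water,
        fat=fat,
        fieldmap_hz=fieldmap,
        r2star=r2star,
        init_phase=init_phase,
        eddy_phase=float(eddy_phase),
        masks=masks,
        voxel_spacing=spacing,
    )


def simulate_signal(
    truth: GroundTruth,
    protocol: AcquisitionProtocol | None = None,
    spectrum: FatSpectrum | None = None,
    snr: float | None = None,
    seed: int = 0,
) -> EchoSeries:
    """Forward-simulate the multi-echo complex gradient-echo signal.

    For echo n (1-based) at ``TE_n``::

        s_n = (W + F c_n) exp(i 2 pi psi TE_n) exp(-R2* TE_n)
              exp(i phi0) exp(i (-1)**n theta)

    where ``c_n`` are the fat spectral coefficients and the last factor is
    applied only for bipolar protocols.

    Parameters
    ----------
    snr : float, optional
        If given, additive circular complex Gaussian noise with total
        complex SD ``sigma = (mean in-mask |s_1|) / snr`` (each real/imag
        component has SD ``sigma / sqrt(2)``, so ``E|n|^2 = sigma^2``).
        ``None`` means noiseless.
    seed : int
        Seeds the noise generator; deterministic for a fixed seed.
    """
    if protocol is None:
        protocol = AcquisitionProtocol()
    if spectrum is None:
        spectrum = make_default_spectrum()
    te = protocol.echo_times
    if np.any(np.diff(te) <= 0) or te[0] <= 0:
        raise ValueError("echo times must be positive and increasing")

    shape = truth.water.shape
    c = spectrum.signal_coefficients(te, protocol.field_strength)  # (N,)
    rho = truth.water[None] + truth.fat[None] * c.reshape(-1, 1, 1, 1)
    phase = np.exp(
        (2j * np.pi * truth.fieldmap_hz[None] - truth.r2star[None]) * te.reshape(-1, 1, 1, 1)
    )
    sig = rho * phase * np.exp(1j * truth.init_phase)[None]
    if protocol.bipolar and truth.eddy_phase != 0.0:
        sig = sig * np.exp(1j * protocol.eddy_signs * truth.eddy_phase).reshape(-1, 1, 1, 1)

    if snr is not None:
        if snr <= 0:
            raise ValueError(f"snr must be positive, got {snr}")
        ref_mask = truth.union_mask
        if not ref_mask.any():
            ref_mask = np.ones(shape, dtype=bool)
        sigma = float(np.abs(sig[0][ref_mask]).mean()) / snr
        rng = np.random.default_rng(seed)
        noise = rng.normal(scale=sigma / np.sqrt(2.0), size=(2,) + sig.shape)
        sig = sig + noise[0] + 1j * noise[1]

    return EchoSeries(signal=sig, protocol=protocol)
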