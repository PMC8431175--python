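"""Complex-based water-fat separation and PDFF / T2* mapping.

Signal model for echo n (1-based) at echo time ``TE_n``::

    s_n = (W + F * c_n) * exp(i 2 pi psi TE_n) * exp(-R2* TE_n)
          * exp(i phi0) * exp(i (-1)**n theta)

with ``c_n = sum_p a_p exp(i 2 pi f_p TE_n)`` the multi-peak fat dephasing
coefficient, ``psi`` the B0 field map (Hz), ``R2*`` the common effective
transverse relaxation rate (1/s), ``phi0`` a voxel-wise initial phase and
``theta`` a global echo-parity phase from eddy currents on bipolar readouts.

Estimation uses variable projection: for each candidate ``(psi, R2*)`` the
complex amplitudes ``(W, F)`` enter the model linearly and are solved in
closed form, leaving a 2-parameter nonlinear search.  A shared coarse grid is
scanned for every voxel simultaneously, then each voxel's best candidate is
polished with a per-voxel pattern search (step halving on failure).  Allowing
``W`` and ``F`` to be complex absorbs ``phi0``; PDFF is formed from the
magnitudes, ``100 |F| / (|W| + |F|)``, which is bounded to [0, 100].

Field-map smoothness is exploited to suppress water-fat swaps: after the
per-voxel fits, the field map is median-filtered and voxels deviating from
the filtered value by more than a threshold are re-fit with the field map
constrained near the local median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage, optimize

from .protocol import AcquisitionProtocol, FatSpectrum, make_default_spectrum

__all__ = [
    "EchoSeries",
    "VoxelFit",
    "QuantMaps",
    "fit_voxel",
    "separate",
    "estimate_eddy_phase",
]


@dataclass(frozen=True)
class EchoSeries:
    """Complex multi-echo signal, echo-major: shape ``(n_echoes, nx, ny, nz)``."""

    signal: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal)
        if not np.iscomplexobj(sig):
            sig = sig.astype(complex)
        if sig.ndim != 4:
            raise ValueError(f"signal must be 4D (echo, x, y, z), got shape {sig.shape}")
        if sig.shape[0] != self.protocol.n_echoes:
            raise ValueError(
                f"signal has {sig.shape[0]} echoes but protocol declares {self.protocol.n_echoes}"
            )
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite values")
        object.__setattr__(self, "signal", sig)

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[1:]


@dataclass(frozen=True)
class VoxelFit:
    """Single-voxel water-fat fit.

    ``water`` and ``fat`` are the magnitudes of the complex amplitudes (the
    shared initial phase is absorbed in the linear solve and discarded).
    """

    water: float
    fat: float
    fieldmap_hz: float
    r2star: float
    residual: float
    converged: bool
    at_bound: bool = False

    @property
    def pdff(self) -> float:
        """Fat fraction in percent, ``100 |F| / (|W| + |F|)``; 0 for zero signal."""
        tot = self.water + self.fat
        return 100.0 * self.fat / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class QuantMaps:
    """Quantitative maps from water-fat separation.

    ``pdff`` in percent, ``t2star`` in ms (NaN where invalid), ``fieldmap``
    in Hz, ``r2star`` in 1/s.  ``t2star_valid`` flags voxels whose R2* is
    positive and away from the search bounds; T2* values at a bound are
    reported as NaN rather than silently clamped so that the downstream T2*
    filter sees honest values.
    """

    pdff: np.ndarray
    t2star: np.ndarray
    fieldmap: np.ndarray
    r2star: np.ndarray
    voxel_spacing: tuple[float, float, float]
    t2star_valid: np.ndarray
    residual: np.ndarray
    eddy_phase: float = 0.0


# ---------------------------------------------------------------------------
# Variable-projection core
# ---------------------------------------------------------------------------

def _varpro_residual(
    sig: np.ndarray,
    te: np.ndarray,
    c: np.ndarray,
    psi: np.ndarray,
    r2s: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares misfit after projecting out complex (W, F).

    Parameters
    ----------
    sig : (N, V) complex
    te : (N,) seconds
    c : (N,) complex fat coefficients
    psi : (V,) or scalar, Hz
    r2s : (V,) or scalar, 1/s

    Returns
    -------
    (resid, w, f) : each shape (V,); resid is the sum of squared residuals,
    w and f the complex amplitudes at the optimum.
    """
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    r2s = np.atleast_1d(np.asarray(r2s, dtype=float))
    # basis column 1: phi_n = exp((i 2 pi psi - r2s) te_n); column 2: c_n phi_n
    expo = (2j * np.pi * psi - r2s)[None, :] * te[:, None]
    phi = np.exp(expo)  # (N, V)
    decay2 = np.exp(-2.0 * np.multiply.outer(te, r2s))  # |phi|^2
    g11 = decay2.sum(axis=0)
    g12 = (c[:, None] * decay2).sum(axis=0)
    g22 = ((np.abs(c) ** 2)[:, None] * decay2).sum(axis=0)
    b1 = (np.conj(phi) * sig).sum(axis=0)
    b2 = (np.conj(c)[:, None] * np.conj(phi) * sig).sum(axis=0)
    det = g11 * g22 - np.abs(g12) ** 2
    ss = (np.abs(sig) ** 2).sum(axis=0)

    # Rank-deficient Gram (e.g. degenerate single-peak spectrum at 0 ppm):
    # fall back to water-only projection.
    ok = det > 1e-12 * np.maximum(g11 * g22, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(ok, (g22 * b1 - g12 * b2) / det, b1 / np.maximum(g11, 1e-300))
        f = np.where(ok, (g11 * b2 - np.conj(g12) * b1) / det, 0.0)
    resid = ss - np.real(np.conj(b1) * w + np.conj(b2) * f)
    return np.maximum(resid, 0.0), w, f


def _grid_search(
    sig: np.ndarray,
    te: np.ndarray,
    c: np.ndarray,
    psi_grid: np.ndarray,
    r2s_grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best (psi, r2s) per voxel over a shared candidate grid.

    Returns (best_resid, best_psi, best_r2s), each shape (V,).
    """
    n_vox = sig.shape[1]
    best_resid = np.full(n_vox, np.inf)
    best_psi = np.zeros(n_vox)
    best_r2s = np.zeros(n_vox)
    ss = (np.abs(sig) ** 2).sum(axis=0)
    # Demodulation matrix over the psi grid is r2s-independent.
    pmat = np.exp(-2j * np.pi * np.multiply.outer(psi_grid, te))  # (P, N)
    abs_c2 = np.abs(c) ** 2
    for r2s in r2s_grid:
        decay = np.exp(-r2s * te)
        decay2 = decay * decay
        g11 = decay2.sum()
        g12 = (c * decay2).sum()
        g22 = (abs_c2 * decay2).sum()
        det = g11 * g22 - abs(g12) ** 2
        sig_d = sig * decay[:, None]
        b1 = pmat @ sig_d  # (P, V)
        b2 = (pmat * np.conj(c)[None, :]) @ sig_d
        if det > 1e-12 * max(g11 * g22, 1e-300):
            quad = (
                g22 * np.abs(b1) ** 2
                + g11 * np.abs(b2) ** 2
                - 2.0 * np.real(g12 * b2 * np.conj(b1))
            ) / det
        else:
            quad = np.abs(b1) ** 2 / max(g11, 1e-300)
        resid = ss[None, :] - quad  # (P, V)
        idx = np.argmin(resid, axis=0)
        cand = resid[idx, np.arange(n_vox)]
        better = cand < best_resid
        best_resid[better] = cand[better]
        best_psi[better] = psi_grid[idx[better]]
        best_r2s[better] = r2s
    return np.maximum(best_resid, 0.0), best_psi, best_r2s


_PATTERN_MOVES = [
    (1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1),
]


def _pattern_refine(
    sig: np.ndarray,
    te: np.ndarray,
    c: np.ndarray,
    psi: np.ndarray,
    r2s: np.ndarray,
    psi_step: float,
    r2s_step: float,
    psi_bounds: tuple,
    r2s_bounds: tuple,
    n_iter: int = 40,
    min_psi_step: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel pattern search around the grid optimum.

    ``psi_bounds`` / ``r2s_bounds`` may be scalars or per-voxel arrays.
    Steps halve whenever no neighbouring move improves a voxel's misfit, so
    the final parameter resolution is ``step * 2**-halvings``.
    """
    psi = psi.astype(float).copy()
    r2s = r2s.astype(float).copy()
    resid, _, _ = _varpro_residual(sig, te, c, psi, r2s)
    steps_psi = np.full(psi.shape, float(psi_step))
    steps_r2s = np.full(r2s.shape, float(r2s_step))
    for _ in range(n_iter):
        if np.all(steps_psi < min_psi_step):
            break
        improved = np.zeros(psi.shape, dtype=bool)
        for dp, dr in _PATTERN_MOVES:
            cand_psi = np.clip(psi + dp * steps_psi, psi_bounds[0], psi_bounds[1])
            cand_r2s = np.clip(r2s + dr * steps_r2s, r2s_bounds[0], r2s_bounds[1])
            cand_resid, _, _ = _varpro_residual(sig, te, c, cand_psi, cand_r2s)
            better = cand_resid < resid
            psi[better] = cand_psi[better]
            r2s[better] = cand_r2s[better]
            resid[better] = cand_resid[better]
            improved |= better
        shrink = ~improved
        steps_psi[shrink] *= 0.5
        steps_r2s[shrink] *= 0.5
    resid, w, f = _varpro_residual(sig, te, c, psi, r2s)
    return resid, psi, r2s


def _fit_batch(
    sig: np.ndarray,
    protocol: AcquisitionProtocol,
    spectrum: FatSpectrum,
    psi_search: tuple[float, float],
    r2s_search: tuple[float, float],
    psi_grid_step: float,
    r2s_grid_step: float,
    refine_iters: int = 40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Grid + refinement for a (N, V) signal batch.

    Returns (resid, psi, r2s, w, f).
    """
    te = protocol.echo_times
    c = spectrum.signal_coefficients(te, protocol.field_strength)
    psi_grid = np.arange(psi_search[0], psi_search[1] + 0.5 * psi_grid_step, psi_grid_step)
    r2s_grid = np.arange(r2s_search[0], r2s_search[1] + 0.5 * r2s_grid_step, r2s_grid_step)
    resid, psi, r2s = _grid_search(sig, te, c, psi_grid, r2s_grid)
    resid, psi, r2s = _pattern_refine(
        sig, te, c, psi, r2s,
        psi_step=psi_grid_step, r2s_step=r2s_grid_step,
        psi_bounds=psi_search, r2s_bounds=r2s_search,
        n_iter=refine_iters,
    )
    resid, w, f = _varpro_residual(sig, te, c, psi, r2s)
    return resid, psi, r2s, w, f


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def fit_voxel(
    signal: np.ndarray,
    protocol: AcquisitionProtocol,
    spectrum: FatSpectrum | None = None,
    psi_search: tuple[float, float] = (-200.0, 200.0),
    r2s_search: tuple[float, float] = (0.0, 300.0),
    psi_grid_step: float = 2.0,
    r2s_grid_step: float = 10.0,
    polish: bool = True,
) -> VoxelFit:
    """Fit the water-fat signal model to a single voxel's echo train.

    Variable projection over a ``(psi, R2*)`` candidate grid followed by
    per-voxel pattern search and (optionally) a Nelder-Mead polish.  The
    returned misfit is the global minimum over the searched region up to the
    refinement resolution; refinement can only improve on the grid optimum.

    Raises ``ValueError`` for NaN input or fewer than 4 echoes (with 6
    real unknowns -- psi, R2*, complex W and F -- at least 4 complex echoes
    are needed).  An all-zero signal returns W = F = 0 with
    ``converged=False``.
    """
    if spectrum is None:
        spectrum = make_default_spectrum()
    sig = np.asarray(signal, dtype=complex).reshape(-1)
    if sig.size != protocol.n_echoes:
        raise ValueError(f"signal has {sig.size} echoes, protocol declares {protocol.n_echoes}")
    if sig.size < 4:
        raise ValueError("need at least 4 echoes to separate water and fat with R2* and field map")
    if not np.all(np.isfinite(sig)):
        raise ValueError("signal contains NaN or infinite values")
    if psi_search[0] >= psi_search[1] or r2s_search[0] > r2s_search[1]:
        raise ValueError("empty search range")
    if np.all(sig == 0):
        return VoxelFit(0.0, 0.0, 0.0, 0.0, 0.0, converged=False)

    resid, psi, r2s, w, f = _fit_batch(
        sig[:, None], protocol, spectrum, psi_search, r2s_search,
        psi_grid_step, r2s_grid_step,
    )
    best = (float(resid[0]), float(psi[0]), float(r2s[0]), complex(w[0]), complex(f[0]))

    if polish:
        te = protocol.echo_times
        c = spectrum.signal_coefficients(te, protocol.field_strength)

        def objective(params: np.ndarray) -> float:
            p = np.clip(params[0], *psi_search)
            r = np.clip(params[1], *r2s_search)
            return float(_varpro_residual(sig[:, None], te, c, p, r)[0][0])

        res = optimize.minimize(
            objective, x0=[best[1], best[2]], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-14, "maxiter": 400},
        )
        if res.fun < best[0]:
            p = float(np.clip(res.x[0], *psi_search))
            r = float(np.clip(res.x[1], *r2s_search))
            rr, ww, ff = _varpro_residual(sig[:, None], te, c, p, r)
            best = (float(rr[0]), p, r, complex(ww[0]), complex(ff[0]))

    resid_v, psi_v, r2s_v, w_v, f_v = best
    at_bound = bool(
        np.isclose(r2s_v, r2s_search[0])
        or np.isclose(r2s_v, r2s_search[1])
        or np.isclose(psi_v, psi_search[0])
        or np.isclose(psi_v, psi_search[1])
    )
    return VoxelFit(
        water=float(np.abs(w_v)),
        fat=float(np.abs(f_v)),
        fieldmap_hz=psi_v,
        r2star=r2s_v,
        residual=resid_v,
        converged=True,
        at_bound=at_bound,
    )


def separate(
    series: EchoSeries,
    spectrum: FatSpectrum | None = None,
    psi_search: tuple[float, float] = (-200.0, 200.0),
    r2s_search: tuple[float, float] = (0.0, 300.0),
    psi_grid_step: float = 4.0,
    r2s_grid_step: float = 20.0,
    eddy: "str | float" = "off",
    swap_filter: bool = True,
    swap_threshold_hz: float = 30.0,
) -> QuantMaps:
    """Water-fat separation of a full volume into PDFF / T2* / field maps.

    Parameters
    ----------
    series : EchoSeries
    spectrum : FatSpectrum, optional
        Defaults to the six-peak spectrum.
    psi_search, r2s_search : (low, high)
        Field-map (Hz) and R2* (1/s) search ranges.
    eddy : "off", "estimate", or float
        Echo-parity eddy-current phase handling: ignore, estimate globally
        before fitting, or apply a known theta (radians).
    swap_filter : bool
        Apply the field-map consistency pass: median-filter the fitted field
        map and re-fit voxels deviating by more than ``swap_threshold_hz``
        with the field map constrained near the local median.

    Returns
    -------
    QuantMaps
        ``pdff = 100 |F| / (|W| + |F|)`` (0 where the signal is zero),
        ``t2star = 1000 / R2*`` ms where R2* is positive and off the search
        bounds, NaN otherwise.
    """
    if spectrum is None:
        spectrum = make_default_spectrum()
    shape = series.volume_shape
    n_echo = series.protocol.n_echoes
    sig_full = series.signal.reshape(n_echo, -1)

    theta = 0.0
    if eddy == "estimate":
        theta = estimate_eddy_phase(series, spectrum, psi_search=psi_search, r2s_search=r2s_search)
    elif isinstance(eddy, (int, float)) and not isinstance(eddy, bool):
        theta = float(eddy)
    elif eddy != "off":
        raise ValueError(f"eddy must be 'off', 'estimate' or a float, got {eddy!r}")
    if theta != 0.0:
        signs = series.protocol.eddy_signs
        sig_full = sig_full * np.exp(-1j * signs * theta)[:, None]

    nonzero = np.abs(sig_full).sum(axis=0) > 0
    sig = sig_full[:, nonzero]

    resid, psi, r2s, w, f = _fit_batch(
        sig, series.protocol, spectrum, psi_search, r2s_search,
        psi_grid_step, r2s_grid_step,
    )

    n_vox = sig_full.shape[1]
    psi_map = np.zeros(n_vox)
    psi_map[nonzero] = psi

    if swap_filter:
        psi_vol = psi_map.reshape(shape)
        psi_med = ndimage.median_filter(psi_vol, size=3).reshape(-1)
        deviant = nonzero & (np.abs(psi_map - psi_med) > swap_threshold_hz)
        if np.any(deviant):
            te = series.protocol.echo_times
            c = spectrum.signal_coefficients(te, series.protocol.field_strength)
            sig_d = sig_full[:, deviant]
            med = psi_med[deviant]
            lo = np.maximum(med - 1.5 * swap_threshold_hz, psi_search[0])
            hi = np.minimum(med + 1.5 * swap_threshold_hz, psi_search[1])
            # restart from the local median, search only near it
            r_resid, r_psi, r_r2s = _grid_search(
                sig_d, te, c, np.array([0.0]), np.arange(
                    r2s_search[0], r2s_search[1] + 0.5 * r2s_grid_step, r2s_grid_step)
            )
            r_psi = med.copy()
            r_resid, r_psi, r_r2s = _pattern_refine(
                sig_d, te, c, r_psi, r_r2s,
                psi_step=psi_grid_step, r2s_step=r2s_grid_step,
                psi_bounds=(lo, hi), r2s_bounds=r2s_search,
            )
            r_resid, r_w, r_f = _varpro_residual(sig_d, te, c, r_psi, r_r2s)
            # keep the constrained re-fit for these voxels (the smoothness
            # prior overrides the raw per-voxel optimum)
            dev_in_fit = deviant[nonzero]
            psi[dev_in_fit] = r_psi
            r2s[dev_in_fit] = r_r2s
            w[dev_in_fit] = r_w
            f[dev_in_fit] = r_f
            resid[dev_in_fit] = r_resid
            psi_map[deviant] = r_psi

    w_mag = np.zeros(n_vox)
    f_mag = np.zeros(n_vox)
    r2s_map = np.zeros(n_vox)
    resid_map = np.zeros(n_vox)
    w_mag[nonzero] = np.abs(w)
    f_mag[nonzero] = np.abs(f)
    r2s_map[nonzero] = r2s
    resid_map[nonzero] = resid

    tot = w_mag + f_mag
    with np.errstate(divide="ignore", invalid="ignore"):
        pdff = np.where(tot > 0, 100.0 * f_mag / np.where(tot > 0, tot, 1.0), 0.0)

    eps_b = 1e-9
    valid = (
        nonzero
        & (r2s_map > max(r2s_search[0], 0.0) + eps_b)
        & (r2s_map < r2s_search[1] - eps_b)
    )
    t2star = np.full(n_vox, np.nan)
    t2star[valid] = 1000.0 / r2s_map[valid]

    return QuantMaps(
        pdff=pdff.reshape(shape),
        t2star=t2star.reshape(shape),
        fieldmap=psi_map.reshape(shape),
        r2star=r2s_map.reshape(shape),
        voxel_spacing=series.protocol.voxel_spacing,
        t2star_valid=valid.reshape(shape),
        residual=resid_map.reshape(shape),
        eddy_phase=theta,
    )


def estimate_eddy_phase(
    series: EchoSeries,
    spectrum: FatSpectrum | None = None,
    psi_search: tuple[float, float] = (-200.0, 200.0),
    r2s_search: tuple[float, float] = (0.0, 300.0),
    theta_bounds: tuple[float, float] = (-0.6, 0.6),
    n_sample: int = 96,
) -> float:
    """Estimate the global echo-parity eddy-current phase theta (radians).

    The ``n_sample`` strongest-signal voxels are pooled and the corrected
    signal ``s_n * exp(-i (-1)**n theta)`` is fitted for a 1D search over
    theta; the theta minimising the pooled misfit is returned.  For a
    monopolar protocol there is no echo-parity phase and 0 is returned with
    a warning.
    """
    if spectrum is None:
        spectrum = make_default_spectrum()
    if not series.protocol.bipolar:
        warnings.warn("protocol is monopolar: no echo-parity eddy phase to estimate; returning 0")
        return 0.0

    sig_full = series.signal.reshape(series.protocol.n_echoes, -1)
    mag = np.abs(sig_full).sum(axis=0)
    n_sample = min(n_sample, int(np.count_nonzero(mag > 0)))
    if n_sample == 0:
        return 0.0
    order = np.argsort(mag)[::-1][:n_sample]
    sig = sig_full[:, order]
    te = series.protocol.echo_times
    c = spectrum.signal_coefficients(te, series.protocol.field_strength)
    signs = series.protocol.eddy_signs
    psi_grid = np.arange(psi_search[0], psi_search[1] + 2.0, 4.0)
    r2s_grid = np.arange(r2s_search[0], r2s_search[1] + 10.0, 20.0)

    def pooled_misfit(theta: float) -> float:
        corr = sig * np.exp(-1j * signs * theta)[:, None]
        resid, psi, r2s = _grid_search(corr, te, c, psi_grid, r2s_grid)
        resid, _, _ = _pattern_refine(
            corr, te, c, psi, r2s, psi_step=4.0, r2s_step=20.0,
            psi_bounds=psi_search, r2s_bounds=r2s_search, n_iter=22,
        )
        return float(resid.sum())

    res = optimize.minimize_scalar(
        pooled_misfit, bounds=theta_bounds, method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x)
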