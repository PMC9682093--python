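"""Single-molecule spot detection by anisotropic 3D Gaussian fitting.

A diffraction-limited smFISH spot is modeled as a 3D Gaussian with lateral
(XY) symmetry:

    I(x, y, z) = b + A * exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma_xy^2)
                             - (z-z0)^2 / (2 sigma_z^2))

Detection proceeds in three stages, in the style of AIRLOCALIZE-type
detectors: a global intensity threshold rejects noise, locally brightest
voxels above the threshold become candidates, and a least-squares Gaussian
fit around each candidate yields subvoxel positions, amplitudes and local
backgrounds. Nearby duplicate fits are merged.

Widths are carried in nanometres (the field's convention for PSF sizes);
coordinates in micrometres using the voxel-center convention of
:mod:`smfish3d.core_io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree

from .core_io import ImageStack, SpotTable, empty_spot_frame

TWO_PI_32 = (2.0 * np.pi) ** 1.5


class EstimationError(RuntimeError):
    """PSF estimation failed (too few usable fits)."""


@dataclass
class PSFParams:
    """Gaussian widths of the spot model (the effective PSF), in nm.

    sigma_z >= sigma_xy for any realistic objective; a violation is allowed
    but warned about, since it usually means swapped parameters.
    """

    sigma_xy: float = 120.0
    sigma_z: float = 400.0

    def __post_init__(self) -> None:
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ValueError("PSF sigmas must be positive")
        if self.sigma_z < self.sigma_xy:
            warnings.warn("sigma_z < sigma_xy is unusual; check parameter order", stacklevel=2)

    @property
    def sigma_xy_um(self) -> float:
        return self.sigma_xy / 1000.0

    @property
    def sigma_z_um(self) -> float:
        return self.sigma_z / 1000.0


@dataclass
class SpotCandidate:
    """A locally brightest voxel above the global threshold."""

    index_zyx: tuple[int, int, int]
    intensity: float


@dataclass
class Spot:
    """One fitted molecule."""

    center_um: tuple[float, float, float]  # (x0, y0, z0)
    amplitude: float
    background: float
    sigma_xy_nm: float
    sigma_z_nm: float
    integrated_intensity: float  # A * (2*pi)^(3/2) * sigma_xy^2 * sigma_z, intensity*um^3
    residual_rms: float = 0.0
    label: int = 0


@dataclass
class FitFailure:
    """A candidate whose Gaussian fit was rejected, with the reason."""

    index_zyx: tuple[int, int, int]
    reason: str


def integrated_intensity(amplitude: float, psf_xy_um: float, psf_z_um: float) -> float:
    """Closed-form volume integral of the 3D Gaussian (intensity * µm^3)."""
    return amplitude * TWO_PI_32 * psf_xy_um**2 * psf_z_um


# ---------------------------------------------------------------------------
# Candidate detection
# ---------------------------------------------------------------------------


def detect_candidates(
    stack: ImageStack, channel: int | str, threshold: float
) -> list[SpotCandidate]:
    """Locally brightest voxels with intensity >= threshold.

    A candidate is a voxel that is the strict maximum of its 26-neighborhood.
    On a flat plateau that is itself a local maximum, the tie is broken by
    keeping the lexicographically smallest ``(z, y, x)`` voxel. Candidates
    are returned sorted by descending intensity.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    img = stack.channel(channel)
    # Max over the 26 neighbors (footprint excludes the center); -inf padding
    # lets boundary voxels qualify.
    footprint = np.ones((3, 3, 3), bool)
    footprint[1, 1, 1] = False
    nbr_max = ndimage.maximum_filter(img, footprint=footprint, mode="constant", cval=-np.inf)

    strict = (img > nbr_max) & (img >= threshold)
    out = [tuple(int(v) for v in idx) for idx in np.argwhere(strict)]

    # Plateaus: voxels equal to their neighborhood max. Adjacent plateau
    # members necessarily share the same value, so 26-connected components of
    # this set are constant-valued; each is one candidate at its smallest index.
    plateau = (img == nbr_max) & (img >= threshold)
    if plateau.any():
        lab, _ = ndimage.label(plateau, structure=np.ones((3, 3, 3), int))
        for zz, yy, xx in ndimage.value_indices(lab, ignore_value=0).values():
            order = np.lexsort((xx, yy, zz))
            out.append((int(zz[order[0]]), int(yy[order[0]]), int(xx[order[0]])))

    cands = [SpotCandidate(index_zyx=i, intensity=float(img[i])) for i in out]
    cands.sort(key=lambda c: (-c.intensity, c.index_zyx))
    return cands


# ---------------------------------------------------------------------------
# Gaussian fitting
# ---------------------------------------------------------------------------


def _window_slices(
    index_zyx: Sequence[int],
    shape: Sequence[int],
    half_vox: Sequence[int],
) -> tuple[slice, slice, slice]:
    return tuple(
        slice(max(0, i - h), min(n, i + h + 1))
        for i, n, h in zip(index_zyx, shape, half_vox)
    )


def _model(coords, x0, y0, z0, A, b, sxy_um, sz_um):
    zc, yc, xc = coords
    r2_xy = (xc - x0) ** 2 + (yc - y0) ** 2
    return b + A * np.exp(-r2_xy / (2 * sxy_um**2) - (zc - z0) ** 2 / (2 * sz_um**2))


def fit_spot(
    stack: ImageStack,
    channel: int | str,
    candidate: SpotCandidate,
    psf: PSFParams,
    fit_window_sigmas: float = 2.0,
    mode: str = "fixed_sigma",
    residual_factor: float = 10.0,
) -> Spot | FitFailure:
    """Least-squares Gaussian fit around a candidate voxel.

    ``fixed_sigma`` fits (x0, y0, z0, A, b) with the widths pinned to ``psf``;
    ``free_sigma`` additionally fits sigma_xy and sigma_z (used for PSF
    estimation). The default window of ±2 sigma per axis keeps neighboring
    spots (which the simulator guarantees are >= 3 scaled sigma away) out of
    the fitted region; a wider window lets a bright neighbor capture the fit.
    Failure conditions: the clipped window holds fewer than 10 voxels, the
    fitted amplitude is non-positive, the center converges onto the window
    boundary, or the residual RMS exceeds ``residual_factor`` times the
    robust local noise level.
    """
    if mode not in ("fixed_sigma", "free_sigma"):
        raise ValueError(f"unknown fit mode {mode!r}")
    img = stack.channel(channel)
    dz, dy, dx = stack.voxel_size_um
    half = (
        max(1, int(np.ceil(fit_window_sigmas * psf.sigma_z_um / dz))),
        max(1, int(np.ceil(fit_window_sigmas * psf.sigma_xy_um / dy))),
        max(1, int(np.ceil(fit_window_sigmas * psf.sigma_xy_um / dx))),
    )
    sl = _window_slices(candidate.index_zyx, img.shape, half)
    win = img[sl]
    if win.size < 10:
        return FitFailure(candidate.index_zyx, "window too small")

    # Voxel-center physical coordinates of the window.
    zi = np.arange(sl[0].start, sl[0].stop)
    yi = np.arange(sl[1].start, sl[1].stop)
    xi = np.arange(sl[2].start, sl[2].stop)
    zc = ((zi + 0.5) * dz)[:, None, None]
    yc = ((yi + 0.5) * dy)[None, :, None]
    xc = ((xi + 0.5) * dx)[None, None, :]
    coords = (zc, yc, xc)
    data = win.ravel()

    b0 = float(np.median(win))
    cz, cy, cx = candidate.index_zyx
    p0_center = ((cx + 0.5) * dx, (cy + 0.5) * dy, (cz + 0.5) * dz)
    A0 = max(float(img[cz, cy, cx]) - b0, 1e-6)
    lo_x, hi_x = (xi[0] + 0.5) * dx, (xi[-1] + 0.5) * dx
    lo_y, hi_y = (yi[0] + 0.5) * dy, (yi[-1] + 0.5) * dy
    lo_z, hi_z = (zi[0] + 0.5) * dz, (zi[-1] + 0.5) * dz

    if mode == "fixed_sigma":
        def resid(p):
            x0, y0, z0, A, b = p
            return (_model(coords, x0, y0, z0, A, b, psf.sigma_xy_um, psf.sigma_z_um)
                    - win).ravel()

        p0 = [*p0_center, A0, b0]
        lb = [lo_x, lo_y, lo_z, 0.0, -np.inf]
        ub = [hi_x, hi_y, hi_z, np.inf, np.inf]
    else:
        def resid(p):
            x0, y0, z0, A, b, sxy, sz = p
            return (_model(coords, x0, y0, z0, A, b, sxy, sz) - win).ravel()

        p0 = [*p0_center, A0, b0, psf.sigma_xy_um, psf.sigma_z_um]
        lb = [lo_x, lo_y, lo_z, 0.0, -np.inf, 0.2 * psf.sigma_xy_um, 0.2 * psf.sigma_z_um]
        ub = [hi_x, hi_y, hi_z, np.inf, np.inf, 5 * psf.sigma_xy_um, 5 * psf.sigma_z_um]

    try:
        res = optimize.least_squares(resid, p0, bounds=(lb, ub), method="trf", x_scale="jac")
    except Exception as exc:  # numerical breakdown
        return FitFailure(candidate.index_zyx, f"optimizer error: {exc}")
    if not np.all(np.isfinite(res.x)):
        return FitFailure(candidate.index_zyx, "non-finite fit")

    x0, y0, z0, A, b = res.x[:5]
    if A <= 1e-9:
        return FitFailure(candidate.index_zyx, "non-positive amplitude")
    edge_tol = 1e-6
    if (x0 - lo_x < edge_tol or hi_x - x0 < edge_tol
            or y0 - lo_y < edge_tol or hi_y - y0 < edge_tol
            or z0 - lo_z < edge_tol or hi_z - z0 < edge_tol):
        return FitFailure(candidate.index_zyx, "center left the fit window")

    r = resid(res.x)
    rms = float(np.sqrt(np.mean(r**2)))
    noise = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    noise = max(noise, 1e-9 * (A + abs(b)))
    if rms > residual_factor * noise:
        return FitFailure(candidate.index_zyx, "residual exceeds local noise bound")

    if mode == "free_sigma":
        sxy_um, sz_um = res.x[5], res.x[6]
    else:
        sxy_um, sz_um = psf.sigma_xy_um, psf.sigma_z_um
    return Spot(
        center_um=(float(x0), float(y0), float(z0)),
        amplitude=float(A),
        background=float(b),
        sigma_xy_nm=float(sxy_um * 1000),
        sigma_z_nm=float(sz_um * 1000),
        integrated_intensity=integrated_intensity(float(A), sxy_um, sz_um),
        residual_rms=rms,
    )


# ---------------------------------------------------------------------------
# PSF estimation
# ---------------------------------------------------------------------------


def estimate_psf(
    stack: ImageStack,
    channel: int | str,
    picked_spots: Iterable[Sequence[int]],
    initial: Optional[PSFParams] = None,
) -> tuple[PSFParams, dict]:
    """Estimate the spot-model widths from user-picked spot locations.

    Each pick (an approximate ``(z, y, x)`` voxel) is re-fit with free widths;
    the median fitted sigma_xy and sigma_z over the surviving fits define the
    PSF. Returns the estimate plus a report with per-spot fits and dispersion
    (median absolute deviation, nm).
    """
    picks = [tuple(int(v) for v in p) for p in picked_spots]
    if len(picks) < 3:
        raise ValueError(f"need >= 3 picked spots, got {len(picks)}")
    psf0 = initial or PSFParams()
    img = stack.channel(channel)
    sxy, sz = [], []
    for p in picks:
        cand = SpotCandidate(index_zyx=p, intensity=float(img[p]))
        fit = fit_spot(stack, channel, cand, psf0, mode="free_sigma")
        if isinstance(fit, FitFailure):
            warnings.warn(f"PSF pick at {p} dropped: {fit.reason}", stacklevel=2)
            continue
        if fit.amplitude < 3.0 * fit.residual_rms:
            # indistinguishable from local noise: not a usable size reference
            warnings.warn(f"PSF pick at {p} dropped: amplitude within noise",
                          stacklevel=2)
            continue
        sxy.append(fit.sigma_xy_nm)
        sz.append(fit.sigma_z_nm)
    if len(sxy) < 3:
        raise EstimationError(
            f"only {len(sxy)} of {len(picks)} picks produced usable fits (need >= 3)"
        )
    report = {
        "n_used": len(sxy),
        "n_picked": len(picks),
        "sigma_xy_nm_all": sxy,
        "sigma_z_nm_all": sz,
        "mad_xy_nm": float(np.median(np.abs(np.array(sxy) - np.median(sxy)))),
        "mad_z_nm": float(np.median(np.abs(np.array(sz) - np.median(sz)))),
    }
    return PSFParams(sigma_xy=float(np.median(sxy)), sigma_z=float(np.median(sz))), report


# ---------------------------------------------------------------------------
# Duplicate merging and the composed detector
# ---------------------------------------------------------------------------


def dedupe_spots(spots: list[Spot], psf: PSFParams) -> list[Spot]:
    """Merge fits closer than one anisotropically scaled sigma.

    Distance metric: sqrt((dx^2 + dy^2)/sigma_xy^2 + dz^2/sigma_z^2) < 1
    merges two spots, keeping the brighter fit (greedy by descending
    amplitude). Output pairwise separations are >= the merge radius.
    """
    if len(spots) <= 1:
        return list(spots)
    order = sorted(range(len(spots)), key=lambda i: -spots[i].amplitude)
    pts = np.array(
        [
            (
                s.center_um[0] / psf.sigma_xy_um,
                s.center_um[1] / psf.sigma_xy_um,
                s.center_um[2] / psf.sigma_z_um,
            )
            for s in spots
        ]
    )
    tree = cKDTree(pts)
    keep: list[int] = []
    suppressed = np.zeros(len(spots), bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        for j in tree.query_ball_point(pts[i], 1.0):
            if j != i:
                suppressed[j] = True
    keep.sort()
    return [spots[i] for i in keep]


def spots_to_table(
    spots: list[Spot], source_image: str = "", params: Optional[dict] = None
) -> SpotTable:
    if not spots:
        return SpotTable(df=empty_spot_frame(), source_image=source_image, params=params or {})
    df = pd.DataFrame(
        {
            "x_um": [s.center_um[0] for s in spots],
            "y_um": [s.center_um[1] for s in spots],
            "z_um": [s.center_um[2] for s in spots],
            "amplitude": [s.amplitude for s in spots],
            "background": [s.background for s in spots],
            "sigma_xy_nm": [s.sigma_xy_nm for s in spots],
            "sigma_z_nm": [s.sigma_z_nm for s in spots],
            "integrated_intensity": [s.integrated_intensity for s in spots],
            "label": [s.label for s in spots],
        }
    )
    return SpotTable(df=df, source_image=source_image, params=params or {})


def resolve_threshold(
    stack: ImageStack, channel: int | str, threshold: float, mode: str = "absolute"
) -> float:
    """Turn a configured threshold into absolute intensity units.

    ``absolute`` uses the value as-is; ``mad`` reads it as a multiple of the
    robust (MAD-based) noise SD above the channel median, which transfers
    across acquisition batches with different backgrounds.
    """
    if mode == "absolute":
        return float(threshold)
    if mode == "mad":
        img = stack.channel(channel)
        med = float(np.median(img))
        sd = 1.4826 * float(np.median(np.abs(img - med)))
        return med + float(threshold) * sd
    raise ValueError(f"unknown threshold mode {mode!r}")


def detect_spots(
    stack: ImageStack,
    channel: int | str,
    threshold: float,
    psf: PSFParams,
    mode: str = "fixed_sigma",
    threshold_mode: str = "absolute",
    fit_window_sigmas: float = 2.0,
    residual_factor: float = 10.0,
    max_candidates: Optional[int] = None,
    source_image: str = "",
) -> SpotTable:
    """Full detector: threshold -> candidates -> fit -> filter -> dedupe.

    After fitting, spots whose amplitude does not clear the same margin above
    their fitted background as the detection threshold does above the image
    background are rejected; this suppresses fits to noise fluctuations that
    happened to produce a candidate voxel.
    """
    t_abs = resolve_threshold(stack, channel, threshold, threshold_mode)
    img = stack.channel(channel)
    baseline = float(np.median(img))
    amp_floor = max(0.0, t_abs - baseline)

    cands = detect_candidates(stack, channel, t_abs)
    if max_candidates is not None:
        cands = cands[:max_candidates]
    fitted: list[Spot] = []
    for c in cands:
        fit = fit_spot(
            stack, channel, c, psf,
            fit_window_sigmas=fit_window_sigmas, mode=mode,
            residual_factor=residual_factor,
        )
        if isinstance(fit, FitFailure):
            continue
        if fit.amplitude < amp_floor:
            continue
        fitted.append(fit)
    fitted = dedupe_spots(fitted, psf)
    params = {
        "threshold": threshold,
        "threshold_mode": threshold_mode,
        "threshold_absolute": t_abs,
        "sigma_xy_nm": psf.sigma_xy,
        "sigma_z_nm": psf.sigma_z,
        "fit_mode": mode,
        "fit_window_sigmas": fit_window_sigmas,
        "residual_factor": residual_factor,
    }
    table = spots_to_table(fitted, source_image=source_image, params=params)
    table.check_bounds(stack)
    return table
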