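"""Synthetic fluorescence-stack simulator with ground truth.

Emulates the statistical structure the pipeline assumes so every downstream
stage is testable without microscope data:

* a membrane-marker channel: contiguous ellipsoidal cells with a bright
  membrane shell and strong multiplicative intracellular texture, whose pixel
  histogram is bimodal (background mode near zero, signal mode well above);
* an smFISH channel: a sum of anisotropic 3D Gaussian spots (lateral width
  sigma_xy, axial width sigma_z) over a flat background, with Poisson shot
  noise and Gaussian read noise, and optional exponential depth attenuation;
* a nuclear channel: bright spheres inside each cell.

Everything is deterministic given the seed, and every stack comes with exact
label masks, the true spot catalog and per-cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import ImageStack, LabelMask
from .spots import PSFParams


class PlacementError(RuntimeError):
    """Cells could not be placed inside the canvas after bounded retries."""


@dataclass
class ScenarioParams:
    """Everything that defines one simulated acquisition.

    Defaults describe the study system: a small cluster of contiguous clock
    neurons (radius ~2.5 µm), ~80 transcripts per cell at the expression peak,
    PSF widths sigma_xy = 120 nm / sigma_z = 400 nm, and photon-limited noise
    giving a peak-amplitude SNR well above the detector's working point.
    """

    n_cells: int = 4
    cell_radius_um: tuple[float, float] = (2.5, 0.2)  # mean, sd
    nucleus_radius_fraction: float = 0.5
    spots_per_cell: float = 80
    spots_distribution: str = "fixed"  # or "poisson"
    psf: PSFParams = field(default_factory=PSFParams)
    marker_heterogeneity: float = 0.4  # multiplicative texture strength (log-sd)
    background_level: float = 100.0
    spot_amplitude: float = 500.0
    amplitude_cv: float = 0.10  # lognormal sd as a fraction of the mean
    photon_gain: float = 1.0
    read_noise_sd: float = 5.0
    depth_attenuation_per_um: float = 0.0
    # Minimum pairwise spot separation, in anisotropically scaled sigma units
    # (sqrt((dxy/sigma_xy)^2 + (dz/sigma_z)^2)). Two equal Gaussians merge
    # into a single maximum at 2 sigma separation, so 3 keeps every planted
    # spot individually resolvable; 0 allows overlap (stress-test mode with
    # ambiguous ground truth).
    min_spot_separation_sigmas: float = 3.0
    shape_zyx: tuple[int, int, int] = (32, 256, 256)
    voxel_size_um: tuple[float, float, float] = (0.2, 0.05, 0.05)
    marker_interior_level: float = 150.0
    marker_membrane_level: float = 320.0
    marker_background_level: float = 8.0
    membrane_thickness_fraction: float = 0.12
    nuclear_level: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.cell_radius_um[0] <= 0:
            raise ValueError("cell radius must be positive")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ValueError("nucleus_radius_fraction must be in (0, 1)")
        if self.depth_attenuation_per_um < 0:
            raise ValueError("depth attenuation must be >= 0")
        if self.marker_heterogeneity < 0:
            raise ValueError("marker_heterogeneity must be >= 0")
        if self.spots_distribution not in ("fixed", "poisson"):
            raise ValueError("spots_distribution must be 'fixed' or 'poisson'")

    @property
    def background_noise_sd(self) -> float:
        """Predicted noise SD on a background voxel of the smFISH channel."""
        shot_var = self.background_level / self.photon_gain
        return float(np.sqrt(shot_var + self.read_noise_sd**2))

    @property
    def snr(self) -> float:
        """Mean peak amplitude over background noise SD."""
        return self.spot_amplitude / self.background_noise_sd


@dataclass
class GroundTruth:
    """Exact masks, spot catalog and per-cell counts for one simulated stack."""

    cell_mask: LabelMask
    nucleus_mask: LabelMask
    spots: pd.DataFrame  # columns x_um, y_um, z_um, amplitude, label (0 = extracellular)
    per_cell_counts: dict[int, int]

    def __post_init__(self) -> None:
        counted = self.spots[self.spots["label"] > 0]["label"].value_counts().to_dict()
        for lab in self.cell_mask.label_ids:
            if self.per_cell_counts.get(int(lab), 0) != counted.get(lab, 0):
                raise ValueError("per-cell counts inconsistent with the spot catalog")

    @property
    def extracellular_count(self) -> int:
        return int((self.spots["label"] == 0).sum())


# ---------------------------------------------------------------------------
# Spot rendering
# ---------------------------------------------------------------------------


def render_gaussian_spot(
    center_um: tuple[float, float, float],
    amplitude: float,
    psf: PSFParams,
    canvas: ImageStack,
    channel: int | str,
) -> ImageStack:
    """Accumulate one anisotropic 3D Gaussian onto a canvas channel.

    The Gaussian is evaluated at voxel centers and truncated at ±4 sigma per
    axis (tails outside the canvas are silently clipped). The same pointwise
    model is used by the fitting routines, so noise-free recovery is exact.
    """
    idx = canvas.channel_index(channel)
    _render_into(
        canvas.voxels[idx], canvas.voxel_size_um, center_um, amplitude, psf
    )
    return canvas


def _render_into(vol, voxel_size_um, center_um, amplitude, psf: PSFParams) -> None:
    dz, dy, dx = voxel_size_um
    x0, y0, z0 = center_um
    sxy, sz = psf.sigma_xy_um, psf.sigma_z_um
    nz, ny, nx = vol.shape
    # ±4 sigma support, in voxel indices (voxel i covers [(i)*d, (i+1)*d)).
    z_lo = max(0, int(np.floor((z0 - 4 * sz) / dz - 0.5)))
    z_hi = min(nz, int(np.ceil((z0 + 4 * sz) / dz - 0.5)) + 1)
    y_lo = max(0, int(np.floor((y0 - 4 * sxy) / dy - 0.5)))
    y_hi = min(ny, int(np.ceil((y0 + 4 * sxy) / dy - 0.5)) + 1)
    x_lo = max(0, int(np.floor((x0 - 4 * sxy) / dx - 0.5)))
    x_hi = min(nx, int(np.ceil((x0 + 4 * sxy) / dx - 0.5)) + 1)
    if z_lo >= z_hi or y_lo >= y_hi or x_lo >= x_hi:
        return
    gz = np.exp(-((np.arange(z_lo, z_hi) + 0.5) * dz - z0) ** 2 / (2 * sz**2))
    gy = np.exp(-((np.arange(y_lo, y_hi) + 0.5) * dy - y0) ** 2 / (2 * sxy**2))
    gx = np.exp(-((np.arange(x_lo, x_hi) + 0.5) * dx - x0) ** 2 / (2 * sxy**2))
    vol[z_lo:z_hi, y_lo:y_hi, x_lo:x_hi] += amplitude * (
        gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _place_cells(params: ScenarioParams, rng: np.random.Generator):
    """Place ellipsoid cells adjacent to each other inside the canvas.

    Returns (centers_um (z,y,x), semi_axes_um (z,y,x)) per cell. Cells touch
    (center distance ~ sum of mean radii) to mimic contiguous neuron clusters.
    """
    ext = tuple(n * s for n, s in zip(params.shape_zyx, params.voxel_size_um))
    centers: list[np.ndarray] = []
    axes: list[np.ndarray] = []
    mean_r, sd_r = params.cell_radius_um
    for i in range(params.n_cells):
        r = max(0.3 * mean_r, rng.normal(mean_r, sd_r))
        ratios = rng.uniform(1.0, 1.5, size=3)
        semi = r * ratios / ratios.prod() ** (1 / 3)  # volume of a sphere of radius r
        semi = np.minimum(semi, np.array(ext) / 2 * 0.95)
        placed = False
        for _ in range(500):
            if not centers:
                c = np.array(ext) / 2 + rng.uniform(-0.3, 0.3, 3)
            else:
                ref = centers[rng.integers(len(centers))]
                theta = rng.uniform(0, 2 * np.pi)
                # cluster mostly laterally; mild z offset keeps cells in-slab
                direction = np.array(
                    [rng.uniform(-0.15, 0.15), np.sin(theta), np.cos(theta)]
                )
                direction /= np.linalg.norm(direction)
                dist = (np.mean(axes[-1]) + np.mean(semi)) * rng.uniform(0.95, 1.05)
                c = ref + direction * dist
            margin = semi * 0.8
            if np.any(c < margin) or np.any(c > np.array(ext) - margin):
                continue
            too_close = False
            for cj, aj in zip(centers, axes):
                if np.linalg.norm(c - cj) < 0.8 * (np.mean(semi) + np.mean(aj)):
                    too_close = True
                    break
            if not too_close:
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{params.n_cells} after 500 attempts"
            )
        centers.append(c)
        axes.append(semi)
    return centers, axes


def _normalized_radius(params: ScenarioParams, center, semi):
    """rho(z, y, x): 1 on the ellipsoid surface, < 1 inside, on a local box."""
    dz, dy, dx = params.voxel_size_um
    nz, ny, nx = params.shape_zyx
    lo = [max(0, int((c - a) / d) - 1) for c, a, d in zip(center, semi, (dz, dy, dx))]
    hi = [
        min(n, int((c + a) / d) + 2)
        for c, a, d, n in zip(center, semi, (dz, dy, dx), (nz, ny, nx))
    ]
    zc = ((np.arange(lo[0], hi[0]) + 0.5) * dz - center[0]) / semi[0]
    yc = ((np.arange(lo[1], hi[1]) + 0.5) * dy - center[1]) / semi[1]
    xc = ((np.arange(lo[2], hi[2]) + 0.5) * dx - center[2]) / semi[2]
    rho = np.sqrt(
        zc[:, None, None] ** 2 + yc[None, :, None] ** 2 + xc[None, None, :] ** 2
    )
    return (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2])), rho


def _sample_point_in_ellipsoid(rng, center, semi, max_rho=0.92):
    while True:
        u = rng.uniform(-1, 1, 3)
        r = np.linalg.norm(u)
        if 1e-9 < r <= 1:
            rho = max_rho * rng.uniform(0, 1) ** (1 / 3)
            return center + u / r * rho * semi


def _add_noise(vol, params: ScenarioParams, rng) -> np.ndarray:
    g = params.photon_gain
    noisy = rng.poisson(np.maximum(vol, 0) * g).astype(np.float64) / g
    noisy += rng.normal(0.0, params.read_noise_sd, size=vol.shape)
    return np.maximum(noisy, 0.0)


# ---------------------------------------------------------------------------
# Full-stack simulation
# ---------------------------------------------------------------------------


def simulate_stack(params: ScenarioParams) -> tuple[ImageStack, GroundTruth]:
    """Render one 3-channel stack (marker, smFISH, DAPI) with ground truth."""
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape_zyx
    dz, dy, dx = params.voxel_size_um

    centers, axes = _place_cells(params, rng)

    cell_labels = np.zeros((nz, ny, nx), np.int32)
    nucleus_labels = np.zeros((nz, ny, nx), np.int32)
    marker = np.full((nz, ny, nx), params.marker_background_level, np.float64)
    dapi = np.full((nz, ny, nx), params.marker_background_level, np.float64)

    t = params.membrane_thickness_fraction
    for lab, (center, semi) in enumerate(zip(centers, axes), start=1):
        sl, rho = _normalized_radius(params, center, semi)
        inside = rho <= 1.0
        region = cell_labels[sl]
        claim = inside & (region == 0)  # first-come on touching cells
        region[claim] = lab
        membrane = claim & (rho >= 1.0 - t)
        interior = claim & (rho < 1.0 - t)
        marker_sl = marker[sl]
        marker_sl[membrane] = params.marker_membrane_level
        marker_sl[interior] = params.marker_interior_level
        # nucleus: sphere scaled from the same ellipsoid
        nuc = claim & (rho <= params.nucleus_radius_fraction)
        nucleus_labels[sl][nuc] = lab
        dapi[sl][nuc] = params.nuclear_level

    # Multiplicative intracellular texture: a smooth lognormal random field.
    if params.marker_heterogeneity > 0:
        field_raw = rng.standard_normal((nz, ny, nx))
        smooth = ndimage.gaussian_filter(field_raw, sigma=(1.0, 4.0, 4.0))
        smooth /= max(smooth.std(), 1e-12)
        texture = np.exp(params.marker_heterogeneity * smooth)
        marker = np.where(cell_labels > 0, marker * texture, marker)

    # smFISH channel: planted spots + background.
    smfish = np.full((nz, ny, nx), params.background_level, np.float64)
    min_sep = params.min_spot_separation_sigmas
    sep_scale = np.array(  # (z, y, x) order to match sampled positions
        [params.psf.sigma_z_um, params.psf.sigma_xy_um, params.psf.sigma_xy_um]
    )
    rows = []
    per_cell: dict[int, int] = {}
    for lab, (center, semi) in enumerate(zip(centers, axes), start=1):
        if params.spots_distribution == "poisson":
            n_spots = int(rng.poisson(params.spots_per_cell))
        else:
            n_spots = int(round(params.spots_per_cell))
        placed: list[np.ndarray] = []
        attempts = 0
        while len(placed) < n_spots and attempts < 200 * max(n_spots, 1):
            attempts += 1
            p = _sample_point_in_ellipsoid(rng, np.array(center), np.array(semi))
            ext = np.array([nz * dz, ny * dy, nx * dx])
            if np.any(p < 0.25) or np.any(p > ext - 0.25):  # keep fit window inside
                continue
            if min_sep > 0 and placed and (
                np.linalg.norm((np.array(placed) - p) / sep_scale, axis=1).min()
                < min_sep
            ):
                continue
            placed.append(p)
        if len(placed) < n_spots:
            raise PlacementError(
                f"could only place {len(placed)}/{n_spots} spots in cell {lab}"
            )
        sigma_ln = np.sqrt(np.log(1 + params.amplitude_cv**2))
        for p in placed:
            amp = params.spot_amplitude * np.exp(
                rng.normal(-0.5 * sigma_ln**2, sigma_ln)
            )
            z_um, y_um, x_um = p
            amp_eff = amp * np.exp(-params.depth_attenuation_per_um * z_um)
            _render_into(smfish, params.voxel_size_um, (x_um, y_um, z_um), amp_eff, params.psf)
            vz, vy, vx = int(z_um / dz), int(y_um / dy), int(x_um / dx)
            spot_label = int(cell_labels[vz, vy, vx])
            rows.append((x_um, y_um, z_um, amp_eff, spot_label))
            if spot_label > 0:
                per_cell[spot_label] = per_cell.get(spot_label, 0) + 1
    for lab in range(1, len(centers) + 1):
        per_cell.setdefault(lab, 0)

    marker = _add_noise(marker, params, rng)
    smfish = _add_noise(smfish, params, rng)
    dapi = _add_noise(dapi, params, rng)

    stack = ImageStack(
        voxels=np.stack([marker, smfish, dapi]),
        channel_names=["marker", "smFISH", "DAPI"],
        voxel_size_um=params.voxel_size_um,
        metadata={"simulated": True, "seed": params.seed},
    )
    spots_df = pd.DataFrame(
        rows, columns=["x_um", "y_um", "z_um", "amplitude", "label"]
    ) if rows else pd.DataFrame(columns=["x_um", "y_um", "z_um", "amplitude", "label"])
    gt = GroundTruth(
        cell_mask=LabelMask(cell_labels, "cell", params.voxel_size_um),
        nucleus_mask=LabelMask(nucleus_labels, "nucleus", params.voxel_size_um),
        spots=spots_df,
        per_cell_counts=per_cell,
    )
    return stack, gt


def make_training_set(
    params: ScenarioParams, n_stacks: int
) -> list[tuple[ImageStack, LabelMask]]:
    """Independent simulated stacks with exact cell masks for training.

    Per-stack seeds are derived deterministically from the base seed, so two
    calls with the same parameters produce identical sets.
    """
    if n_stacks < 1:
        raise ValueError("n_stacks must be >= 1")
    out = []
    for i in range(n_stacks):
        sub_seed = int((params.seed * 1_000_003 + i) % 2**31)
        stack, gt = simulate_stack(replace(params, seed=sub_seed))
        out.append((stack, gt.cell_mask))
    return out


# ---------------------------------------------------------------------------
# Lightweight generators for detector / QC studies
# ---------------------------------------------------------------------------


def simulate_isolated_spots(
    n_spots: int,
    psf: Optional[PSFParams] = None,
    snr: float = 8.0,
    background_level: float = 100.0,
    photon_gain: float = 1.0,
    read_noise_sd: float = 5.0,
    amplitude_cv: float = 0.0,
    voxel_size_um: tuple[float, float, float] = (0.2, 0.05, 0.05),
    seed: int = 0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Well-separated spots on a flat noisy background, on a regular grid
    with random subvoxel offsets. Returns the stack (single ``smFISH``
    channel) and the true catalog (x_um, y_um, z_um, amplitude, zi, yi, xi).

    The peak amplitude is chosen as ``snr`` times the background noise SD,
    matching the definition used for the detector's working point.
    """
    psf = psf or PSFParams()
    rng = np.random.default_rng(seed)
    dz, dy, dx = voxel_size_um
    spacing_um = max(8 * psf.sigma_xy_um, 6 * psf.sigma_z_um, 1.2)
    per_side = int(np.ceil(np.sqrt(n_spots)))
    nx = ny = int(np.ceil((per_side + 1) * spacing_um / dx))
    nz = int(np.ceil((2 * 4 * psf.sigma_z_um + 2.0) / dz))
    vol = np.full((nz, ny, nx), background_level, np.float64)
    noise_sd = np.sqrt(background_level / photon_gain + read_noise_sd**2)
    amp_mean = snr * noise_sd
    sigma_ln = np.sqrt(np.log(1 + amplitude_cv**2)) if amplitude_cv > 0 else 0.0

    rows = []
    for k in range(n_spots):
        gy, gx = divmod(k, per_side)
        x0 = (gx + 1) * spacing_um + rng.uniform(-0.5, 0.5) * dx
        y0 = (gy + 1) * spacing_um + rng.uniform(-0.5, 0.5) * dy
        z0 = nz * dz / 2 + rng.uniform(-0.5, 0.5) * dz
        amp = amp_mean * (
            np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln)) if sigma_ln else 1.0
        )
        _render_into(vol, voxel_size_um, (x0, y0, z0), amp, psf)
        rows.append((x0, y0, z0, amp, int(z0 / dz), int(y0 / dy), int(x0 / dx)))

    noisy = np.maximum(
        rng.poisson(np.maximum(vol, 0) * photon_gain) / photon_gain
        + rng.normal(0, read_noise_sd, vol.shape),
        0.0,
    )
    stack = ImageStack(
        voxels=noisy[np.newaxis],
        channel_names=["smFISH"],
        voxel_size_um=voxel_size_um,
        metadata={"simulated": True, "snr": snr},
    )
    truth = pd.DataFrame(
        rows, columns=["x_um", "y_um", "z_um", "amplitude", "zi", "yi", "xi"]
    )
    return stack, truth


def simulate_spot_tables(
    n_tables: int,
    n_spots: int = 50,
    z_extent_um: float = 10.0,
    mean_intensity: float = 100.0,
    amplitude_cv: float = 0.10,
    depth_attenuation_per_um: float = 0.0,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Spot catalogs (not images) for QC calibration studies.

    Each table has spots uniform in z over ``z_extent_um`` (the ~10 µm scan
    depth typical of a hemi-brain acquisition) with lognormal integrated
    intensities of the given coefficient of variation, optionally attenuated
    exponentially with depth.
    """
    rng = np.random.default_rng(seed)
    sigma_ln = np.sqrt(np.log(1 + amplitude_cv**2))
    out = []
    for _ in range(n_tables):
        z = rng.uniform(0, z_extent_um, n_spots)
        inten = mean_intensity * np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln, n_spots))
        inten *= np.exp(-depth_attenuation_per_um * z)
        out.append(
            pd.DataFrame(
                {
                    "x_um": rng.uniform(0, 10, n_spots),
                    "y_um": rng.uniform(0, 10, n_spots),
                    "z_um": z,
                    "integrated_intensity": inten,
                }
            )
        )
    return out
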