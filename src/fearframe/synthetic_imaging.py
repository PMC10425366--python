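"""Synthetic section micrographs and two-channel z-stacks with ground truth.

Two generators feed the image-quantification layer:

* :func:`simulate_section` renders Gaussian-profile somata inside a
  rectangular traced region of a low-magnification section image, with
  additive background noise, and logs every planted cell.
* :func:`simulate_cell_stack` renders a confocal z-stack of one cell: an
  ellipsoidal soma mask plus diffraction-scale 3-D Gaussian puncta
  scattered uniformly through the 5-um perisomatic shell at a per-label
  planted density, together with a paired background stack sharing the
  same noise statistics.

Default per-label punctum densities are 2:1 (retro-labeled : unlabeled),
and the cohort-level helpers plant a 2:1 female : male section cell
density, matching the effect sizes the quantification layer is expected
to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SimulationError
from .image_quant import CellStack, SectionImage, extract_perisomatic_shell

__all__ = [
    "SectionSimParams",
    "SectionGroundTruth",
    "StackSimParams",
    "StackGroundTruth",
    "simulate_section",
    "simulate_cell_stack",
]


@dataclass(frozen=True)
class SectionSimParams:
    """Generative parameters for a section micrograph.

    ``cell_density`` is cells/mm^2 inside the traced region (Poisson
    count); give ``n_cells`` to plant an exact number instead.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0  # um / px
    n_cells: int | None = None
    cell_density: float = 100.0  # cells / mm^2
    cell_radius_um: tuple[float, float] = (5.0, 8.0)
    peak_intensity: tuple[float, float] = (150.0, 220.0)
    background_level: float = 10.0
    noise_sd: float = 3.0
    roi_margin_px: int = 30
    min_separation_factor: float = 3.0  # x mean radius, centre-to-centre

    def __post_init__(self) -> None:
        if self.cell_density < 0:
            raise ValueError("cell_density must be >= 0")
        if min(self.peak_intensity) <= self.background_level:
            raise ValueError("punctum/soma intensity must exceed background")


@dataclass
class SectionGroundTruth:
    centers: np.ndarray  # (n, 2) row/col px
    radii_um: np.ndarray
    n_cells: int


def _default_roi(params: SectionSimParams) -> np.ndarray:
    m = params.roi_margin_px
    h, w = params.shape
    return np.array(
        [[m, m], [m, w - m], [h - m, w - m], [h - m, m]], dtype=float
    )


def simulate_section(
    params: SectionSimParams, seed: int | np.random.SeedSequence
) -> tuple[SectionImage, SectionGroundTruth]:
    """Render one section image; deterministic under ``seed``.

    Cell centres are placed by rejection sampling with a minimum
    centre-to-centre separation; exceeding the achievable packing raises
    :class:`SimulationError`.
    """
    rng = np.random.default_rng(seed)
    roi = _default_roi(params)
    h, w = params.shape
    m = params.roi_margin_px
    area_mm2 = ((h - 2 * m) * (w - 2 * m)) * params.pixel_size**2 * 1e-6
    n = (
        params.n_cells
        if params.n_cells is not None
        else int(rng.poisson(params.cell_density * area_mm2))
    )
    mean_r_px = np.mean(params.cell_radius_um) / params.pixel_size
    min_sep = params.min_separation_factor * mean_r_px
    centers: list[tuple[float, float]] = []
    pad = mean_r_px + 2
    for _ in range(n):
        for attempt in range(200):
            r = rng.uniform(m + pad, h - m - pad)
            c = rng.uniform(m + pad, w - m - pad)
            if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep**2 for rr, cc in centers):
                centers.append((r, c))
                break
        else:
            raise SimulationError(
                f"could not place {n} cells at the requested separation"
            )
    image = np.zeros(params.shape)
    radii = rng.uniform(*params.cell_radius_um, size=n)
    peaks = rng.uniform(*params.peak_intensity, size=n)
    for (r, c), rad_um, amp in zip(centers, radii, peaks):
        rad_px = rad_um / params.pixel_size
        sigma = 0.5 * rad_px
        ext = int(np.ceil(3 * sigma))
        r0, c0 = int(round(r)), int(round(c))
        rr = np.arange(max(0, r0 - ext), min(h, r0 + ext + 1))
        cc = np.arange(max(0, c0 - ext), min(w, c0 + ext + 1))
        d2 = (rr[:, None] - r) ** 2 + (cc[None, :] - c) ** 2
        image[np.ix_(rr, cc)] += amp * np.exp(-d2 / (2 * sigma**2))
    image += params.background_level
    image += rng.normal(0.0, params.noise_sd, params.shape)
    np.clip(image, 0.0, None, out=image)
    truth = SectionGroundTruth(
        centers=np.array(centers, dtype=float).reshape(n, 2),
        radii_um=radii,
        n_cells=n,
    )
    return (
        SectionImage(intensity=image, pixel_size=params.pixel_size, roi=roi),
        truth,
    )


@dataclass(frozen=True)
class StackSimParams:
    """Generative parameters for a per-cell confocal z-stack.

    ``punctum_density`` maps cell label to puncta per cubic micrometre of
    shell; the default plants retro-labeled cells at twice the unlabeled
    density.  Puncta are in-plane-isotropic Gaussians of
    diffraction-scale width so binarization at 0.111-um pixels behaves
    realistically.
    """

    shape: tuple[int, int, int] = (32, 192, 192)
    voxel_size: tuple[float, float, float] = (0.33, 0.111, 0.111)
    soma_radius_xy_um: tuple[float, float] = (3.5, 4.5)
    soma_radius_z_um: tuple[float, float] = (3.0, 4.0)
    shell_width_um: float = 5.0
    punctum_density: dict = field(
        default_factory=lambda: {"retro-labeled": 0.02, "unlabeled": 0.01}
    )
    punctum_sigma_um: tuple[float, float, float] = (0.4, 0.3, 0.3)
    punctum_intensity: float = 150.0
    background_level: float = 20.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.punctum_density.values()):
            raise ValueError("punctum densities must be >= 0")
        if self.punctum_intensity <= self.background_level:
            raise ValueError("punctum intensity must exceed background level")

    @property
    def suggested_threshold(self) -> float:
        """Absolute binarization threshold halfway up a punctum peak."""
        return self.background_level + 0.5 * self.punctum_intensity


@dataclass
class StackGroundTruth:
    cell_label: str
    n_puncta: int
    planted_shell_fraction: float  # noiseless half-max occupancy of the shell
    soma_semiaxes_um: tuple[float, float, float]


def simulate_cell_stack(
    params: StackSimParams,
    seed: int | np.random.SeedSequence,
    label: str = "unlabeled",
) -> tuple[CellStack, np.ndarray, StackGroundTruth]:
    """Render one two-stack cell (signal + paired background).

    Returns ``(stack, background_stack, truth)``.  The punctum count is
    the label's planted density times the shell volume (rounded), so the
    per-label contrast is set exactly by the density parameters; puncta
    are centred on voxels drawn uniformly from the shell.  The paired
    background stack carries the same background level and noise.
    """
    if label not in params.punctum_density:
        raise ValueError(f"no planted density for label {label!r}")
    rng = np.random.default_rng(seed)
    nz, ny, nx = params.shape
    vz, vy, vx = params.voxel_size
    ax = rng.uniform(*params.soma_radius_xy_um)
    az = rng.uniform(*params.soma_radius_z_um)
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij", sparse=True
    )
    soma = (
        ((zz - cz) * vz / az) ** 2
        + ((yy - cy) * vy / ax) ** 2
        + ((xx - cx) * vx / ax) ** 2
    ) <= 1.0
    probe = CellStack(
        signal=np.zeros(params.shape),
        soma_mask=soma,
        voxel_size=params.voxel_size,
        cell_label=label,
    )
    shell = extract_perisomatic_shell(probe, params.shell_width_um)
    shell_voxels = np.argwhere(shell.mask)
    if len(shell_voxels) == 0:
        raise SimulationError("shell construction produced no voxels")
    voxel_vol = vz * vy * vx
    shell_vol_um3 = len(shell_voxels) * voxel_vol
    n_puncta = int(round(params.punctum_density[label] * shell_vol_um3))
    signal = np.zeros(params.shape)
    sz, sy, sx = params.punctum_sigma_um
    ez = int(np.ceil(3 * sz / vz))
    exy = int(np.ceil(3 * sy / vy))
    for idx in rng.choice(len(shell_voxels), size=n_puncta, replace=True) if n_puncta else []:
        pz, py, px = shell_voxels[idx]
        z_rng = np.arange(max(0, pz - ez), min(nz, pz + ez + 1))
        y_rng = np.arange(max(0, py - exy), min(ny, py + exy + 1))
        x_rng = np.arange(max(0, px - exy), min(nx, px + exy + 1))
        gz = np.exp(-(((z_rng - pz) * vz) ** 2) / (2 * sz**2))
        gy = np.exp(-(((y_rng - py) * vy) ** 2) / (2 * sy**2))
        gx = np.exp(-(((x_rng - px) * vx) ** 2) / (2 * sx**2))
        signal[np.ix_(z_rng, y_rng, x_rng)] += params.punctum_intensity * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
    planted_fraction = float(
        np.mean(signal[shell.mask] >= 0.5 * params.punctum_intensity)
    )
    noisy = signal + params.background_level
    noisy = noisy + rng.normal(0.0, params.noise_sd, params.shape)
    np.clip(noisy, 0.0, None, out=noisy)
    background = np.clip(
        params.background_level + rng.normal(0.0, params.noise_sd, params.shape),
        0.0,
        None,
    )
    stack = CellStack(
        signal=noisy,
        soma_mask=soma,
        voxel_size=params.voxel_size,
        cell_label=label,
    )
    truth = StackGroundTruth(
        cell_label=label,
        n_puncta=n_puncta,
        planted_shell_fraction=planted_fraction,
        soma_semiaxes_um=(az, ax, ax),
    )
    return stack, background, truth
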