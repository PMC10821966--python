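"""Core volume and mask containers, filter bank, and gray-level discretization.

This module holds the shared geometry layer of the pipeline: axis-aligned 3D
scalar lattices (planning CT in HU, dose in Gy), binary volumes of interest
(VOIs), the 12-image filter bank (original + 3 Laplacian-of-Gaussian scales +
8 stationary-wavelet sub-bands) used for radiomics, and the fixed-bin-number
gray-level discretization applied before texture analysis.

Array axis convention is ``(x, y, z)`` with ``z`` the craniocaudal axis;
physical position of voxel ``(i, j, k)`` is ``origin + index * spacing``
(no direction matrix — grids are assumed axis-aligned).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pywt
from scipy import ndimage as ndi

__all__ = [
    "VolumeGrid",
    "VOIMask",
    "FilterConfig",
    "WAVELET_SUBBANDS",
    "combine_masks",
    "build_filter_bank",
    "discretize_fixed_bin_number",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
]

#: The 8 sub-band labels of a single-level 3D wavelet decomposition,
#: one low(L)/high(H)-pass choice per axis (x, y, z).
WAVELET_SUBBANDS: tuple[str, ...] = tuple(
    "".join(b) for b in itertools.product("LH", repeat=3)
)


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar lattice (CT intensities in HU or dose in Gy).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values; must be finite.
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    origin : tuple of float
        Physical position (mm) of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.size == 0:
            raise ValueError("VolumeGrid requires a non-empty 3D lattice")
        if not np.all(np.isfinite(values)):
            raise ValueError("VolumeGrid values must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three strictly positive values")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinate arrays (mm) broadcastable to ``values``."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))


@dataclass(frozen=True)
class VOIMask:
    """A named boolean volume of interest on a grid's index lattice."""

    indicator: np.ndarray
    name: str = "ESO"

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if ind.dtype != bool:
            uniq = np.unique(ind)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask labels must be binary {0,1}")
            ind = ind.astype(bool)
        if ind.ndim != 3:
            raise ValueError("VOIMask requires a 3D lattice")
        object.__setattr__(self, "indicator", ind)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.indicator.shape

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())


def combine_masks(a: VOIMask, b: VOIMask, name: str = "EG") -> VOIMask:
    """Voxelwise union of two VOIs on the same lattice.

    Used to form the combined esophagus+GTV volume (EG).
    """
    if a.shape != b.shape:
        raise ValueError(
            f"mask shapes differ: {a.shape} vs {b.shape}; "
            "VOIs must live on the same lattice"
        )
    return VOIMask(a.indicator | b.indicator, name=name)


@dataclass(frozen=True)
class FilterConfig:
    """Configuration of the derived-image bank and discretization levels.

    Defaults reproduce the conventional 12-image CT radiomics bank:
    original + LoG at sigma 1, 3, 6 mm + the 8 single-level stationary
    (undecimated) wavelet sub-bands, with gray-level counts 10..50.
    """

    log_sigmas: tuple[float, ...] = (1.0, 3.0, 6.0)
    wavelet: str = "coif1"
    wavelet_subbands: tuple[str, ...] = WAVELET_SUBBANDS
    bin_numbers: tuple[int, ...] = (10, 20, 30, 40, 50)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.log_sigmas):
            raise ValueError("LoG sigma must be positive (mm)")
        bad = [b for b in self.wavelet_subbands if b not in WAVELET_SUBBANDS]
        if bad:
            raise ValueError(f"unknown wavelet sub-bands: {bad}")
        if any((int(b) != b or b < 1) for b in self.bin_numbers):
            raise ValueError("bin numbers must be positive integers")
        object.__setattr__(self, "log_sigmas", tuple(float(s) for s in self.log_sigmas))
        object.__setattr__(self, "bin_numbers", tuple(int(b) for b in self.bin_numbers))

    @property
    def n_images(self) -> int:
        return 1 + len(self.log_sigmas) + len(self.wavelet_subbands)


def _gauss_kernels(sigma_vox: float, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled 1D Gaussian and second-derivative-of-Gaussian kernels.

    The second-derivative kernel is corrected to zero sum so a constant
    input maps exactly to zero even at sub-voxel sigma (where naive
    sampling leaves a large DC residue).  Units are physical: the
    derivative kernel already includes the 1/spacing^2 factor.
    """
    radius = max(2, int(np.ceil(4.0 * sigma_vox)))
    t = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(t**2) / (2.0 * sigma_vox**2))
    g /= g.sum()
    x = t * spacing
    sigma = sigma_vox * spacing
    d2 = (x**2 - sigma**2) / sigma**4 * np.exp(-(x**2) / (2.0 * sigma**2))
    d2 *= spacing / (np.sqrt(2.0 * np.pi) * sigma)  # continuous normalization
    d2 -= d2.mean()  # zero-sum: annihilate constants exactly
    return g, d2


def _log_filter(grid: VolumeGrid, sigma_mm: float) -> np.ndarray:
    """Physical-unit Laplacian of Gaussian: sum of per-axis second derivatives.

    Sigma is specified in mm and converted per axis by the voxel spacing, so
    anisotropic grids are filtered isotropically in physical space.  Boundary
    handling is mirror reflection.
    """
    kernels = [
        _gauss_kernels(sigma_mm / s, s) for s in grid.spacing
    ]
    out = np.zeros_like(grid.values)
    for deriv_axis in range(3):
        term = grid.values
        for axis in range(3):
            g, d2 = kernels[axis]
            kernel = d2 if axis == deriv_axis else g
            term = ndi.correlate1d(term, kernel, axis=axis, mode="mirror")
        out += term
    return out


def _swt3(values: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
    """Single-level 3D stationary wavelet transform, labelled L/H per axis.

    The stationary (undecimated) transform keeps every sub-band on the
    original lattice.  Odd-sized axes are edge-padded to even length for the
    transform and cropped back.
    """
    pad = [(0, s % 2) for s in values.shape]
    padded = np.pad(values, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1, norm=True)[0]
    out: dict[str, np.ndarray] = {}
    for band in WAVELET_SUBBANDS:
        key = band.replace("L", "a").replace("H", "d")
        arr = coeffs[key]
        out[band] = arr[tuple(slice(0, s) for s in values.shape)]
    return out


def build_filter_bank(
    ct: VolumeGrid, cfg: FilterConfig | None = None
) -> list[tuple[str, VolumeGrid]]:
    """Return the labelled derived-image bank for radiomics extraction.

    With the default configuration this is 12 images: the original, one LoG
    response per sigma, and the 8 stationary-wavelet sub-bands, all on the
    original lattice.
    """
    cfg = cfg or FilterConfig()
    bank: list[tuple[str, VolumeGrid]] = [("original", ct)]
    for sigma in cfg.log_sigmas:
        bank.append(
            (
                f"log-sigma-{sigma:g}mm",
                VolumeGrid(_log_filter(ct, sigma), ct.spacing, ct.origin),
            )
        )
    if cfg.wavelet_subbands:
        subbands = _swt3(ct.values, cfg.wavelet)
        for band in cfg.wavelet_subbands:
            bank.append(
                (f"wavelet-{band}", VolumeGrid(subbands[band], ct.spacing, ct.origin))
            )
    return bank


def discretize_fixed_bin_number(values: Sequence[float], n_bins: int) -> np.ndarray:
    """Fixed-bin-number gray-level discretization onto integer levels 1..n_bins.

    ``bin = min(n_bins, floor(n_bins * (v - min) / (max - min)) + 1)``;
    a constant input maps entirely to level 1.  The map is invariant under
    positive affine rescaling of the input and monotone non-decreasing.
    """
    if int(n_bins) != n_bins or n_bins < 1:
        raise ValueError("n_bins must be a positive integer")
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot discretize an empty value list")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.ones(v.shape, dtype=np.int64)
    bins = np.floor(n_bins * (v - lo) / (hi - lo)).astype(np.int64) + 1
    return np.minimum(bins, n_bins)


# ---------------------------------------------------------------------------
# NIfTI I/O (axis-aligned affines only)

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(grid: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(grid.values.astype(np.float32), _affine(grid.spacing, grid.origin))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return VolumeGrid(np.asanyarray(img.dataobj, dtype=float), spacing, origin)


def save_mask(mask: VOIMask, grid: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.indicator.astype(np.uint8), _affine(grid.spacing, grid.origin)
    )
    nib.save(img, str(path))


def load_mask(path: str | Path, name: str) -> VOIMask:
    img = nib.load(str(path))
    return VOIMask(np.asanyarray(img.dataobj) > 0, name=name)
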