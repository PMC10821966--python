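"""Dosiomics: DVH parameters, scale-invariant 3D dose moments, and
dose-based radiomics.

Three families summarize the planned dose inside a VOI:

* **DVH parameters** ``Dx`` (minimum dose received by the hottest x% of the
  VOI volume, linearly interpolated on the sorted voxel doses) and ``Vx``
  (fraction of the VOI receiving strictly more than x Gy), plus
  Dmin/Dmean/Dmax.
* **Scale-invariant 3D dose moments**: dose-weighted central spatial moments
  over physical coordinates, normalized as
  ``eta_pqr = mu_pqr / mu_000**(1 + (p+q+r)/3)`` for all 63 order triples
  ``(p,q,r)`` in ``{0..3}^3`` except ``(0,0,0)``.  The weight of a voxel is
  ``dose * voxel_volume``, which makes every ``eta`` exactly invariant under
  isotropic stretching of the lattice and under translation.
* **Dose-based radiomics**: the 18 first-order + 73 texture features of the
  unfiltered dose map within the VOI.

With the default grids (39 Dx points, 20 Vx points) the per-VOI dose
profile has ``59 + 63 + 91 = 213`` features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .imaging_core import VOIMask, VolumeGrid
from .radiomics_features import extract_first_order, extract_texture

__all__ = [
    "DVHSummary",
    "DoseFeatureConfig",
    "MOMENT_ORDERS",
    "compute_dvh",
    "compute_dose_moments",
    "extract_dose_radiomics",
    "extract_dose_profile",
    "n_dose_features",
]

#: The 63 moment order triples (p, q, r) with 0 <= p,q,r <= 3, excluding (0,0,0).
MOMENT_ORDERS: tuple[tuple[int, int, int], ...] = tuple(
    o for o in itertools.product(range(4), repeat=3) if o != (0, 0, 0)
)

#: Default Dx percent-volume grid (39 points) and Vx dose grid (20 points, Gy).
DEFAULT_DX_GRID: tuple[float, ...] = (0.5, 0.8) + tuple(
    np.arange(2.5, 93.0, 2.5)
)
DEFAULT_VX_GRID: tuple[float, ...] = tuple(np.arange(4.0, 81.0, 4.0))


@dataclass(frozen=True)
class DVHSummary:
    """Cumulative dose-volume histogram summaries of one VOI."""

    dx: dict[float, float]  # percent volume -> Gy
    vx: dict[float, float]  # Gy threshold -> fractional volume
    d_min: float
    d_mean: float
    d_max: float

    def as_features(self) -> dict[str, float]:
        out = {f"dvh_D{x:g}": v for x, v in self.dx.items()}
        out.update({f"dvh_V{x:g}": v for x, v in self.vx.items()})
        return out


@dataclass(frozen=True)
class DoseFeatureConfig:
    dx_grid: tuple[float, ...] = DEFAULT_DX_GRID
    vx_grid: tuple[float, ...] = DEFAULT_VX_GRID
    n_bins: int = 20  # gray levels for dose-based radiomics

    def __post_init__(self) -> None:
        if any(not (0 < x <= 100) for x in self.dx_grid):
            raise ValueError("Dx percent-volume points must lie in (0, 100]")
        if any(x < 0 for x in self.vx_grid):
            raise ValueError("Vx dose thresholds must be non-negative (Gy)")


def compute_dvh(
    dose: VolumeGrid,
    mask: VOIMask,
    x_percent_grid=DEFAULT_DX_GRID,
    x_gy_grid=DEFAULT_VX_GRID,
) -> DVHSummary:
    """Dx/Vx DVH parameters of the dose within a VOI.

    ``Dx`` is interpolated on the descending-sorted voxel doses against the
    cumulative volume fraction ``j/n``; ``Vx`` uses the strict inequality
    ``dose > x``.
    """
    if mask.n_voxels == 0:
        raise ValueError("DVH requires a non-empty mask")
    cfg = DoseFeatureConfig(tuple(x_percent_grid), tuple(x_gy_grid), 2)
    d = np.sort(dose.values[mask.indicator])[::-1]
    if d[-1] < 0:
        raise ValueError("dose must be non-negative")
    n = d.size
    frac = np.arange(1, n + 1) / n  # hottest-volume fraction at each sorted voxel
    xq = np.asarray(cfg.dx_grid) / 100.0
    dx_vals = np.interp(xq, frac, d)  # clamps to d[0] below frac 1/n
    vx_vals = [(d > x).mean() for x in cfg.vx_grid]
    return DVHSummary(
        dx=dict(zip(cfg.dx_grid, map(float, dx_vals))),
        vx=dict(zip(cfg.vx_grid, map(float, vx_vals))),
        d_min=float(d[-1]),
        d_mean=float(d.mean()),
        d_max=float(d[0]),
    )


def compute_dose_moments(dose: VolumeGrid, mask: VOIMask) -> dict[str, float]:
    """The 63 scale-invariant, translation-invariant dose moments.

    Weight per voxel is ``dose * voxel_volume``; coordinates are physical
    (mm).  Keys are ``moment_eta_pqr`` with p, q, r the orders along the
    x (medial-lateral), y (anterior-posterior) and z (craniocaudal) axes.
    """
    if mask.n_voxels == 0:
        raise ValueError("dose moments require a non-empty mask")
    w = dose.values[mask.indicator] * dose.voxel_volume
    if w.sum() <= 0:
        raise ValueError("total dose inside the VOI must be positive")
    idx = np.argwhere(mask.indicator).astype(float)
    coords = idx * np.array(dose.spacing) + np.array(dose.origin)
    mu000 = float(w.sum())
    centroid = (w[:, None] * coords).sum(axis=0) / mu000
    c = coords - centroid
    powers = {axis: [np.ones(len(w)), c[:, axis], c[:, axis] ** 2, c[:, axis] ** 3]
              for axis in range(3)}
    out: dict[str, float] = {}
    for p, q, r in MOMENT_ORDERS:
        if p + q + r == 1:
            # first-order central moments vanish identically (the centroid
            # is the dose-weighted mean); report the exact zero
            out[f"moment_eta_{p}{q}{r}"] = 0.0
            continue
        mu = float((w * powers[0][p] * powers[1][q] * powers[2][r]).sum())
        out[f"moment_eta_{p}{q}{r}"] = mu / mu000 ** (1.0 + (p + q + r) / 3.0)
    return out


def extract_dose_radiomics(
    dose: VolumeGrid, mask: VOIMask, n_bins: int = 20
) -> dict[str, float]:
    """First-order + texture features of the raw dose map (91 values).

    Delegates to the radiomics extractors on the unfiltered dose grid:
    dose-based radiomics are by definition the same statistics computed on
    dose instead of CT, with no filtered images and no shape family.
    """
    out = {
        f"dose_firstorder_{k}_{n_bins}": v
        for k, v in extract_first_order(dose, mask, n_bins).items()
    }
    out.update(
        {f"dose_{k}_{n_bins}": v for k, v in extract_texture(dose, mask, n_bins).items()}
    )
    return out


def n_dose_features(cfg: DoseFeatureConfig) -> int:
    """Counting identity: |Dx grid| + |Vx grid| + 63 + 91."""
    return len(cfg.dx_grid) + len(cfg.vx_grid) + len(MOMENT_ORDERS) + 91


def extract_dose_profile(
    dose: VolumeGrid,
    mask: VOIMask,
    cfg: DoseFeatureConfig | None = None,
) -> dict[str, float]:
    """Concatenated DVH + moment + dose-radiomics features for one VOI
    (213 under the default grids)."""
    cfg = cfg or DoseFeatureConfig()
    profile = compute_dvh(dose, mask, cfg.dx_grid, cfg.vx_grid).as_features()
    profile.update(compute_dose_moments(dose, mask))
    profile.update(extract_dose_radiomics(dose, mask, cfg.n_bins))
    return profile
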