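"""CT radiomics: first-order, 3D shape, and texture feature extraction.

The default profile of a VOI comprises 14 shape features (computed once, on
the original mask) plus, for every derived image in the filter bank and
every gray-level count, 18 first-order and 73 texture features:
``14 + 12 * 5 * (18 + 73) = 5474`` features per VOI under the default
:class:`~fistulomics.imaging_core.FilterConfig`.

Feature names follow ``<image-label>_<class>_<Feature>_<bins>`` (shape:
``shape_<Feature>``), so every column of the resulting feature table is
traceable to its derived image and discretization.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from ._texture import N_TEXTURE_FEATURES, texture_features
from .imaging_core import (
    FilterConfig,
    VOIMask,
    VolumeGrid,
    build_filter_bank,
    discretize_fixed_bin_number,
)

__all__ = [
    "FIRST_ORDER_FEATURES",
    "SHAPE_FEATURES",
    "extract_first_order",
    "extract_shape",
    "extract_texture",
    "extract_radiomics_profile",
    "n_profile_features",
]

FIRST_ORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)

SHAPE_FEATURES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)


def _require_nonempty(mask: VOIMask) -> None:
    if mask.n_voxels == 0:
        raise ValueError("feature extraction requires a non-empty mask")


def extract_first_order(
    img: VolumeGrid, mask: VOIMask, n_bins: int
) -> dict[str, float]:
    """The 18 first-order intensity statistics of the ROI.

    Entropy and uniformity are computed on the fixed-bin-number histogram;
    skewness/kurtosis/variance use population moments, kurtosis is
    non-excess (a normal distribution scores 3).
    """
    _require_nonempty(mask)
    v = img.values[mask.indicator]
    n = v.size
    mean = float(v.mean())
    var = float(v.var())  # population
    p10, p25, p50, p75, p90 = np.percentile(v, (10, 25, 50, 75, 90))
    levels = discretize_fixed_bin_number(v, n_bins)
    p = np.bincount(levels)[1:].astype(float) / n
    p = p[p > 0]
    robust = v[(v >= p10) & (v <= p90)]
    if var > 0:
        m = v - mean
        skew = float((m**3).mean() / var**1.5)
        kurt = float((m**4).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float((v**2).sum()),
        "TotalEnergy": float(img.voxel_volume * (v**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(v.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(v.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }


def _mesh(mask: VOIMask, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated iso-surface of the mask.

    The indicator is lightly smoothed (sigma 1 voxel) before marching cubes
    so the digitized surface of a smooth object is not over-counted by
    staircase faces; masks too thin to survive smoothing fall back to the
    raw indicator (surfacing the voxel-midpoint iso-surface).
    """
    padded = np.pad(mask.indicator.astype(float), 2)
    smoothed = ndi.gaussian_filter(padded, sigma=1.0)
    vol = smoothed if smoothed.max() > 0.6 else padded
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5, spacing=spacing)
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    return float(abs(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))) / 6.0)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 4:
        try:
            points = points[ConvexHull(points, qhull_options="QJ").vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    if len(points) > 3000:  # hull failed on a big degenerate set: thin it
        points = points[:: len(points) // 3000 + 1]
    return float(pdist(points).max())


def extract_shape(mask: VOIMask, spacing) -> dict[str, float]:
    """The 14 3D shape descriptors of a VOI.

    Surface area, mesh volume and sphericity use a triangulated iso-surface
    (marching cubes at the voxel-boundary level); axis lengths derive from
    the principal components of the voxel-center point cloud
    (``4 * sqrt(eigenvalue)``).  Single-voxel and other degenerate masks
    return the appropriate limits rather than raising.
    """
    _require_nonempty(mask)
    spacing = tuple(float(s) for s in spacing)
    verts, faces = _mesh(mask, spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    mesh_vol = _mesh_volume(verts, faces)
    voxel_vol = mask.n_voxels * float(np.prod(spacing))

    idx = np.argwhere(mask.indicator)
    pts = idx * np.array(spacing)
    diam3d = _max_pairwise(pts)

    # in-plane maximum diameters, one per fixed axis (z, x, y order matches
    # the slice/column/row naming of the axial, sagittal, coronal planes)
    diam2d = {}
    for feat, fixed_axis in (
        ("Maximum2DDiameterSlice", 2),
        ("Maximum2DDiameterColumn", 0),
        ("Maximum2DDiameterRow", 1),
    ):
        keep = [a for a in range(3) if a != fixed_axis]
        best = 0.0
        for level in np.unique(idx[:, fixed_axis]):
            sel = pts[idx[:, fixed_axis] == level][:, keep]
            best = max(best, _max_pairwise(sel))
        diam2d[feat] = best

    cov = np.cov(pts, rowvar=False, bias=True) if len(pts) > 1 else np.zeros((3, 3))
    eig = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0, None))[::-1]
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    sphericity = float((36.0 * np.pi * mesh_vol**2) ** (1.0 / 3.0) / area)
    return {
        "MeshVolume": mesh_vol,
        "VoxelVolume": voxel_vol,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / mesh_vol,
        "Sphericity": sphericity,
        "Maximum3DDiameter": diam3d,
        "Maximum2DDiameterSlice": diam2d["Maximum2DDiameterSlice"],
        "Maximum2DDiameterColumn": diam2d["Maximum2DDiameterColumn"],
        "Maximum2DDiameterRow": diam2d["Maximum2DDiameterRow"],
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }


def extract_texture(img: VolumeGrid, mask: VOIMask, n_bins: int) -> dict[str, float]:
    """The 73 texture features (22 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM +
    5 NGTDM) of the discretized ROI."""
    _require_nonempty(mask)
    return texture_features(img.values, mask.indicator, n_bins)


def n_profile_features(cfg: FilterConfig) -> int:
    """Feature-count identity: 14 shape + images * bins * (18 + 73)."""
    return len(SHAPE_FEATURES) + cfg.n_images * len(cfg.bin_numbers) * (
        len(FIRST_ORDER_FEATURES) + N_TEXTURE_FEATURES
    )


def extract_radiomics_profile(
    ct: VolumeGrid, mask: VOIMask, cfg: FilterConfig | None = None
) -> dict[str, float]:
    """Full radiomics profile of one VOI: 5474 features at default config.

    Shape is extracted once from the original mask (it does not depend on
    intensities); first-order and texture are extracted for every
    (derived image, bin count) pair.  Ordering is deterministic.
    """
    cfg = cfg or FilterConfig()
    _require_nonempty(mask)
    profile: dict[str, float] = {
        f"shape_{k}": v for k, v in extract_shape(mask, ct.spacing).items()
    }
    for label, img in build_filter_bank(ct, cfg):
        for n_bins in cfg.bin_numbers:
            for k, v in extract_first_order(img, mask, n_bins).items():
                profile[f"{label}_firstorder_{k}_{n_bins}"] = v
            for k, v in extract_texture(img, mask, n_bins).items():
                profile[f"{label}_{k}_{n_bins}"] = v
    return profile
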