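"""3D gray-level texture matrices and their scalar features.

Implements the five standard texture families on a discretized 3D ROI:

* GLCM  — gray-level co-occurrence, symmetric, distance 1, the 22
  non-deprecated features, averaged over the 13 unique 3D directions;
* GLRLM — gray-level run length, 13 directions averaged (16 features);
* GLSZM — gray-level size zone, 26-connected zones (16 features);
* GLDM  — gray-level dependence, 26-neighborhood, alpha = 0 (14 features);
* NGTDM — neighborhood gray-tone difference, 26-neighborhood (5 features).

All computations are on integer gray levels ``1..n_bins`` produced by
fixed-bin-number discretization; voxels outside the mask carry level 0 and
never pair with ROI voxels.  Degenerate ROIs (constant intensity, single
voxel) return defined values rather than raising: features of an empty
co-occurrence/run population are 0, and correlation-type features of a
single gray level are their analytic limits.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage as ndi

_EPS = np.finfo(float).tiny

#: The 13 unique direction offsets of a 26-neighborhood (antipodes removed).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
)

_OFFSETS_26 = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)

GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy",
    "MaximumProbability", "SumEntropy", "SumSquares",
)
GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_FEATURES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

N_TEXTURE_FEATURES = (
    len(GLCM_FEATURES) + len(GLRLM_FEATURES) + len(GLSZM_FEATURES)
    + len(GLDM_FEATURES) + len(NGTDM_FEATURES)
)  # = 73


def _bbox_crop(gray: np.ndarray, mask: np.ndarray):
    """Crop both arrays to the mask bounding box (keeps matrices small)."""
    idx = np.argwhere(mask)
    lo = idx.min(0)
    hi = idx.max(0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return gray[sl], mask[sl]


def _overlap_slices(shape, d):
    """Slice pairs selecting voxels v and v+d that both lie in the array."""
    sl1, sl2 = [], []
    for n, step in zip(shape, d):
        if step == 0:
            sl1.append(slice(0, n))
            sl2.append(slice(0, n))
        elif step > 0:
            sl1.append(slice(0, n - step))
            sl2.append(slice(step, n))
        else:
            sl1.append(slice(-step, n))
            sl2.append(slice(0, n + step))
    return tuple(sl1), tuple(sl2)


# ---------------------------------------------------------------------------
# GLCM

def _glcm_matrix(gray, mask, d, n_levels):
    sl1, sl2 = _overlap_slices(gray.shape, d)
    both = mask[sl1] & mask[sl2]
    if not both.any():
        return None
    i = gray[sl1][both] - 1
    j = gray[sl2][both] - 1
    counts = np.bincount(i * n_levels + j, minlength=n_levels * n_levels)
    mat = counts.reshape(n_levels, n_levels).astype(float)
    return mat + mat.T  # symmetric co-occurrence


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    ux = float((i * px).sum())
    sx = float(np.sqrt((((i - ux) ** 2) * px).sum()))

    # marginal distributions of i+j and |i-j|
    ksum = (ii + jj).astype(int)
    kdiff = np.abs(ii - jj).astype(int)
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    k_diff = np.arange(0, ng, dtype=float)

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hxy = ent(p)
    hx = ent(px)
    pxpy = np.outer(px, px)
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz] + _EPS)).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    da = float((k_diff * p_diff).sum())
    out = {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": ux,
        "ClusterProminence": float((((ii + jj - 2 * ux) ** 4) * p).sum()),
        "ClusterShade": float((((ii + jj - 2 * ux) ** 3) * p).sum()),
        "ClusterTendency": float((((ii + jj - 2 * ux) ** 2) * p).sum()),
        "Contrast": float((((ii - jj) ** 2) * p).sum()),
        "Correlation": (
            1.0
            if sx == 0
            else float(((ii - ux) * (jj - ux) * p).sum() / (sx * sx))
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float((((k_diff - da) ** 2) * p_diff).sum()),
        "Id": float((p / (1.0 + kdiff)).sum()),
        "Idm": float((p / (1.0 + kdiff**2)).sum()),
        "Idmn": float((p / (1.0 + (kdiff / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + kdiff / ng)).sum()),
        "Imc1": 0.0 if hx == 0 else float((hxy - hxy1) / hx),
        "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "InverseVariance": float((p[kdiff > 0] / (kdiff[kdiff > 0] ** 2)).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float((((ii - ux) ** 2) * p).sum()),
    }
    return out


def glcm_features(gray, mask, n_levels) -> dict[str, float]:
    per_dir = []
    for d in DIRECTIONS_13:
        mat = _glcm_matrix(gray, mask, d, n_levels)
        if mat is None:
            continue
        per_dir.append(_glcm_single(mat / mat.sum()))
    if not per_dir:
        return {k: 0.0 for k in GLCM_FEATURES}
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRLM

def _runs_along(idx, g, d):
    """Run grays and lengths along lattice direction d for masked voxels."""
    d = np.asarray(d)
    axis = int(np.nonzero(d)[0][0])
    t = idx[:, axis] * d[axis]
    base = idx - t[:, None] * d
    order = np.lexsort((t, base[:, 2], base[:, 1], base[:, 0]))
    t_o, b_o, g_o = t[order], base[order], g[order]
    starts = np.ones(len(g), dtype=bool)
    if len(g) > 1:
        same_line = (b_o[1:] == b_o[:-1]).all(axis=1) & (t_o[1:] == t_o[:-1] + 1)
        starts[1:] = ~(same_line & (g_o[1:] == g_o[:-1]))
    run_id = np.cumsum(starts) - 1
    lengths = np.bincount(run_id)
    return g_o[starts], lengths


def _srm_style_features(P, n_voxels, names) -> dict[str, float]:
    """Shared feature formulas for run-length and size-zone matrices.

    ``P[i-1, l-1]`` counts runs (zones) of gray level i and length (size) l.
    ``names`` maps the family's naming of the 16 analogous features.
    """
    nr = P.sum()
    if nr == 0:
        return {k: 0.0 for k in names}
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / nr
    mu_i = (i * p).sum()
    mu_l = (l * p).sum()
    pg = P.sum(axis=1)
    pl = P.sum(axis=0)
    pnz = p[p > 0]
    vals = (
        float((P / l**2).sum() / nr),
        float((P * l**2).sum() / nr),
        float((pg**2).sum() / nr),
        float((pg**2).sum() / nr**2),
        float((pl**2).sum() / nr),
        float((pl**2).sum() / nr**2),
        float(nr / n_voxels),
        float((((i - mu_i) ** 2) * p).sum()),
        float((((l - mu_l) ** 2) * p).sum()),
        float(-(pnz * np.log2(pnz)).sum()),
        float((P / i**2).sum() / nr),
        float((P * i**2).sum() / nr),
        float((P / (i**2 * l**2)).sum() / nr),
        float((P * i**2 / l**2).sum() / nr),
        float((P * l**2 / i**2).sum() / nr),
        float((P * i**2 * l**2).sum() / nr),
    )
    return dict(zip(names, vals))


def glrlm_features(gray, mask, n_levels) -> dict[str, float]:
    idx = np.argwhere(mask)
    g = gray[mask]
    n_vox = len(g)
    per_dir = []
    for d in DIRECTIONS_13:
        run_gray, lengths = _runs_along(idx, g, d)
        lmax = int(lengths.max())
        P = np.zeros((n_levels, lmax))
        np.add.at(P, (run_gray - 1, lengths - 1), 1.0)
        per_dir.append(_srm_style_features(P, n_vox, GLRLM_FEATURES))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM

def glszm_features(gray, mask, n_levels) -> dict[str, float]:
    structure = np.ones((3, 3, 3), dtype=int)  # 26-connectivity
    n_vox = int(mask.sum())
    levels = np.unique(gray[mask])
    records: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for lev in levels:
        lab, nz = ndi.label((gray == lev) & mask, structure=structure)
        if nz == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        records.append((int(lev), sizes))
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((n_levels, max_size))
    for lev, sizes in records:
        np.add.at(P, (lev - 1, sizes - 1), 1.0)
    return _srm_style_features(P, n_vox, GLSZM_FEATURES)


# ---------------------------------------------------------------------------
# GLDM

def gldm_features(gray, mask, n_levels, alpha: int = 0) -> dict[str, float]:
    dep = np.zeros(gray.shape, dtype=np.int64)
    for d in _OFFSETS_26:
        sl1, sl2 = _overlap_slices(gray.shape, d)
        both = mask[sl1] & mask[sl2]
        close = np.abs(gray[sl1] - gray[sl2]) <= alpha
        dep[sl1] += (both & close).astype(np.int64)
    g = gray[mask]
    dcount = dep[mask] + 1  # center voxel is always dependent on itself
    dmax = int(dcount.max())
    P = np.zeros((n_levels, dmax))
    np.add.at(P, (g - 1, dcount - 1), 1.0)
    nz_total = P.sum()
    i = np.arange(1, n_levels + 1, dtype=float)[:, None]
    j = np.arange(1, dmax + 1, dtype=float)[None, :]
    p = P / nz_total
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    pnz = p[p > 0]
    return dict(
        zip(
            GLDM_FEATURES,
            (
                float((P / j**2).sum() / nz_total),
                float((P * j**2).sum() / nz_total),
                float((pg**2).sum() / nz_total),
                float((pd**2).sum() / nz_total),
                float((pd**2).sum() / nz_total**2),
                float((((i - mu_i) ** 2) * p).sum()),
                float((((j - mu_j) ** 2) * p).sum()),
                float(-(pnz * np.log2(pnz)).sum()),
                float((P / i**2).sum() / nz_total),
                float((P * i**2).sum() / nz_total),
                float((P / (i**2 * j**2)).sum() / nz_total),
                float((P * i**2 / j**2).sum() / nz_total),
                float((P * j**2 / i**2).sum() / nz_total),
                float((P * i**2 * j**2).sum() / nz_total),
            ),
        )
    )


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_features(gray, mask, n_levels) -> dict[str, float]:
    nb_sum = np.zeros(gray.shape, dtype=float)
    nb_cnt = np.zeros(gray.shape, dtype=np.int64)
    gm = np.where(mask, gray, 0).astype(float)
    for d in _OFFSETS_26:
        sl1, sl2 = _overlap_slices(gray.shape, d)
        nb_sum[sl1] += gm[sl2]
        nb_cnt[sl1] += mask[sl2].astype(np.int64)
    g = gray[mask].astype(float)
    cnt = nb_cnt[mask]
    tot = nb_sum[mask]
    diff = np.zeros_like(g)
    has_nb = cnt > 0
    diff[has_nb] = np.abs(g[has_nb] - tot[has_nb] / cnt[has_nb])

    n_vox = len(g)
    n_i = np.bincount(gray[mask] - 1, minlength=n_levels).astype(float)
    s_i = np.bincount(gray[mask] - 1, weights=diff, minlength=n_levels)
    p_i = n_i / n_vox
    i = np.arange(1, n_levels + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())

    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp <= 1:
        contrast = 0.0
    else:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pp = np.outer(p_i[present], p_i[present])
        contrast = float(
            (pp * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / n_vox)
        )

    ipi = i * p_i
    den = float(
        np.abs(ipi[present][:, None] - ipi[present][None, :]).sum()
    )
    busyness = ps / den if den > 0 else 0.0

    if ngp <= 1:
        complexity = 0.0
        strength = 0.0
    else:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pi_ = p_i[present][:, None]
        pj_ = p_i[present][None, :]
        si_ = s_i[present][:, None]
        sj_ = s_i[present][None, :]
        complexity = float(
            (np.abs(ii - jj) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)).sum() / n_vox
        )
        ssum = float(s_i.sum())
        strength = (
            float(((pi_ + pj_) * (ii - jj) ** 2).sum() / ssum) if ssum > 0 else 0.0
        )

    return dict(
        zip(
            NGTDM_FEATURES,
            (coarseness, contrast, busyness, complexity, strength),
        )
    )


# ---------------------------------------------------------------------------

def texture_features(
    values: np.ndarray,
    mask: np.ndarray,
    n_bins: int,
    families: tuple[str, ...] = ("glcm", "glrlm", "glszm", "gldm", "ngtdm"),
) -> dict[str, float]:
    """All requested texture families on an ROI; keys ``<family>_<Feature>``.

    ``values``/``mask`` are full-lattice arrays; the ROI is discretized onto
    ``n_bins`` gray levels before matrix construction.
    """
    from .imaging_core import discretize_fixed_bin_number

    if n_bins < 2:
        raise ValueError("texture analysis requires n_bins >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("texture analysis requires a non-empty mask")
    gray = np.zeros(mask.shape, dtype=np.int64)
    gray[mask] = discretize_fixed_bin_number(np.asarray(values, float)[mask], n_bins)
    gray, mask = _bbox_crop(gray, mask)
    n_levels = int(gray.max())

    funcs = {
        "glcm": glcm_features,
        "glrlm": glrlm_features,
        "glszm": glszm_features,
        "gldm": gldm_features,
        "ngtdm": ngtdm_features,
    }
    out: dict[str, float] = {}
    for fam in families:
        for name, val in funcs[fam](gray, mask, n_levels).items():
            out[f"{fam}_{name}"] = val
    return out
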