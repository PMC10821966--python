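"""Synthetic esophageal-cancer radiotherapy cohorts.

No public imaging dataset accompanies the esophageal-fistula endpoint, so
this module generates complete cohorts — planning CT, 3D dose, esophagus
(ESO) and gross-tumor-volume (GTV) masks, a clinical covariate table, and a
binary fistula label — from a stated generative model, so that every
downstream stage (feature extraction, selection, evaluation) is testable
end to end.

Geometry: the esophagus is an axial tube with per-patient radius jitter;
the GTV is an ellipsoid centered on the tube (the tumor abuts the
esophageal wall, so the two VOIs always overlap).  CT is a smoothed
Gaussian random field with tissue offsets; dose is an anisotropic Gaussian
kernel centered near the GTV, scaled to the prescription implied by the
patient's fraction-dose category (1.8 Gy x 33 = 59.4 Gy or
2.0 Gy x 30 = 60 Gy) plus a small scatter background.

The fistula label is drawn from a logistic model over interpretable
drivers computed by the real dosiomics/radiomics operations:

* the craniocaudal dose-skewness moment ``eta_003`` of the GTV dose,
* esophageal high-dose coverage ``V50`` (fraction of ESO above 50 Gy),
* one esophageal CT texture feature (GLCM joint entropy, 20 gray levels),
* the fraction-dose covariate (2.0 Gy vs 1.8 Gy per fraction).

Drivers are z-scored across the cohort; the intercept is solved so the
expected prevalence matches the requested class balance (default
149:138 ~ 1:1.08).  Clinical covariate marginals default to the pooled
category proportions of the modelled cohort, the same source of truth as
the printed contingency-table fixtures in :func:`table1_fixtures`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from scipy.optimize import brentq

from ._texture import texture_features
from .clinical_stats import ContingencyTable
from .dosiomics_features import compute_dose_moments, compute_dvh
from .imaging_core import (
    VOIMask,
    VolumeGrid,
    save_mask,
    save_volume,
)

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "DEFAULT_EFFECTS",
    "generate_cohort",
    "cohort_tables",
    "write_cohort",
    "table1_fixtures",
]

#: Default logistic effect (log-odds per SD) of each label driver.  The
#: weighting mirrors the modelled cohort's structure: esophageal CT texture
#: dominates, esophageal high-dose coverage and the GTV dose-shape moment
#: contribute, and the fraction-dose covariate carries a clinical effect.
DEFAULT_EFFECTS: dict[str, float] = {
    "eso_glcm_joint_entropy": 1.4,
    "eso_v50": 0.8,
    "gtv_moment_eta003": 0.6,
    "fraction_dose_2gy": 0.5,
}

#: A complementary-signal plant: one strong CT-texture driver visible only
#: through esophagus radiomics and one strong dose-geometry driver visible
#: only through GTV dosiomics, statistically independent by construction.
#: Cohorts planted this way demonstrate multi-VOI synergy: the combined
#: EG model can recover both signal sources while each single-VOI model is
#: blind to one of them.
COMPLEMENTARY_EFFECTS: dict[str, float] = {
    "eso_glcm_joint_entropy": 1.3,
    "gtv_moment_eta003": 1.3,
}

# Pooled covariate category proportions of the modelled 287-patient cohort
# (EF + NEF column sums of the printed characteristics table).
_POOLED = {
    "gender": (("Male", 209), ("Female", 78)),
    "pathology": (("Squamous", 285), ("Adenocarcinoma", 2)),
    "t_stage": (("T2", 21), ("T3", 206), ("T4", 60)),
    "n_stage": (("N0", 35), ("N1", 162), ("N2", 77), ("N3", 13)),
    "m_stage": (("M0", 246), ("M1", 41)),
    "treatment": (("CCRT", 186), ("SRT", 41), ("RT", 60)),
}


@dataclass(frozen=True)
class CohortSpec:
    """All knobs of the generator; the seed fixes every random draw."""

    n_patients: int = 287
    prevalence: float = 149.0 / 287.0
    effect_vector: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    noise_sd: float = 1.0
    grid_shape: tuple[int, int, int] = (24, 24, 32)
    spacing: tuple[float, float, float] = (1.152, 1.152, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticPatient:
    patient_id: str
    ct: VolumeGrid
    dose: VolumeGrid
    eso_mask: VOIMask
    gtv_mask: VOIMask
    clinical: dict
    label: int = 0


def _sample_categorical(rng, spec) -> str:
    names = [n for n, _ in spec]
    weights = np.array([w for _, w in spec], dtype=float)
    return str(rng.choice(names, p=weights / weights.sum()))


def _make_patient(rng: np.random.Generator, spec: CohortSpec, pid: str) -> SyntheticPatient:
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    if nx * sx < 16 or ny * sy < 16 or nz * sz < 24:
        raise ValueError(
            "grid too small to contain the VOIs: need >= 16 mm laterally "
            "and >= 24 mm craniocaudally"
        )
    x, y, z = np.meshgrid(
        np.arange(nx) * sx, np.arange(ny) * sy, np.arange(nz) * sz, indexing="ij"
    )
    cx, cy = (nx - 1) * sx / 2.0, (ny - 1) * sy / 2.0

    # esophagus: axial tube, radius jittered per patient and along z
    r_eso = rng.uniform(3.5, 5.5)  # mm
    r_wobble = 1.0 + 0.1 * np.sin(2 * np.pi * z / z.max() * rng.uniform(1, 3))
    eso = (x - cx) ** 2 + (y - cy) ** 2 <= (r_eso * r_wobble) ** 2
    if not eso.any():
        raise ValueError("grid too small to contain the esophagus VOI")

    # GTV: ellipsoid centered on the tube, craniocaudal extent dominant
    gz = rng.uniform(0.35, 0.65) * (nz - 1) * sz
    ax_ = rng.uniform(6.0, 10.0)
    ay_ = rng.uniform(6.0, 10.0)
    az_ = rng.uniform(12.0, 22.0)
    gtv = ((x - cx) / ax_) ** 2 + ((y - cy) / ay_) ** 2 + ((z - gz) / az_) ** 2 <= 1.0
    if not gtv.any() or not (gtv & eso).any():
        raise ValueError("grid too small to contain an overlapping GTV VOI")

    # CT: tissue offsets + per-patient textured random field
    texture_scale = rng.uniform(0.6, 1.6)  # voxels; drives ESO texture entropy
    noise = ndi.gaussian_filter(rng.standard_normal((nx, ny, nz)), texture_scale)
    noise *= 60.0 / max(noise.std(), 1e-9)
    ct_vals = 40.0 + noise
    ct_vals[eso] -= 30.0
    ct_vals[gtv] += 25.0

    # clinical covariates from the pooled marginals
    fraction_dose = 2.0 if rng.random() < 103.0 / 287.0 else 1.8
    prescription = 60.0 if fraction_dose == 2.0 else 59.4
    clinical = {
        "patient_id": pid,
        "gender": _sample_categorical(rng, _POOLED["gender"]),
        "age": int(np.clip(rng.normal(65, 9), 39, 87)),
        "bmi": float(np.clip(rng.normal(21.6, 2.6), 13.8, 32.8)),
        "pathology": _sample_categorical(rng, _POOLED["pathology"]),
        "t_stage": _sample_categorical(rng, _POOLED["t_stage"]),
        "n_stage": _sample_categorical(rng, _POOLED["n_stage"]),
        "m_stage": _sample_categorical(rng, _POOLED["m_stage"]),
        "treatment": _sample_categorical(rng, _POOLED["treatment"]),
        "fraction_dose": fraction_dose,
    }

    # dose: anisotropic Gaussian centered near the GTV (random craniocaudal
    # offset gives patient-to-patient variation in dose skewness), scaled to
    # the prescription, plus a small non-negative scatter background
    dz_off = rng.normal(0.0, 6.0)  # mm
    sig = (ax_ + 8.0, ay_ + 8.0, az_ + 10.0)
    kernel = np.exp(
        -((x - cx) ** 2 / (2 * sig[0] ** 2)
          + (y - cy) ** 2 / (2 * sig[1] ** 2)
          + (z - gz - dz_off) ** 2 / (2 * sig[2] ** 2))
    )
    dose_vals = prescription * rng.uniform(0.95, 1.05) * kernel
    dose_vals += 0.5 + 0.2 * np.abs(rng.standard_normal((nx, ny, nz)))

    spacing = (sx, sy, sz)
    return SyntheticPatient(
        patient_id=pid,
        ct=VolumeGrid(ct_vals, spacing),
        dose=VolumeGrid(dose_vals, spacing),
        eso_mask=VOIMask(eso, "ESO"),
        gtv_mask=VOIMask(gtv, "GTV"),
        clinical=clinical,
    )


def _drivers(p: SyntheticPatient) -> dict[str, float]:
    """Label drivers, computed with the pipeline's own feature operations."""
    eta = compute_dose_moments(p.dose, p.gtv_mask)["moment_eta_003"]
    v50 = compute_dvh(p.dose, p.eso_mask, (50.0,), (50.0,)).vx[50.0]
    tex = texture_features(
        p.ct.values, p.eso_mask.indicator, n_bins=20, families=("glcm",)
    )["glcm_JointEntropy"]
    return {
        "gtv_moment_eta003": eta,
        "eso_v50": v50,
        "eso_glcm_joint_entropy": tex,
        "fraction_dose_2gy": float(p.clinical["fraction_dose"] == 2.0),
    }


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Generate a labelled cohort; identical seeds give identical cohorts."""
    rng = np.random.default_rng(spec.seed)
    patients = [
        _make_patient(rng, spec, f"P{i:04d}") for i in range(spec.n_patients)
    ]
    if not patients:
        return patients

    driver_rows = pd.DataFrame([_drivers(p) for p in patients])
    logits = np.zeros(len(patients))
    for name, beta in spec.effect_vector.items():
        col = driver_rows[name].to_numpy(dtype=float)
        sd = col.std()
        zcol = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        logits += beta * zcol
    logits += spec.noise_sd * rng.standard_normal(len(patients))

    # intercept: match expected prevalence
    def excess(c):
        return (1.0 / (1.0 + np.exp(-(logits + c)))).mean() - spec.prevalence

    intercept = brentq(excess, -30.0, 30.0)
    prob = 1.0 / (1.0 + np.exp(-(logits + intercept)))
    labels = (rng.random(len(patients)) < prob).astype(int)
    for p, lab in zip(patients, labels):
        p.label = int(lab)
    return patients


def cohort_tables(patients: list[SyntheticPatient]) -> tuple[pd.DataFrame, pd.Series]:
    """Clinical covariate table and label vector of a generated cohort."""
    clin = pd.DataFrame([p.clinical for p in patients]).set_index("patient_id")
    labels = pd.Series(
        [p.label for p in patients],
        index=clin.index,
        name="ef",
    )
    return clin, labels


def write_cohort(patients: list[SyntheticPatient], spec: CohortSpec, out_dir) -> None:
    """Write the cohort as NIfTI volumes + clinical/label CSVs + spec YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in patients:
        save_volume(p.ct, out / f"{p.patient_id}_ct.nii.gz")
        save_volume(p.dose, out / f"{p.patient_id}_dose.nii.gz")
        save_mask(p.eso_mask, p.ct, out / f"{p.patient_id}_eso.nii.gz")
        save_mask(p.gtv_mask, p.ct, out / f"{p.patient_id}_gtv.nii.gz")
    clin, labels = cohort_tables(patients)
    clin.to_csv(out / "clinical.csv")
    labels.to_frame().to_csv(out / "labels.csv")
    meta = {
        "n_patients": spec.n_patients,
        "prevalence": spec.prevalence,
        "effect_vector": spec.effect_vector,
        "noise_sd": spec.noise_sd,
        "grid_shape": list(spec.grid_shape),
        "spacing": list(spec.spacing),
        "seed": spec.seed,
    }
    (out / "cohort_spec.yaml").write_text(yaml.safe_dump(meta))


def table1_fixtures() -> dict[str, ContingencyTable]:
    """EF/NEF contingency tables of the modelled cohort's characteristics.

    Row order is (EF, NEF); categories that are structurally empty (T1,
    overall stage I) are included as zero columns and dropped by the test.
    """
    t = ContingencyTable
    return {
        "gender": t(np.array([[115, 34], [94, 44]]), col_labels=("Male", "Female")),
        "pathology": t(
            np.array([[147, 2], [138, 0]]),
            col_labels=("Squamous", "Adenocarcinoma"),
        ),
        "t_stage": t(
            np.array([[0, 10, 105, 34], [0, 11, 101, 26]]),
            col_labels=("T1", "T2", "T3", "T4"),
        ),
        "n_stage": t(
            np.array([[13, 92, 39, 5], [22, 70, 38, 8]]),
            col_labels=("N0", "N1", "N2", "N3"),
        ),
        "m_stage": t(np.array([[126, 23], [120, 18]]), col_labels=("M0", "M1")),
        "overall_stage": t(
            np.array([[0, 15, 81, 53], [0, 22, 73, 43]]),
            col_labels=("I", "II", "III", "IV"),
        ),
        "treatment": t(
            np.array([[99, 23, 27], [87, 18, 33]]),
            col_labels=("CCRT", "SRT", "RT"),
        ),
        "fraction_dose": t(
            np.array([[78, 71], [106, 32]]), col_labels=("1.8Gy", "2.0Gy")
        ),
    }
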