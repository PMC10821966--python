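"""End-to-end study orchestration.

Wires the stages together: cohort generation (or ingestion from a
directory of NIfTI volumes), per-VOI radiomics and dosiomics extraction
over ESO, GTV and the combined EG volume, assembly of the nine
VOI x omics feature groups (ESO/GTV/EG x R/D/RD), per-group repeated-split
evaluation with embedded feature selection, and report emission
(metric means, CIs, pairwise model tests, decision curves).

EG feature sets default to extraction on the union mask (EG is a VOI of
its own); ``eg_mode="concat"`` instead concatenates the ESO and GTV
feature columns, for the reading under which the combined model simply
pools both single-VOI feature sets.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dosiomics_features import DoseFeatureConfig, extract_dose_profile
from .feature_selection import SelectionConfig
from .imaging_core import (
    FilterConfig,
    VOIMask,
    combine_masks,
    load_mask,
    load_volume,
)
from .model_eval import (
    EvalReport,
    RidgeConfig,
    fit_ridge,
    net_benefit_curve,
    paired_model_test,
    repeated_evaluation,
)
from .radiomics_features import extract_radiomics_profile
from .synthetic_cohort import CohortSpec, SyntheticPatient, cohort_tables, generate_cohort

__all__ = [
    "VOIS",
    "OMICS",
    "MODEL_TAGS",
    "FeatureMatrix",
    "RunConfig",
    "extract_cohort_features",
    "assemble_feature_groups",
    "run_study",
    "load_cohort",
]

VOIS = ("ESO", "GTV", "EG")
OMICS = ("R", "D", "RD")
MODEL_TAGS = tuple(f"{voi}-{om}" for om, voi in itertools.product(OMICS, VOIS))


@dataclass
class FeatureMatrix:
    """Patients x named features, with per-column VOI/omics provenance."""

    data: pd.DataFrame
    tags: pd.DataFrame  # index = feature name; columns: voi, omics

    def __post_init__(self) -> None:
        if not self.data.columns.equals(self.tags.index):
            raise ValueError("tags must describe exactly the data columns")

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def _tagged(df: pd.DataFrame, voi: str, omics: str) -> FeatureMatrix:
    tags = pd.DataFrame({"voi": voi, "omics": omics}, index=df.columns)
    return FeatureMatrix(df, tags)


def _concat(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    data = pd.concat([a.data, b.data], axis=1)
    tags = pd.concat([a.tags, b.tags], axis=0)
    return FeatureMatrix(data, tags)


def patient_masks(p: SyntheticPatient) -> dict[str, VOIMask]:
    return {
        "ESO": p.eso_mask,
        "GTV": p.gtv_mask,
        "EG": combine_masks(p.eso_mask, p.gtv_mask),
    }


def extract_cohort_features(
    patients: list[SyntheticPatient],
    filter_cfg: FilterConfig | None = None,
    dose_cfg: DoseFeatureConfig | None = None,
    eg_mode: str = "union",
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-VOI radiomics (R) and dosiomics (D) tables for a cohort.

    Returns a mapping ``(voi, omics) -> DataFrame`` indexed by patient.
    Under ``eg_mode="union"`` EG features are extracted on the union mask;
    under ``"concat"`` the EG entry is the column concatenation of the
    (prefixed) ESO and GTV tables.
    """
    if eg_mode not in ("union", "concat"):
        raise ValueError("eg_mode must be 'union' or 'concat'")
    filter_cfg = filter_cfg or FilterConfig()
    dose_cfg = dose_cfg or DoseFeatureConfig()
    extract_vois = ("ESO", "GTV", "EG") if eg_mode == "union" else ("ESO", "GTV")
    rows: dict[tuple[str, str], list] = {
        (voi, om): [] for voi in extract_vois for om in ("R", "D")
    }
    ids = []
    for p in patients:
        ids.append(p.patient_id)
        masks = patient_masks(p)
        for voi in extract_vois:
            rows[(voi, "R")].append(
                extract_radiomics_profile(p.ct, masks[voi], filter_cfg)
            )
            rows[(voi, "D")].append(extract_dose_profile(p.dose, masks[voi], dose_cfg))
    out = {
        key: pd.DataFrame(vals, index=pd.Index(ids, name="patient_id"))
        for key, vals in rows.items()
    }
    if eg_mode == "concat":
        for om in ("R", "D"):
            out[("EG", om)] = pd.concat(
                [
                    out[("ESO", om)].add_prefix("ESO:"),
                    out[("GTV", om)].add_prefix("GTV:"),
                ],
                axis=1,
            )
    return out


def assemble_feature_groups(
    tables: dict[tuple[str, str], pd.DataFrame]
) -> dict[str, FeatureMatrix]:
    """The nine VOI x omics model feature groups.

    R and D groups are the per-VOI tables; RD groups are their column
    concatenation.  All tables must share the patient index.
    """
    index = None
    for df in tables.values():
        if index is None:
            index = df.index
        elif not df.index.equals(index):
            raise ValueError("feature tables do not share a patient index")
    groups: dict[str, FeatureMatrix] = {}
    for voi in VOIS:
        r = _tagged(tables[(voi, "R")].add_prefix(f"{voi}|R|"), voi, "R")
        d = _tagged(tables[(voi, "D")].add_prefix(f"{voi}|D|"), voi, "D")
        groups[f"{voi}-R"] = r
        groups[f"{voi}-D"] = d
        groups[f"{voi}-RD"] = _concat(r, d)
    return groups


@dataclass
class RunConfig:
    """Serializable configuration of a full nine-model study run."""

    cohort_dir: str | None = None  # ingest instead of simulate when set
    n_patients: int = 287
    prevalence: float = 149.0 / 287.0
    noise_sd: float = 1.0
    grid_shape: tuple[int, int, int] = (24, 24, 32)
    spacing: tuple[float, float, float] = (1.152, 1.152, 3.0)
    log_sigmas: tuple[float, ...] = (1.0, 3.0, 6.0)
    wavelet_subbands: tuple[str, ...] = FilterConfig().wavelet_subbands
    bin_numbers: tuple[int, ...] = (10, 20, 30, 40, 50)
    dose_bins: int = 20
    eg_mode: str = "union"
    n_iterations: int = 30
    n_resamples: int = 100
    p_thresh: float = 0.01
    top_frac: float = 0.10
    min_keep: int = 40
    r_thresh: float = 0.5
    n_folds: int = 10
    seed: int = 0
    output_dir: str = "study_output"

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            log_sigmas=tuple(self.log_sigmas),
            wavelet_subbands=tuple(self.wavelet_subbands),
            bin_numbers=tuple(self.bin_numbers),
        )

    def dose_config(self) -> DoseFeatureConfig:
        return DoseFeatureConfig(n_bins=self.dose_bins)

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            n_resamples=self.n_resamples,
            p_thresh=self.p_thresh,
            top_frac=self.top_frac,
            min_keep=self.min_keep,
            r_thresh=self.r_thresh,
        )

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_patients=self.n_patients,
            prevalence=self.prevalence,
            noise_sd=self.noise_sd,
            grid_shape=tuple(self.grid_shape),
            spacing=tuple(self.spacing),
            seed=self.seed,
        )

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))


def _plain(obj):
    """YAML-safe plain-python conversion (tuples -> lists, numpy -> float)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_cohort(cohort_dir) -> list[SyntheticPatient]:
    """Read a cohort directory written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    clin = pd.read_csv(cohort_dir / "clinical.csv").set_index("patient_id")
    labels = pd.read_csv(cohort_dir / "labels.csv").set_index("patient_id")["ef"]
    patients = []
    for pid in clin.index:
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                ct=load_volume(cohort_dir / f"{pid}_ct.nii.gz"),
                dose=load_volume(cohort_dir / f"{pid}_dose.nii.gz"),
                eso_mask=load_mask(cohort_dir / f"{pid}_eso.nii.gz", "ESO"),
                gtv_mask=load_mask(cohort_dir / f"{pid}_gtv.nii.gz", "GTV"),
                clinical=clin.loc[pid].to_dict() | {"patient_id": pid},
                label=int(labels.loc[pid]),
            )
        )
    return patients


def run_study(cfg: RunConfig) -> dict[str, EvalReport]:
    """Execute the full nine-model study and write all report files.

    Outputs in ``cfg.output_dir``: ``table2_metrics.csv`` (metric means per
    model/cohort), ``table3_ci.csv`` (95% CIs of the AUC),
    ``pairwise_tests.csv`` (paired t-test p-values on test AUCs),
    ``dca_curves.csv`` (net-benefit curves on the final split), and
    ``run_config.yaml``.  Reruns with the same config are reproducible.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.cohort_dir:
        patients = load_cohort(cfg.cohort_dir)
    else:
        patients = generate_cohort(cfg.cohort_spec())
    if len(patients) < 10:
        raise ValueError("cohort too small for a stratified 7:3 study")
    _, labels = cohort_tables(patients)

    tables = extract_cohort_features(
        patients, cfg.filter_config(), cfg.dose_config(), cfg.eg_mode
    )
    groups = assemble_feature_groups(tables)
    sel_cfg = cfg.selection_config()
    ridge_cfg = RidgeConfig(n_folds=cfg.n_folds)

    reports: dict[str, EvalReport] = {}
    dca_frames = []
    for tag in MODEL_TAGS:
        fm = groups[tag]
        report = repeated_evaluation(
            fm.data,
            labels.to_numpy(),
            n_iter=cfg.n_iterations,
            selection_cfg=sel_cfg,
            ridge_cfg=ridge_cfg,
            seed=cfg.seed,
            model_tag=tag,
        )
        reports[tag] = report
        dca_frames.append(_dca_frame(fm, labels, report, ridge_cfg, cfg.seed, tag))

    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    agg = pd.concat([r.aggregate() for r in reports.values()], ignore_index=True)
    table2 = agg.pivot_table(
        index=["metric", "cohort"], columns="model", values="mean", sort=False
    ).reindex(columns=list(MODEL_TAGS))
    table2.to_csv(out / "table2_metrics.csv")

    ci = agg[agg["metric"] == "AUC"].assign(**meta)
    ci.to_csv(out / "table3_ci.csv", index=False)

    pw_rows = []
    for a, b in itertools.combinations(MODEL_TAGS, 2):
        pw_rows.append(
            {"model_a": a, "model_b": b,
             "p_test_auc": paired_model_test(
                 reports[a].test_aucs(), reports[b].test_aucs()),
             **meta}
        )
    pd.DataFrame(pw_rows).to_csv(out / "pairwise_tests.csv", index=False)

    pd.concat(dca_frames, ignore_index=True).assign(**meta).to_csv(
        out / "dca_curves.csv", index=False
    )

    full_records = pd.concat(
        [r.records.assign(model=tag) for tag, r in reports.items()],
        ignore_index=True,
    ).assign(**meta)
    full_records.to_csv(out / "iteration_metrics.csv", index=False)

    cfg.to_yaml(out / "run_config.yaml")
    return reports


def _dca_frame(fm, labels, report, ridge_cfg, seed, tag) -> pd.DataFrame:
    """Net-benefit curve of the model refit on a final stratified split."""
    from sklearn.model_selection import train_test_split

    from .feature_selection import standardize

    y = labels.to_numpy()
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), train_size=0.7, stratify=y, random_state=seed
    )
    cols = report.selected_features or list(fm.data.columns)
    z_train = standardize(fm.data.iloc[idx_train])
    z_test = standardize(fm.data.iloc[idx_train], fm.data.iloc[idx_test])
    model = fit_ridge(z_train[cols], y[idx_train], ridge_cfg, seed=seed)
    frames = []
    for cohort, z, yy in (
        ("train", z_train[cols], y[idx_train]),
        ("test", z_test[cols], y[idx_test]),
    ):
        curve = net_benefit_curve(model.predict_proba(z), yy).as_frame()
        frames.append(curve.assign(model_tag=tag, cohort=cohort))
    return pd.concat(frames, ignore_index=True)
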