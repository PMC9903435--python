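"""Readers and encoders for the clinical table and PET volumes.

The clinical table follows the standard NSCLC covariate schema: age, sex,
histology, T/N/M stage, overall stage, smoking history, smoking amount
(pack-years), plus overall-survival time in days and the event indicator.
PET volumes are 3-D NIfTI images stored with axis roles
(left-right, anterior-posterior, inferior-superior).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .survival import SurvivalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SEX_LEVELS",
    "HISTOLOGY_LEVELS",
    "T_LEVELS",
    "N_LEVELS",
    "M_LEVELS",
    "STAGE_LEVELS",
    "SMOKING_LEVELS",
    "ClinicalFeatures",
    "ClinicalTable",
    "DesignMatrix",
    "PETVolume",
    "read_clinical_table",
    "write_clinical_table",
    "encode_design",
    "decode_design_row",
    "load_volume",
    "save_volume",
    "normalize_volume",
    "coronal_mip",
    "split_cohort",
    "stratified_kfold",
    "save_split_manifest",
    "load_split_manifest",
]

# Categorical enumerations; the first level of each block is the reference
# level dropped from the one-hot design (matching the convention in which
# reference rows of a multivariate Cox table print a log hazard ratio of 0).
SEX_LEVELS = ("female", "male")
HISTOLOGY_LEVELS = ("NOS", "adenocarcinoma", "large_cell", "squamous")
T_LEVELS = ("T1", "T2", "T3", "T4")
N_LEVELS = ("N0", "N1", "N2", "N3")
M_LEVELS = ("M0", "M1")
STAGE_LEVELS = ("I", "II", "III", "IV")
SMOKING_LEVELS = ("ever", "never")

_CATEGORICAL_BLOCKS = {
    "sex": SEX_LEVELS,
    "histology": HISTOLOGY_LEVELS,
    "t_stage": T_LEVELS,
    "n_stage": N_LEVELS,
    "m_stage": M_LEVELS,
    "overall_stage": STAGE_LEVELS,
    "smoking_history": SMOKING_LEVELS,
}

REQUIRED_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "histology",
    "t_stage",
    "n_stage",
    "m_stage",
    "overall_stage",
    "smoking_history",
    "smoking_amount",
    "os_days",
    "event",
)


@dataclass(frozen=True)
class ClinicalFeatures:
    """One subject's clinical covariate vector (validated on construction)."""

    subject_id: str
    age: float
    sex: str
    histology: str
    t_stage: str
    n_stage: str
    m_stage: str
    overall_stage: str
    smoking_history: str
    smoking_amount: float

    def __post_init__(self) -> None:
        if not (self.age > 0 and np.isfinite(self.age)):
            raise ValueError(f"{self.subject_id}: age must be positive, got {self.age!r}")
        if not (self.smoking_amount >= 0 and np.isfinite(self.smoking_amount)):
            raise ValueError(
                f"{self.subject_id}: smoking_amount must be nonnegative, "
                f"got {self.smoking_amount!r}"
            )
        for name, levels in _CATEGORICAL_BLOCKS.items():
            value = getattr(self, name)
            if value not in levels:
                raise ValueError(
                    f"{self.subject_id}: {name}={value!r} not in {levels}"
                )
        if self.smoking_history == "never" and self.smoking_amount != 0:
            raise ValueError(
                f"{self.subject_id}: never-smokers must have smoking_amount = 0"
            )


class ClinicalTable(NamedTuple):
    features: list[ClinicalFeatures]
    records: list[SurvivalRecord]
    rejected: list[tuple[int, str]]  # (1-based data line number, reason)


def read_clinical_table(path, sep: str = ",") -> ClinicalTable:
    """Read and validate the clinical CSV.

    Rows failing validation (unknown category level, nonpositive age or time,
    missing value) are rejected and reported with their line numbers rather
    than aborting the load — mirroring the exclusion of subjects with
    incomplete clinical factors from the study cohort.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} is missing columns: {missing}")
    features: list[ClinicalFeatures] = []
    records: list[SurvivalRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        line_no = int(i) + 1
        try:
            if row[list(REQUIRED_COLUMNS)].isna().any():
                bad = [c for c in REQUIRED_COLUMNS if pd.isna(row[c])]
                raise ValueError(f"missing value(s) in {bad}")
            feat = ClinicalFeatures(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                histology=str(row["histology"]),
                t_stage=str(row["t_stage"]),
                n_stage=str(row["n_stage"]),
                m_stage=str(row["m_stage"]),
                overall_stage=str(row["overall_stage"]),
                smoking_history=str(row["smoking_history"]),
                smoking_amount=float(row["smoking_amount"]),
            )
            rec = SurvivalRecord(
                subject_id=str(row["subject_id"]),
                time=float(row["os_days"]),
                event=int(row["event"]),
            )
        except (ValueError, TypeError) as exc:
            rejected.append((line_no, str(exc)))
            logger.warning("clinical table line %d rejected: %s", line_no, exc)
            continue
        features.append(feat)
        records.append(rec)
    if rejected:
        logger.info(
            "clinical table %s: %d/%d rows rejected", path, len(rejected), len(df)
        )
    return ClinicalTable(features, records, rejected)


def write_clinical_table(path, features, records, sep: str = ",") -> None:
    rows = []
    for f, r in zip(features, records, strict=True):
        rows.append(
            {
                "subject_id": f.subject_id,
                "age": f.age,
                "sex": f.sex,
                "histology": f.histology,
                "t_stage": f.t_stage,
                "n_stage": f.n_stage,
                "m_stage": f.m_stage,
                "overall_stage": f.overall_stage,
                "smoking_history": f.smoking_history,
                "smoking_amount": f.smoking_amount,
                "os_days": r.time,
                "event": r.event,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class DesignMatrix:
    """One-hot design matrix with reference-level bookkeeping.

    Columns: ``age`` and ``smoking_amount`` continuous, then one dummy per
    non-reference level of each categorical block (17 columns total).
    """

    matrix: np.ndarray
    column_names: tuple[str, ...]
    reference_levels: dict

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("matrix width does not match column_names")


def design_column_names() -> tuple[str, ...]:
    names = ["age", "smoking_amount"]
    for block, levels in _CATEGORICAL_BLOCKS.items():
        names.extend(f"{block}={lvl}" for lvl in levels[1:])
    return tuple(names)


def encode_design(features: Sequence[ClinicalFeatures]) -> DesignMatrix:
    """Encode clinical features as the 17-column one-hot design matrix.

    Reference levels (dropped): female, NOS, T1, N0, M0, stage I, ever-smoker.
    """
    if len(features) == 0:
        raise ValueError("cannot encode an empty feature list")
    names = design_column_names()
    X = np.zeros((len(features), len(names)), dtype=float)
    col = {name: j for j, name in enumerate(names)}
    for i, f in enumerate(features):
        X[i, col["age"]] = f.age
        X[i, col["smoking_amount"]] = f.smoking_amount
        for block in _CATEGORICAL_BLOCKS:
            value = getattr(f, block)
            key = f"{block}={value}"
            if key in col:
                X[i, col[key]] = 1.0
    return DesignMatrix(
        matrix=X,
        column_names=names,
        reference_levels={b: lv[0] for b, lv in _CATEGORICAL_BLOCKS.items()},
    )


def decode_design_row(design: DesignMatrix, i: int) -> dict:
    """Recover the categorical levels of row ``i`` from the one-hot encoding."""
    out = {}
    row = design.matrix[i]
    col = {name: j for j, name in enumerate(design.column_names)}
    out["age"] = float(row[col["age"]])
    out["smoking_amount"] = float(row[col["smoking_amount"]])
    for block, levels in _CATEGORICAL_BLOCKS.items():
        level = design.reference_levels[block]
        for lvl in levels[1:]:
            if row[col[f"{block}={lvl}"]] == 1.0:
                level = lvl
        out[block] = level
    return out


# ---------------------------------------------------------------------------
# PET volumes
# ---------------------------------------------------------------------------

AXIS_ROLES = ("LR", "AP", "IS")  # left-right, anterior-posterior, inferior-superior


@dataclass
class PETVolume:
    """A 3-D nonnegative intensity array with axis-role and spacing metadata."""

    data: np.ndarray
    axes: tuple[str, str, str] = AXIS_ROLES
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if len(self.axes) != 3:
            raise ValueError("axes must name all three axis roles")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")


def load_volume(path) -> PETVolume:
    """Load a NIfTI volume into (LR, AP, IS) axis order.

    The image is reoriented to the closest RAS-canonical orientation, so the
    array axes run left-to-right, posterior-to-anterior and inferior-to-
    superior (direction along an axis does not affect downstream use; only
    the axis roles matter, e.g. the MIP collapses the AP axis).  Negative
    intensities are clipped to zero with a logged count.
    """
    import nibabel as nib

    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    n_neg = int(np.sum(data < 0))
    if n_neg:
        logger.info("%s: clipped %d negative voxels to 0", path, n_neg)
        data = np.clip(data, 0.0, None)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PETVolume(data=data, axes=AXIS_ROLES, spacing=zooms, meta={"path": str(path)})


def save_volume(vol: PETVolume, path) -> None:
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine), str(path))


def normalize_volume(
    vol: PETVolume, method: str = "clip_scale", clip_max: float | None = None
) -> PETVolume:
    """Clip intensities at a ceiling and scale to [0, 1] per volume.

    ``clip_max`` defaults to the volume maximum (pure rescaling).  The method
    and parameters are recorded in the volume's provenance metadata.
    """
    if method != "clip_scale":
        raise ValueError(f"unknown normalization method {method!r}")
    data = np.asarray(vol.data, dtype=np.float32)
    vmax = float(data.max())
    if vmax <= 0:
        raise ValueError("cannot normalize an all-zero volume")
    ceiling = float(clip_max) if clip_max is not None else vmax
    if ceiling <= 0:
        raise ValueError("clip_max must be positive")
    out = np.clip(data, 0.0, ceiling) / ceiling
    meta = dict(vol.meta)
    meta["normalization"] = {"method": method, "clip_max": ceiling}
    return PETVolume(data=out, axes=vol.axes, spacing=vol.spacing, meta=meta)


def coronal_mip(vol: PETVolume) -> np.ndarray:
    """Coronal maximum intensity projection: voxelwise max along the AP axis.

    Output shape is (LR extent, IS extent).
    """
    if "AP" not in vol.axes:
        raise ValueError(f"volume axes {vol.axes} lack an anterior-posterior label")
    ap_axis = vol.axes.index("AP")
    return np.max(vol.data, axis=ap_axis)


# ---------------------------------------------------------------------------
# Cohort splitting
# ---------------------------------------------------------------------------


def _strata(records, stratify_on: str) -> np.ndarray:
    if stratify_on == "event":
        return np.array([r.event for r in records])
    if stratify_on == "none":
        return np.zeros(len(records), dtype=int)
    raise ValueError(f"unknown stratification variable {stratify_on!r}")


def split_cohort(
    records, fraction: float = 0.8, stratify_on: str = "event", seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split; returns (train_idx, test_idx)."""
    from sklearn.model_selection import train_test_split

    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    y = _strata(records, stratify_on)
    idx = np.arange(len(records))
    train, test = train_test_split(
        idx, train_size=fraction, stratify=y, random_state=seed, shuffle=True
    )
    return np.sort(train), np.sort(test)


def stratified_kfold(
    records, k: int = 5, stratify_on: str = "event", seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition; returns k (train_idx, test_idx) pairs.

    Folds are disjoint and exhaustive; a stratum with fewer members than
    ``k`` raises with the stratum named.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be at least 2")
    y = _strata(records, stratify_on)
    values, counts = np.unique(y, return_counts=True)
    for v, c in zip(values, counts):
        if c < k:
            raise ValueError(
                f"stratum {stratify_on}={v} has only {c} members, fewer than k={k}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (np.asarray(tr), np.asarray(te)) for tr, te in skf.split(np.zeros(len(y)), y)
    ]


def save_split_manifest(path, records, folds, seed: int, stratify_on: str) -> None:
    ids = [r.subject_id for r in records]
    payload = {
        "seed": seed,
        "stratify_on": stratify_on,
        "folds": [
            {
                "train": [ids[i] for i in tr],
                "test": [ids[i] for i in te],
            }
            for tr, te in folds
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_split_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
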