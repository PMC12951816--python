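"""Clinical feature encoding and clinical-imaging fusion with Random Forest.

The clinical table carries 15 baseline indices per patient: five continuous
(age, gravidity, parity, embryo transfers before/after testing) and ten
binary lesion/test indicators (1 = lesion present or test positive).  Two
composites are added: ``pathology_count`` (sum of the six lesion
indicators) and ``inflammation_score`` (sum of the four endometrial or
vaginal test indicators).  Imaging enters through five statistical
descriptors of each case's 12 per-case ensemble scores (mean, SD, range,
IQR, median), giving a 22-predictor fused matrix (17 clinical + 5 scores).

Protocol: a group-aware shuffled 70/30 train/validation split (seed 42);
median imputation fitted on training rows only; grouped 5-fold exhaustive
grid search maximizing accuracy to tune a Random Forest; validation metrics
per :mod:`uteroflow.evaluation` with probability threshold 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, GroupKFold, GroupShuffleSplit

from .evaluation import MetricsReport, compute_metrics

CONTINUOUS_VARS = ["age", "gravidity", "parity", "transfers_before", "transfers_after"]
PATHOLOGY_VARS = [
    "adenomyosis",
    "leiomyoma",
    "uterine_anomaly",
    "endometrial_polyp",
    "oviductal_anomaly",
    "ovarian_endometrioma",
]
INFLAMMATION_VARS = [
    "hysteroscopy_abnormal",
    "cd138_positive",
    "mycoplasma_positive",
    "non_lactobacillus",
]
BINARY_VARS = PATHOLOGY_VARS + INFLAMMATION_VARS
BASELINE_VARS = CONTINUOUS_VARS + BINARY_VARS  # the 15 baseline indices
COMPOSITE_VARS = ["pathology_count", "inflammation_score"]
DESCRIPTOR_VARS = ["score_mean", "score_std", "score_range", "score_iqr", "score_median"]

DEFAULT_RF_GRID = {
    "n_estimators": [100, 200],
    "max_depth": [3, None],
    "max_features": ["sqrt"],
}


# ---------------------------------------------------------------------------
# Records and encoding
# ---------------------------------------------------------------------------

@dataclass
class ClinicalRecord:
    """One patient's clinical indices; binary fields may be None (missing)."""

    case_id: str
    age: float
    gravidity: int
    parity: int
    transfers_before: int
    transfers_after: int
    leiomyoma: int | None
    adenomyosis: int | None
    ovarian_endometrioma: int | None
    endometrial_polyp: int | None
    uterine_anomaly: int | None
    oviductal_anomaly: int | None
    hysteroscopy_abnormal: int | None
    cd138_positive: int | None
    non_lactobacillus: int | None
    mycoplasma_positive: int | None
    truth: int

    def __post_init__(self) -> None:
        for name in BINARY_VARS:
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValueError(
                    f"case {self.case_id!r}, column {name!r}: "
                    f"indicator must be 0, 1 or missing, got {v!r}"
                )
        if self.truth not in (0, 1):
            raise ValueError(f"case {self.case_id!r}: truth must be 0 or 1")


@dataclass
class CompositeFeatures:
    pathology_count: float
    inflammation_score: float


@dataclass
class DescriptorSet:
    """Five summary statistics of a case's per-case ensemble scores."""

    score_mean: float
    score_std: float
    score_range: float
    score_iqr: float
    score_median: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DESCRIPTOR_VARS}


def encode_clinical(record: ClinicalRecord) -> tuple[pd.Series, CompositeFeatures]:
    """Encode one record: continuous pass-through, binaries 0/1 (NaN when
    missing), composites summed over the observed indicators."""
    values: dict[str, float] = {v: float(getattr(record, v)) for v in CONTINUOUS_VARS}
    for v in BINARY_VARS:
        raw = getattr(record, v)
        values[v] = np.nan if raw is None else float(raw)
    series = pd.Series(values, name=record.case_id)
    pathology = float(np.nansum([values[v] for v in PATHOLOGY_VARS]))
    inflammation = float(np.nansum([values[v] for v in INFLAMMATION_VARS]))
    return series, CompositeFeatures(pathology, inflammation)


def clinical_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    """Tidy table of the 15 baseline indices plus ``truth``, one row/case."""
    rows, truths = [], {}
    for rec in records:
        series, _ = encode_clinical(rec)
        rows.append(series)
        truths[rec.case_id] = rec.truth
    frame = pd.DataFrame(rows)
    frame.index.name = "case_id"
    frame["truth"] = pd.Series(truths)
    return frame


# ---------------------------------------------------------------------------
# Imputation and descriptors
# ---------------------------------------------------------------------------

def impute_median(matrix: pd.DataFrame, training_row_mask: np.ndarray) -> pd.DataFrame:
    """Median-impute missing/infinite entries using training rows only.

    Medians are computed from the observed training-row values of each
    column and applied to every row; validation rows never influence the
    imputed value.
    """
    training_row_mask = np.asarray(training_row_mask, dtype=bool)
    if training_row_mask.shape[0] != len(matrix):
        raise ValueError("training_row_mask length must match the matrix")
    out = matrix.replace([np.inf, -np.inf], np.nan).astype(float)
    train = out.loc[training_row_mask]
    medians = train.median(axis=0, skipna=True)
    dead = medians.index[medians.isna()]
    if len(dead):
        raise ValueError(
            f"columns all-missing in training rows: {sorted(dead.tolist())}"
        )
    return out.fillna(medians)


def summarize_scores(values: Sequence[float] | np.ndarray) -> DescriptorSet:
    """Five descriptors of a case's ensemble scores.

    SD is the sample (n-1) standard deviation, defined as 0 for a single
    value; the IQR uses linear-interpolation quantiles.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty score vector")
    std = 0.0 if values.size == 1 else float(np.std(values, ddof=1))
    q1, q3 = np.percentile(values, [25, 75])
    return DescriptorSet(
        score_mean=float(values.mean()),
        score_std=std,
        score_range=float(values.max() - values.min()),
        score_iqr=float(q3 - q1),
        score_median=float(np.median(values)),
    )


def descriptor_frame(case_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-case DescriptorSet table from ``case_id, score`` records."""
    rows = {
        cid: summarize_scores(sub["score"].to_numpy()).as_dict()
        for cid, sub in case_scores.groupby("case_id", sort=True)
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "case_id"
    return frame


# ---------------------------------------------------------------------------
# Split, fit, evaluate
# ---------------------------------------------------------------------------

def split_cohort(
    case_ids: Sequence[str], validation_fraction: float = 0.30, seed: int = 42
) -> tuple[list[str], list[str]]:
    """Group-aware shuffled 70/30 split: each case wholly in one partition."""
    case_ids = list(case_ids)
    if len(case_ids) < 2:
        raise ValueError("need >= 2 cases to split")
    splitter = GroupShuffleSplit(
        n_splits=1, test_size=validation_fraction, random_state=seed
    )
    idx = np.arange(len(case_ids))
    train_idx, val_idx = next(splitter.split(idx, groups=case_ids))
    return [case_ids[i] for i in train_idx], [case_ids[i] for i in val_idx]


def fit_random_forest(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: Sequence[str],
    grid: Mapping[str, Sequence] | None = None,
    grouped_k: int = 5,
    seed: int = 42,
) -> RandomForestClassifier:
    """Grouped k-fold exhaustive grid search maximizing accuracy, then a
    refit of the winning Random Forest on all training rows."""
    grid = dict(grid) if grid else dict(DEFAULT_RF_GRID)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be non-empty")
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        param_grid=grid,
        scoring="accuracy",
        cv=GroupKFold(n_splits=grouped_k),
        refit=True,
    )
    search.fit(X, y, groups=list(groups))
    return search.best_estimator_


def evaluate_model(
    classifier: RandomForestClassifier,
    X_val: pd.DataFrame,
    y_val: np.ndarray,
    threshold: float = 0.5,
) -> MetricsReport:
    proba = classifier.predict_proba(X_val)[:, list(classifier.classes_).index(1)]
    preds = (proba >= threshold).astype(int)
    return compute_metrics(preds, np.asarray(y_val, dtype=int), proba)


# ---------------------------------------------------------------------------
# End-to-end fusion
# ---------------------------------------------------------------------------

def build_feature_matrix(
    clinical: pd.DataFrame,
    train_ids: Sequence[str],
    case_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the predictor matrix (17 clinical, +5 descriptors if fused).

    Imputation comes first (training-row medians), composites are computed
    from the imputed indicators, and undefined ``score_std`` is set to 0.
    """
    features = clinical.drop(columns=["truth"])
    if case_scores is not None:
        desc = descriptor_frame(case_scores)
        features = features.join(desc, how="left")
    train_mask = features.index.isin(set(train_ids))
    if case_scores is not None:
        features["score_std"] = features["score_std"].fillna(0.0)
    imputed = impute_median(features, train_mask)
    imputed["pathology_count"] = imputed[PATHOLOGY_VARS].sum(axis=1)
    imputed["inflammation_score"] = imputed[INFLAMMATION_VARS].sum(axis=1)
    order = BASELINE_VARS + COMPOSITE_VARS
    if case_scores is not None:
        order = order + DESCRIPTOR_VARS
    return imputed[order]


def run_fusion(
    clinical: pd.DataFrame,
    case_scores: pd.DataFrame | None = None,
    seed: int = 42,
    grid: Mapping[str, Sequence] | None = None,
    grouped_k: int = 5,
) -> dict:
    """Train and evaluate the clinical-only or fused Random Forest.

    ``clinical`` is the :func:`clinical_frame` table (indexed by case_id);
    ``case_scores`` are per-case ensemble records (``case_id, score``) —
    pass None for the clinical-only model.  Returns the fitted classifier,
    the split, the feature matrix and the validation MetricsReport.
    """
    case_ids = list(clinical.index)
    train_ids, val_ids = split_cohort(case_ids, seed=seed)
    X = build_feature_matrix(clinical, train_ids, case_scores)
    y = clinical["truth"].astype(int)
    clf = fit_random_forest(
        X.loc[train_ids],
        y.loc[train_ids].to_numpy(),
        groups=train_ids,
        grid=grid,
        grouped_k=grouped_k,
        seed=seed,
    )
    report = evaluate_model(clf, X.loc[val_ids], y.loc[val_ids].to_numpy())
    return {
        "classifier": clf,
        "train_ids": train_ids,
        "validation_ids": val_ids,
        "features": X,
        "report": report,
    }


# ---------------------------------------------------------------------------
# Clinical CSV I/O (header contract = BASELINE_VARS + truth)
# ---------------------------------------------------------------------------

def read_clinical_csv(path) -> list[ClinicalRecord]:
    frame = pd.read_csv(path, dtype={"case_id": str})
    records = []
    for _, row in frame.iterrows():
        kwargs = {"case_id": row["case_id"], "truth": int(row["truth"])}
        for v in CONTINUOUS_VARS:
            kwargs[v] = float(row[v])
        for v in BINARY_VARS:
            raw = row[v]
            kwargs[v] = None if pd.isna(raw) else int(raw)
        records.append(ClinicalRecord(**kwargs))
    return records


def write_clinical_csv(records: Iterable[ClinicalRecord], path) -> None:
    rows = []
    for rec in records:
        row = {"case_id": rec.case_id}
        for v in BASELINE_VARS:
            row[v] = getattr(rec, v)
        row["truth"] = rec.truth
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
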