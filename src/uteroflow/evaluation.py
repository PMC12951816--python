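"""Image-unit and case-unit evaluation of per-image success scores.

Score tables are tidy DataFrames with columns
``case_id, window_start, image_type, fold, repetition, score`` (one row per
combined image per model).  Two evaluation units are supported:

* image unit — every combined image is a sample, scored either by the
  single model of its fold/repetition or by the leave-one-repetition-out
  ensemble (mean of the 11 other repetitions);
* case unit — per case, scores are summed over 20-frame windows
  (17 combined images each); the window with the highest total is the
  case's representative.

Metrics: sensitivity, specificity, accuracy, AUC (rank statistic with
mid-ranked ties) and balanced accuracy = (sensitivity + specificity) / 2.
Results over the 12 repetitions are reported as mean +/- sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

SCORE_COLUMNS = ["case_id", "window_start", "image_type", "fold", "repetition", "score"]

#: combined images per 20-frame case-unit window (20 - 4 + 1)
IMAGES_PER_CASE_WINDOW = 17
CASE_WINDOW_FRAMES = 20
DEFAULT_CASE_WINDOWS = 10


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("auc", "sensitivity", "specificity", "accuracy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        self.balanced_accuracy = (self.sensitivity + self.specificity) / 2.0

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
        }


def rank_auc(scores: np.ndarray, truths: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic; ties are mid-ranked."""
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=int)
    n_pos = int(truths.sum())
    n_neg = len(truths) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: truths contain a single class")
    ranks = rankdata(scores)
    return float((ranks[truths == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    predictions: Sequence[int] | np.ndarray,
    truths: Sequence[int] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
) -> MetricsReport:
    """Confusion-matrix metrics plus rank AUC for binary outcomes."""
    predictions = np.asarray(predictions, dtype=int)
    truths = np.asarray(truths, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (len(predictions) == len(truths) == len(scores)):
        raise ValueError("predictions, truths and scores must be equally long")
    tp = int(((predictions == 1) & (truths == 1)).sum())
    tn = int(((predictions == 0) & (truths == 0)).sum())
    fp = int(((predictions == 1) & (truths == 0)).sum())
    fn = int(((predictions == 0) & (truths == 1)).sum())
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    accuracy = (tp + tn) / len(truths)
    return MetricsReport(
        auc=rank_auc(scores, truths),
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
    )


def aggregate_repetitions(
    reports: Sequence[MetricsReport],
) -> dict[str, dict[str, float]]:
    """Per-metric arithmetic mean and sample (n-1) SD across repetitions."""
    if len(reports) < 2:
        raise ValueError("need >= 2 reports to aggregate")
    frame = pd.DataFrame([r.as_dict() for r in reports])
    return {
        metric: {
            "mean": float(frame[metric].mean()),
            "sd": float(frame[metric].std(ddof=1)),
        }
        for metric in frame.columns
    }


# ---------------------------------------------------------------------------
# Ensembling
# ---------------------------------------------------------------------------

def build_ensembles(records: pd.DataFrame) -> pd.DataFrame:
    """Leave-one-repetition-out ensemble scores.

    For every repetition ``r`` present, the ensemble score of an image is
    the arithmetic mean of the other repetitions' scores for that image.
    Returns a frame with ``left_out_repetition`` replacing ``repetition``.
    All repetitions must cover every image.
    """
    reps = sorted(records["repetition"].unique())
    if len(reps) < 2:
        raise ValueError("need >= 2 repetitions to build leave-one-out ensembles")
    keys = ["case_id", "window_start", "image_type"]
    wide = records.pivot_table(
        index=keys, columns="repetition", values="score", aggfunc="mean"
    )
    missing = wide.isna()
    if missing.any().any():
        gaps = sorted(
            {int(rep) for rep in wide.columns[missing.any(axis=0)]}
        )
        raise ValueError(f"missing repetition coverage for repetitions {gaps}")
    out_frames = []
    total = wide.sum(axis=1)
    n = len(reps)
    for rep in reps:
        ens = (total - wide[rep]) / (n - 1)
        frame = ens.rename("score").reset_index()
        frame["left_out_repetition"] = rep
        out_frames.append(frame)
    return pd.concat(out_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Case-unit aggregation
# ---------------------------------------------------------------------------

@dataclass
class CaseRepresentative:
    case_id: str
    best_window_start: int
    total_score: float
    predicted: int

    @property
    def mean_score(self) -> float:
        return self.total_score / IMAGES_PER_CASE_WINDOW


def case_unit_predict(
    window_scores: Mapping[int, float] | pd.Series,
    case_id: str = "",
    frames_per_case: int = 30,
    decision_threshold: float = 0.5,
    n_windows: int = DEFAULT_CASE_WINDOWS,
) -> CaseRepresentative:
    """Pick a case's representative 20-frame window.

    ``window_scores`` maps combined-image ``window_start`` -> score.  The
    candidate windows are 20-frame spans starting at frames
    ``0 .. n_windows-1``; each sums its 17 combined-image scores and the
    maximal total wins (first such window on ties).  The binary prediction
    thresholds the representative mean score (total / 17).
    """
    if isinstance(window_scores, pd.Series):
        window_scores = window_scores.to_dict()
    if frames_per_case < CASE_WINDOW_FRAMES:
        raise ValueError(
            f"case unit needs >= {CASE_WINDOW_FRAMES} frames, got {frames_per_case}"
        )
    max_start = frames_per_case - CASE_WINDOW_FRAMES
    starts = range(min(n_windows - 1, max_start) + 1)
    best_start, best_total = None, -np.inf
    for start in starts:
        needed = range(start, start + IMAGES_PER_CASE_WINDOW)
        try:
            total = float(sum(window_scores[i] for i in needed))
        except KeyError as exc:
            raise ValueError(
                f"case {case_id!r}: missing combined-image score {exc} "
                f"for window starting at frame {start}"
            ) from None
        if total > best_total:
            best_start, best_total = start, total
    assert best_start is not None
    predicted = int(best_total / IMAGES_PER_CASE_WINDOW >= decision_threshold)
    return CaseRepresentative(
        case_id=case_id,
        best_window_start=best_start,
        total_score=best_total,
        predicted=predicted,
    )


# ---------------------------------------------------------------------------
# Report orchestration over score tables
# ---------------------------------------------------------------------------

def _image_unit_report(
    frame: pd.DataFrame, truth_map: Mapping[str, int], threshold: float
) -> MetricsReport:
    truths = frame["case_id"].map(truth_map).to_numpy()
    scores = frame["score"].to_numpy()
    return compute_metrics((scores >= threshold).astype(int), truths, scores)


def image_unit_reports(
    records: pd.DataFrame,
    truth_map: Mapping[str, int],
    ensemble: bool = False,
    threshold: float = 0.5,
) -> list[MetricsReport]:
    """One image-unit MetricsReport per repetition (or per left-out rep)."""
    if ensemble:
        frame = build_ensembles(records)
        group_col = "left_out_repetition"
    else:
        frame, group_col = records, "repetition"
    return [
        _image_unit_report(sub, truth_map, threshold)
        for _, sub in frame.groupby(group_col, sort=True)
    ]


def case_unit_reports(
    records: pd.DataFrame,
    truth_map: Mapping[str, int],
    frames_per_case: int = 30,
    ensemble: bool = False,
    threshold: float = 0.5,
    n_windows: int = DEFAULT_CASE_WINDOWS,
) -> list[MetricsReport]:
    """One case-unit MetricsReport per repetition (or per left-out rep)."""
    if ensemble:
        frame = build_ensembles(records)
        group_col = "left_out_repetition"
    else:
        frame, group_col = records, "repetition"
    reports = []
    for _, sub in frame.groupby(group_col, sort=True):
        reps = [
            case_unit_predict(
                g.set_index("window_start")["score"],
                case_id=cid,
                frames_per_case=frames_per_case,
                decision_threshold=threshold,
                n_windows=n_windows,
            )
            for cid, g in sub.groupby("case_id", sort=True)
        ]
        truths = np.array([truth_map[r.case_id] for r in reps])
        scores = np.array([r.total_score for r in reps])
        preds = np.array([r.predicted for r in reps])
        reports.append(compute_metrics(preds, truths, scores))
    return reports


def case_representative_scores(
    records: pd.DataFrame,
    frames_per_case: int = 30,
    n_windows: int = DEFAULT_CASE_WINDOWS,
) -> pd.DataFrame:
    """Per-case representative mean score for each left-out-rep ensemble.

    Output columns: ``case_id, left_out_repetition, score`` — the 12
    per-case ensemble records that clinical fusion summarizes.
    """
    ens = build_ensembles(records)
    rows = []
    for (cid, rep), sub in ens.groupby(["case_id", "left_out_repetition"], sort=True):
        r = case_unit_predict(
            sub.set_index("window_start")["score"],
            case_id=cid,
            frames_per_case=frames_per_case,
            n_windows=n_windows,
        )
        rows.append({"case_id": cid, "left_out_repetition": rep, "score": r.mean_score})
    return pd.DataFrame(rows)
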