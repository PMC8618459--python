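"""Submetric computation and the composite rank-sum model selection.

Model quality is summarised by two metrics — mean squared error between
the predicted and actual daily probabilities, and their sample covariance
(n-1 denominator; the actual risk is the independent variable) — each
computed over six patient/day slices: {all, readmitted, non-readmitted}
patients x {first k days, all K days}.  Lower MSE is better; higher
covariance (prediction tracking the actual trend) is better.

Competing model configurations are then ranked per submetric and awarded
``(nm - rank) / (nm - 1)`` points each, where ``nm`` is the number of
models; the per-submetric points are summed and the largest total wins.
Tied submetric values receive the average of the tied rank positions, so
a dead heat splits the points evenly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .labels import PatientMeta, ValidationError

__all__ = [
    "EvaluationReport",
    "SUBMETRIC_KEYS",
    "METRIC_DIRECTIONS",
    "mse",
    "covariance",
    "submetrics",
    "rank_models",
    "reports_to_frame",
]

STRATA = ("all", "nonreadmitted", "readmitted")
WINDOWS = ("first_k", "all_K")
SUBMETRIC_KEYS: tuple[tuple[str, str, str], ...] = tuple(
    (metric, stratum, window)
    for metric in ("mse", "cov")
    for window in WINDOWS
    for stratum in STRATA
)

#: per-metric ranking direction: rank 1 goes to the smallest MSE and to the
#: largest covariance.
METRIC_DIRECTIONS = {"mse": "ascending", "cov": "descending"}


def mse(Y: Sequence[float], Yhat: Sequence[float]) -> float:
    """Mean squared error between actual and predicted probabilities."""
    Y = np.asarray(Y, float)
    Yhat = np.asarray(Yhat, float)
    if Y.size == 0:
        raise ValidationError("mse requires nonempty sequences")
    if Y.shape != Yhat.shape:
        raise ValidationError("mse requires equal-length sequences")
    return float(np.mean((Y - Yhat) ** 2))


def covariance(Y: Sequence[float], Yhat: Sequence[float]) -> float:
    """Sample covariance (n-1 denominator) of actual and predicted risk."""
    Y = np.asarray(Y, float)
    Yhat = np.asarray(Yhat, float)
    if Y.shape != Yhat.shape:
        raise ValidationError("covariance requires equal-length sequences")
    if Y.size < 2:
        raise ValidationError("covariance requires at least 2 points")
    return float(np.cov(Y, Yhat, ddof=1)[0, 1])


@dataclass
class EvaluationReport:
    """The 12 submetric values (and, after ranking, points) for one model."""

    model_name: str
    submetrics: dict[tuple[str, str, str], float | None]
    k: int = 20
    K: int = 60
    point: float | None = None
    final_rank: int | None = None

    def metric(self, metric: str, stratum: str = "all", window: str = "all_K"):
        return self.submetrics[(metric, stratum, window)]


def submetrics(
    predictions: pd.DataFrame,
    metas: Iterable[PatientMeta],
    k: int = 20,
    K: int = 60,
    model_name: str = "model",
) -> EvaluationReport:
    """Compute the 12 submetrics from a prediction frame.

    ``predictions`` needs columns patient_id, day, y_true, y_pred; rows are
    pooled patient-days.  A stratum with no patients (e.g. no readmitted
    patients in the cohort) gets ``None`` entries, which the ranking later
    skips.
    """
    required = {"patient_id", "day", "y_true", "y_pred"}
    if not required.issubset(predictions.columns):
        raise ValidationError(f"predictions frame needs columns {sorted(required)}")
    readmitted_ids = {m.patient_id for m in metas if m.readmitted}
    is_readmitted = predictions["patient_id"].isin(readmitted_ids)
    strata = {
        "all": predictions,
        "readmitted": predictions[is_readmitted],
        "nonreadmitted": predictions[~is_readmitted],
    }
    out: dict[tuple[str, str, str], float | None] = {}
    for stratum, frame in strata.items():
        for window, max_day in (("first_k", k), ("all_K", K)):
            sliced = frame[frame["day"] <= max_day]
            key_mse = ("mse", stratum, window)
            key_cov = ("cov", stratum, window)
            if len(sliced) == 0:
                out[key_mse] = None
                out[key_cov] = None
                continue
            y = sliced["y_true"].to_numpy()
            yhat = sliced["y_pred"].to_numpy()
            out[key_mse] = mse(y, yhat)
            out[key_cov] = covariance(y, yhat) if len(sliced) >= 2 else None
    ordered = {key: out[key] for key in SUBMETRIC_KEYS}
    return EvaluationReport(model_name, ordered, k=k, K=K)


def rank_models(
    reports: Sequence[EvaluationReport],
    directions: dict[str, str] | None = None,
) -> list[EvaluationReport]:
    """Assign rank-sum points and final ranks to competing models.

    Every submetric present (non-``None``) in all reports contributes
    ``(nm - rank) / (nm - 1)`` to each model's point total, with average
    ranks on ties.  The final ranking orders point totals from largest to
    smallest.  Returns ranked copies, sorted by final rank.
    """
    if len(reports) < 2:
        raise ValidationError("ranking requires at least 2 models")
    keysets = {tuple(r.submetrics.keys()) for r in reports}
    if len(keysets) != 1:
        raise ValidationError("reports carry inconsistent submetric sets")
    directions = directions or METRIC_DIRECTIONS
    nm = len(reports)
    usable = [
        key
        for key in reports[0].submetrics
        if all(r.submetrics[key] is not None for r in reports)
    ]
    if not usable:
        raise ValidationError("no submetric is present in every report")
    points = np.zeros(nm)
    for key in usable:
        values = np.array([r.submetrics[key] for r in reports], float)
        if directions[key[0]] == "descending":
            values = -values
        ranks = rankdata(values, method="average")
        points += (nm - ranks) / (nm - 1)
    ranked = [copy.deepcopy(r) for r in reports]
    final = rankdata(-points, method="min").astype(int)
    for r, p, fr in zip(ranked, points, final):
        r.point = float(p)
        r.final_rank = int(fr)
    ranked.sort(key=lambda r: (r.final_rank, r.model_name))
    return ranked


def reports_to_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Ranking table mirroring the published layout: one row per model,
    12 submetric columns grouped metric-first, then the point total."""
    rows = []
    for r in reports:
        row: dict[str, object] = {"model": r.model_name}
        for metric, stratum, window in SUBMETRIC_KEYS:
            w = f"first{r.k}" if window == "first_k" else f"all{r.K}"
            row[f"{metric}_{w}_{stratum}"] = r.submetrics[(metric, stratum, window)]
        row["point"] = r.point
        row["final_rank"] = r.final_rank
        rows.append(row)
    return pd.DataFrame(rows)
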