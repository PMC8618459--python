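"""Classic per-day regression baselines: MLR, regression tree, SVR.

The baselines consume exactly the rows the sequence model sees — one
feature vector per patient-day predicting the next day's risk probability
— but treat them as independent observations: no recurrence, no injected
previous-day probability.  This keeps the comparison honest: whatever the
sequence model gains must come from exploiting the sequential structure.
Library defaults (scikit-learn) are pinned and recorded so results are
reproducible across versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .evaluate import EvaluationReport, rank_models, reports_to_frame
from .features import FeaturePanel
from .labels import PatientMeta, RiskTrajectory, ValidationError
from .model import LOPOResults, build_sequences

__all__ = ["BaselineConfig", "ClassicRegression", "fit_baseline", "compare_models"]

METHODS = ("MLR", "RT", "SVR")


@dataclass(frozen=True)
class BaselineConfig:
    """Baseline family and (pinned) hyperparameters."""

    method: str = "MLR"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown baseline method {self.method!r}")


def _make_estimator(config: BaselineConfig):
    hp = dict(config.hyperparameters)
    if config.method == "MLR":
        return LinearRegression(**hp)
    if config.method == "RT":
        hp.setdefault("random_state", config.seed)
        return DecisionTreeRegressor(**hp)
    return SVR(**hp)


class ClassicRegression:
    """Per-day regression baseline over the same panel as the LSTM.

    Rows are (features on day ``t``) -> (probability on day ``t+1``);
    injected-probability columns, if present on the panel, are excluded.
    ``fit()`` runs leave-one-patient-out by default and returns the same
    :class:`~readmitrisk.model.LOPOResults` container as the LSTM, with
    predictions clipped to [0, 1].
    """

    def __init__(
        self,
        panel: FeaturePanel,
        trajectories,
        metas: Sequence[PatientMeta],
        config: BaselineConfig | None = None,
        name: str | None = None,
    ):
        self.config = config or BaselineConfig()
        if not isinstance(trajectories, Mapping):
            trajectories = {t.patient_id: t for t in trajectories}
        self.trajectories = dict(trajectories)
        self.metas = list(metas)
        keep = [
            c
            for c in panel.feature_names
            if panel.tags[c] != "injected_probability"
        ]
        self.panel = FeaturePanel(
            panel.values[keep].copy(),
            panel.provenance[keep].copy(),
            {c: panel.tags[c] for c in keep},
        )
        self.name = name or self.config.method

    def fit(self, lopo: bool = True) -> LOPOResults:
        samples = build_sequences(self.panel, self.trajectories)
        if lopo and len(samples) < 2:
            raise ValidationError("leave-one-patient-out requires at least 2 patients")
        by_id = {s.patient_id: s for s in samples}
        rows = []
        fold_models = {}
        manifest = None
        for fold, held_out in enumerate(by_id):
            if lopo:
                train = [s for pid, s in by_id.items() if pid != held_out]
            else:
                train = list(by_id.values())
            X = np.vstack([s.inputs for s in train])
            y = np.concatenate([s.targets for s in train])
            est = _make_estimator(self.config)
            est.fit(X, y)
            if manifest is None:
                manifest = est.get_params()
            fold_models[held_out] = est
            sample = by_id[held_out]
            raw = est.predict(sample.inputs)
            yhat = np.clip(raw, 0.0, 1.0)
            for day, yt, yp in zip(sample.days, sample.targets, yhat):
                rows.append((self.name, held_out, int(day), float(yt), float(yp), fold))
        predictions = pd.DataFrame(
            rows, columns=["model", "patient_id", "day", "y_true", "y_pred", "fold"]
        )
        logs = pd.DataFrame(columns=["patient_id", "fold", "epoch", "loss"])
        results = LOPOResults(
            self.name, predictions, logs, fold_models, self.metas, self.config
        )
        results.hyperparameter_manifest = manifest
        return results


def fit_baseline(
    panel: FeaturePanel,
    trajectories,
    metas: Sequence[PatientMeta],
    config: BaselineConfig | None = None,
    lopo: bool = True,
    name: str | None = None,
) -> LOPOResults:
    """Functional entry point mirroring :func:`readmitrisk.model.train_lopo`."""
    return ClassicRegression(panel, trajectories, metas, config=config, name=name).fit(
        lopo=lopo
    )


def compare_models(
    reports: Sequence[EvaluationReport],
) -> tuple[list[EvaluationReport], pd.DataFrame]:
    """Rank LSTM and baseline reports together; returns (ranked, table)."""
    ranked = rank_models(list(reports))
    return ranked, reports_to_frame(ranked)
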