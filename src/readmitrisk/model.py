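"""Autoregressive LSTM daily-risk predictor, trained leave-one-patient-out.

The model consumes one feature vector per patient-day and predicts the
next day's readmission-risk probability.  The previous day's probability
can be *injected* as an additional input feature, either as the known
label (``actual_prev`` — an oracle mode usable when risk can be
recomputed from known scores) or as the model's own previous output
(``predicted_prev`` — the deployable autoregressive mode, teacher-forced
with labels during training and rolled out at inference).

Training follows leave-one-patient-out (LOPO): for each patient one model
is trained on every other patient's full sequence and produces next-day
predictions over the held-out patient's days.  Optimisation is full-batch
Adam on mean-absolute error with early stopping on the training loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeaturePanel, attach_auxiliary
from .labels import PatientMeta, RiskTrajectory, ValidationError, initial_probability
from .nn import LSTMNetwork, mae

__all__ = [
    "ModelConfig",
    "SequenceSample",
    "mae_loss",
    "build_model",
    "build_sequences",
    "DailyRiskLSTM",
    "LOPOResults",
    "train_lopo",
    "predict_trajectory",
]

Injection = Literal["none", "actual_prev", "predicted_prev"]


@dataclass(frozen=True)
class ModelConfig:
    """Every switch of the LSTM experiment grid.

    ``hidden_units=None`` means "match the number of input features", the
    default sizing rule.  ``patience_epochs`` counts consecutive epochs
    without a training-loss decrease before stopping; ``max_epochs`` caps
    the optimisation regardless.
    """

    n_layers: int = 2
    hidden_units: int | None = None
    learning_rate: float = 0.01
    patience_epochs: int = 50
    max_epochs: int = 400
    injection: Injection = "predicted_prev"
    include_date_index: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers not in (1, 2):
            raise ValidationError("n_layers must be 1 or 2")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.patience_epochs < 1:
            raise ValidationError("patience_epochs must be >= 1")
        if self.injection not in ("none", "actual_prev", "predicted_prev"):
            raise ValidationError(f"unknown injection mode {self.injection!r}")


@dataclass
class SequenceSample:
    """One patient's model-ready sequence.

    ``inputs[t]`` is the feature vector on input day ``days[t] - 1``;
    ``targets[t]`` is the risk probability on day ``days[t]`` (the next
    day).  ``days`` are therefore the target day indices.
    """

    patient_id: str
    inputs: np.ndarray  # (T, n_features)
    targets: np.ndarray  # (T,)
    days: np.ndarray  # (T,) target day index per step

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.targets):
            raise ValidationError("inputs and targets must have equal length")
        if np.any((self.targets < 0) | (self.targets > 1)):
            raise ValidationError("targets must lie in [0, 1]")


def mae_loss(Y: Sequence[float], Yhat: Sequence[float]) -> float:
    """Mean absolute error between label and prediction sequences."""
    Y = np.asarray(Y, float)
    Yhat = np.asarray(Yhat, float)
    if Y.size == 0:
        raise ValidationError("mae_loss requires nonempty sequences")
    if Y.shape != Yhat.shape:
        raise ValidationError("mae_loss requires equal-length sequences")
    return mae(Y, Yhat)


def build_model(config: ModelConfig, n_features: int) -> LSTMNetwork:
    """Instantiate the (deterministically seeded) LSTM for a feature count."""
    hidden = config.hidden_units if config.hidden_units is not None else n_features
    return LSTMNetwork(
        n_features=n_features,
        hidden_units=hidden,
        n_layers=config.n_layers,
        seed=config.seed,
    )


def build_sequences(
    panel: FeaturePanel, trajectories: Mapping[str, RiskTrajectory]
) -> list[SequenceSample]:
    """Convert a panel plus label trajectories into per-patient sequences.

    Each patient's input rows are their panel days except the last; the
    target at step ``t`` is the label on the following day.
    """
    samples = []
    for patient in panel.patients:
        if patient not in trajectories:
            raise ValidationError(f"no trajectory for patient {patient!r}")
        block = panel.patient_frame(patient)
        days = block.index.get_level_values("day").to_numpy() if isinstance(
            block.index, pd.MultiIndex
        ) else block.index.to_numpy()
        if len(days) < 2:
            raise ValidationError(
                f"patient {patient!r} needs at least 2 days of data"
            )
        probs = trajectories[patient].probabilities
        x = block.to_numpy()[:-1]
        target_days = days[1:]
        y = probs[target_days - 1]
        samples.append(SequenceSample(patient, x, np.asarray(y, float), target_days))
    return samples


def _pack(samples: Sequence[SequenceSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad sequences to a common length; returns (X, Y, mask)."""
    T = max(len(s.targets) for s in samples)
    F = samples[0].inputs.shape[1]
    X = np.zeros((len(samples), T, F))
    Y = np.zeros((len(samples), T))
    mask = np.zeros((len(samples), T), dtype=bool)
    for b, s in enumerate(samples):
        n = len(s.targets)
        X[b, :n] = s.inputs
        Y[b, :n] = s.targets
        mask[b, :n] = True
    return X, Y, mask


class LOPOResults:
    """Predictions, training logs and trained fold models of a LOPO run.

    ``predictions`` is a long frame (model, patient_id, day, y_true,
    y_pred, fold) with one row per predicted patient-day (days 2..horizon;
    the day-1 probability is known from the discharge scores and is not a
    model output).
    """

    def __init__(
        self,
        model_name: str,
        predictions: pd.DataFrame,
        training_logs: pd.DataFrame,
        fold_models: dict,
        metas: Sequence[PatientMeta],
        config=None,
    ):
        self.model_name = model_name
        self.predictions = predictions
        self.training_logs = training_logs
        self.fold_models = fold_models
        self.metas = list(metas)
        self.config = config

    def evaluate(self, k: int = 20, K: int = 60):
        from .evaluate import submetrics

        return submetrics(self.predictions, self.metas, k=k, K=K, model_name=self.model_name)

    def overall_mse(self, max_day: int | None = None) -> float:
        df = self.predictions
        if max_day is not None:
            df = df[df["day"] <= max_day]
        return float(((df["y_true"] - df["y_pred"]) ** 2).mean())

    def overall_mae(self) -> float:
        return float((self.predictions["y_true"] - self.predictions["y_pred"]).abs().mean())

    def save(self, out_dir) -> None:
        """Write predictions, training log, config snapshot and (for LSTM
        folds) serialized weights under one directory."""
        import dataclasses
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.predictions.to_csv(out / "predictions.csv", index=False)
        self.training_logs.to_csv(out / "training_log.csv", index=False)
        if dataclasses.is_dataclass(self.config):
            snapshot = dataclasses.asdict(self.config)
        else:
            snapshot = {"config": repr(self.config)}
        (out / "config.json").write_text(
            json.dumps({"model": self.model_name, **snapshot}, indent=2, default=str)
        )
        for patient, net in self.fold_models.items():
            if hasattr(net, "save"):
                net.save(out / f"weights_fold_{patient}.npz")

    def summary(self, k: int = 20, K: int = 60) -> str:
        report = self.evaluate(k=k, K=K)
        lines = [
            f"LOPO results: {self.model_name}",
            f"  patients: {self.predictions['patient_id'].nunique()}"
            f"  predicted days: {len(self.predictions)}",
            f"  MAE (all): {self.overall_mae():.4f}"
            f"  MSE (all days): {self.overall_mse():.4f}",
            "  submetrics (metric, stratum, window):",
        ]
        for key, value in report.submetrics.items():
            shown = "absent" if value is None else f"{value:.4f}"
            lines.append(f"    {key[0]:>3} {key[1]:>13} {key[2]:>8}: {shown}")
        return "\n".join(lines)


class DailyRiskLSTM:
    """LSTM daily-readmission-risk model over a feature panel.

    Parameters
    ----------
    panel : preprocessed feature panel (imputed, normalised).  Date-index
        and injected-probability columns are attached automatically per the
        configuration if not already present.
    trajectories : per-patient risk label trajectories.
    metas : patient metadata (used for initial probabilities and later
        evaluation strata).
    config : :class:`ModelConfig`.
    """

    def __init__(
        self,
        panel: FeaturePanel,
        trajectories: Mapping[str, RiskTrajectory] | Sequence[RiskTrajectory],
        metas: Sequence[PatientMeta],
        config: ModelConfig | None = None,
        name: str | None = None,
    ):
        self.config = config or ModelConfig()
        if not isinstance(trajectories, Mapping):
            trajectories = {t.patient_id: t for t in trajectories}
        self.trajectories = dict(trajectories)
        self.metas = list(metas)
        self._meta_by_id = {m.patient_id: m for m in self.metas}
        horizon = len(next(iter(self.trajectories.values())).probabilities)
        needs_date = self.config.include_date_index and "date_index" not in panel.tags.values()
        needs_prob = (
            self.config.injection != "none"
            and "injected_probability" not in panel.tags.values()
        )
        if needs_date or needs_prob:
            panel = attach_auxiliary(
                panel,
                date_index=needs_date,
                trajectories=self.trajectories if needs_prob else None,
                horizon=horizon,
            )
        self.panel = panel
        self._injected_idx = None
        for j, col in enumerate(panel.feature_names):
            if panel.tags[col] == "injected_probability":
                self._injected_idx = j
        self.name = name or self._default_name()

    def _default_name(self) -> str:
        inj = {"none": "no_prob", "actual_prev": "actual_prob", "predicted_prev": "predicted_prob"}[
            self.config.injection
        ]
        date = "with_date" if self.config.include_date_index else "without_date"
        return f"{inj}_{date}"

    def fit(self) -> LOPOResults:
        """Train one model per LOPO fold and predict each held-out patient."""
        samples = build_sequences(self.panel, self.trajectories)
        if len(samples) < 2:
            raise ValidationError("leave-one-patient-out requires at least 2 patients")
        by_id = {s.patient_id: s for s in samples}
        cfg = self.config
        pred_rows = []
        log_rows = []
        fold_models = {}
        n_features = samples[0].inputs.shape[1]
        for fold, held_out in enumerate(by_id):
            train = [s for pid, s in by_id.items() if pid != held_out]
            X, Y, mask = _pack(train)
            net = build_model(cfg, n_features)
            history = net.fit(
                X,
                Y,
                mask,
                lr=cfg.learning_rate,
                patience=cfg.patience_epochs,
                max_epochs=cfg.max_epochs,
            )
            fold_models[held_out] = net
            for epoch, loss in enumerate(history):
                log_rows.append((held_out, fold, epoch, loss))
            sample = by_id[held_out]
            p_init = initial_probability(
                self._meta_by_id[held_out],
                self.trajectories[held_out].config.initial_source,
            )
            yhat = predict_sequence(net, sample, cfg.injection, self._injected_idx, p_init)
            for day, yt, yp in zip(sample.days, sample.targets, yhat):
                pred_rows.append((self.name, held_out, int(day), float(yt), float(yp), fold))
        predictions = pd.DataFrame(
            pred_rows, columns=["model", "patient_id", "day", "y_true", "y_pred", "fold"]
        )
        logs = pd.DataFrame(log_rows, columns=["patient_id", "fold", "epoch", "loss"])
        return LOPOResults(self.name, predictions, logs, fold_models, self.metas, cfg)


def predict_sequence(
    net: LSTMNetwork,
    sample: SequenceSample,
    injection: Injection,
    injected_idx: int | None,
    p_init: float,
) -> np.ndarray:
    """Next-day predictions over one patient's sequence.

    Under ``predicted_prev`` the injected input feature is replaced, from
    the third input day on, by the model's own prediction two steps back
    (the model output for the previous day); the first two input days use
    the initial probability, which is known at discharge.  Other modes run
    a single full forward pass on the panel as given.
    """
    if injection != "predicted_prev":
        return net.forward(sample.inputs[None])[0]
    if injected_idx is None:
        raise ValidationError("predicted_prev injection requires an injected column")
    state = net.init_state(1)
    T = len(sample.targets)
    out = np.empty(T)
    for t in range(T):
        x = sample.inputs[t].copy()
        if t < 2:
            x[injected_idx] = p_init
        else:
            x[injected_idx] = out[t - 2]
        y, state = net.step(x[None], state)
        out[t] = y[0]
    return out


def predict_trajectory(
    net: LSTMNetwork,
    panel: FeaturePanel,
    trajectory: RiskTrajectory,
    meta: PatientMeta,
    injection: Injection = "predicted_prev",
) -> np.ndarray:
    """Full per-day predicted trajectory (one probability per panel day).

    Day 1 carries the initial probability (known from the discharge
    scores); later days carry the model's next-day predictions.
    """
    if meta.patient_id not in panel.patients:
        raise ValidationError(f"panel lacks patient {meta.patient_id!r}")
    keep = panel.values.index.get_level_values("patient_id") == meta.patient_id
    sub = FeaturePanel(
        panel.values[keep], panel.provenance[keep], dict(panel.tags)
    )
    sample = build_sequences(sub, {meta.patient_id: trajectory})[0]
    injected_idx = None
    for j, col in enumerate(panel.feature_names):
        if panel.tags[col] == "injected_probability":
            injected_idx = j
    p_init = initial_probability(meta, trajectory.config.initial_source)
    yhat = predict_sequence(net, sample, injection, injected_idx, p_init)
    return np.concatenate([[p_init], yhat])


def train_lopo(
    panel: FeaturePanel,
    trajectories,
    metas: Sequence[PatientMeta],
    config: ModelConfig | None = None,
    name: str | None = None,
) -> LOPOResults:
    """Functional entry point: LOPO-train and predict in one call."""
    return DailyRiskLSTM(panel, trajectories, metas, config=config, name=name).fit()
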