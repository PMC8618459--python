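"""Model-ready feature panels from daily behavioral feature tables.

The pipeline mirrors common practice for mobile-sensing studies: 7-day
deviation features, removal of mostly-missing and near-constant columns,
causal moving-average imputation with a -1 constant fallback for cells that
have no usable history, min-max normalisation pooled over all patients, and
optional auxiliary columns (normalised day index, previous-day risk
probability).

Missingness is tracked with an explicit per-cell provenance code rather
than a sentinel value, so the -1 constant never collides ambiguously with a
real measurement: 0 = observed, 1 = missing, 2 = moving-average imputed,
3 = constant-filled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .labels import PatientMeta, RiskTrajectory, ValidationError

__all__ = [
    "FeaturePanel",
    "EmptyPanelError",
    "OBSERVED",
    "MISSING",
    "IMPUTED_MA",
    "IMPUTED_CONST",
    "deviation_features",
    "filter_features",
    "impute_moving_average",
    "normalize_minmax",
    "attach_auxiliary",
    "select_data_range",
    "load_feature_table",
]

OBSERVED, MISSING, IMPUTED_MA, IMPUTED_CONST = 0, 1, 2, 3

FeatureTag = Literal["sensor", "symptom", "deviation", "date_index", "injected_probability"]


class EmptyPanelError(ValidationError):
    """All feature columns were removed by filtering."""


@dataclass
class FeaturePanel:
    """Patients x days x features table with explicit missingness provenance.

    ``values`` is a DataFrame indexed by (patient_id, day) with one column
    per feature; missing cells are NaN until imputation.  ``provenance``
    shares the shape and records per-cell origin codes.  ``tags`` maps each
    feature to its source family.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    tags: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.shape != self.provenance.shape:
            raise ValidationError("values and provenance must share shape")
        if list(self.values.columns) != list(self.provenance.columns):
            raise ValidationError("values and provenance must share columns")
        missing_tags = [c for c in self.values.columns if c not in self.tags]
        if missing_tags:
            raise ValidationError(f"features without tags: {missing_tags}")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        tags: Mapping[str, str] | None = None,
        patient_col: str = "patient_id",
        day_col: str = "day",
    ) -> "FeaturePanel":
        """Build a panel from a long table with patient/day columns.

        Feature tags default to ``symptom`` for columns prefixed ``sym_``
        and ``sensor`` otherwise.
        """
        frame = frame.copy()
        frame[patient_col] = frame[patient_col].astype(str)
        values = frame.set_index([patient_col, day_col]).sort_index()
        values.index.names = ["patient_id", "day"]
        values = values.astype(float)
        if tags is None:
            tags = {
                c: ("symptom" if c.startswith("sym_") else "sensor")
                for c in values.columns
            }
        provenance = pd.DataFrame(
            np.where(values.isna(), MISSING, OBSERVED),
            index=values.index,
            columns=values.columns,
            dtype=np.int8,
        )
        return cls(values, provenance, dict(tags))

    @property
    def patients(self) -> list[str]:
        return list(self.values.index.get_level_values("patient_id").unique())

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean mask, True where a cell is an actual observation."""
        return self.provenance == OBSERVED

    def patient_frame(self, patient_id: str) -> pd.DataFrame:
        return self.values.loc[patient_id]

    def copy(self) -> "FeaturePanel":
        return FeaturePanel(self.values.copy(), self.provenance.copy(), dict(self.tags))

    def to_frame(self) -> pd.DataFrame:
        return self.values.reset_index()

    def write_csv(self, csv_path, manifest_path=None, **manifest_extra) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if manifest_path is not None:
            payload = {"feature_tags": self.tags, **manifest_extra}
            with open(manifest_path, "w") as fh:
                json.dump(payload, fh, indent=2, default=str)


def load_feature_table(path, tags: Mapping[str, str] | None = None) -> FeaturePanel:
    """Read a daily feature CSV (patient_id, day, features; empty = missing)."""
    return FeaturePanel.from_frame(pd.read_csv(path), tags=tags)


def deviation_features(
    panel: FeaturePanel,
    window: int = 7,
    sources: Sequence[str] = ("sensor", "symptom"),
    suffix: str = "_dev",
) -> FeaturePanel:
    """Append deviation columns: today's value minus the mean over the
    previous ``window`` days (prior days only, non-missing only).

    A deviation cell is missing when the base value is missing or when no
    prior non-missing value exists in the window (always the case on the
    first day).
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    base_cols = [c for c in panel.feature_names if panel.tags[c] in sources]
    grouped = panel.values[base_cols].groupby(level="patient_id", sort=False)
    prior_mean = grouped.transform(
        lambda s: s.shift(1).rolling(window, min_periods=1).mean()
    )
    dev = panel.values[base_cols] - prior_mean
    dev.columns = [c + suffix for c in base_cols]
    prov = pd.DataFrame(
        np.where(dev.isna(), MISSING, OBSERVED),
        index=dev.index,
        columns=dev.columns,
        dtype=np.int8,
    )
    values = pd.concat([panel.values, dev], axis=1)
    provenance = pd.concat([panel.provenance, prov], axis=1)
    tags = dict(panel.tags)
    tags.update({c: "deviation" for c in dev.columns})
    return FeaturePanel(values, provenance, tags)


def filter_features(
    panel: FeaturePanel,
    max_missing_frac: float = 0.8,
    min_variance: float = 0.3,
    drop_if_first_day_missing: bool = True,
) -> tuple[FeaturePanel, pd.DataFrame]:
    """Drop unusable feature columns; return the reduced panel and a log.

    Rules (evaluated on the raw, pre-normalisation values pooled over all
    patients):

    * more than ``max_missing_frac`` of the cells missing;
    * sample variance of the non-missing values below ``min_variance``
      (columns with fewer than two observations count as zero-variance);
    * when enabled, the day-1 value missing for any patient.  Deviation
      columns are exempt from this rule: their day-1 cell is structurally
      missing (there is no prior window), which says nothing about the
      underlying measurement quality.

    The log lists every (feature, reason) pair; a column may match several
    rules.  Raises :class:`EmptyPanelError` if nothing survives.
    """
    if not (0.0 <= max_missing_frac <= 1.0):
        raise ValidationError("max_missing_frac must lie in [0, 1]")
    records: list[tuple[str, str]] = []
    values = panel.values
    missing_frac = values.isna().mean(axis=0)
    variance = values.var(axis=0, ddof=1)
    day1 = values.xs(1, level="day")
    for col in values.columns:
        if missing_frac[col] > max_missing_frac:
            records.append((col, "missing_fraction"))
        var = variance[col]
        if pd.isna(var) or var < min_variance:
            records.append((col, "low_variance"))
        if (
            drop_if_first_day_missing
            and panel.tags[col] != "deviation"
            and day1[col].isna().any()
        ):
            records.append((col, "first_day_missing"))
    log = pd.DataFrame(records, columns=["feature", "reason"])
    dropped = set(log["feature"])
    kept = [c for c in values.columns if c not in dropped]
    if not kept:
        raise EmptyPanelError(
            f"all {panel.n_features} feature columns removed by filtering"
        )
    reduced = FeaturePanel(
        values[kept].copy(),
        panel.provenance[kept].copy(),
        {c: panel.tags[c] for c in kept},
    )
    return reduced, log


def impute_moving_average(
    panel: FeaturePanel, k_prev: int = 2, fill_constant: float = -1.0
) -> FeaturePanel:
    """Fill missing cells with the mean of up to ``k_prev`` previous days.

    The fill is causal and streaming, per patient and feature: a cell filled
    earlier in the pass becomes available to later fills.  Cells with no
    usable history (leading runs of missingness, or every cell when
    ``k_prev == 0``) receive ``fill_constant`` instead.  Provenance records
    which cells were imputed and how.
    """
    if k_prev < 0:
        raise ValidationError("k_prev must be >= 0")
    out = panel.copy()
    values = out.values
    prov = out.provenance
    if k_prev > 0:
        for patient in out.patients:
            block = values.loc[patient]
            arr = block.to_numpy()  # days x features, day-sorted
            nan_rows, nan_cols = np.nonzero(np.isnan(arr))
            for t, j in zip(nan_rows, nan_cols):
                history = arr[:t, j]
                history = history[~np.isnan(history)]
                if history.size:
                    arr[t, j] = history[-k_prev:].mean()
            filled = pd.DataFrame(arr, index=block.index, columns=block.columns)
            values.loc[patient] = filled.to_numpy()
    ma_filled = values.notna() & (prov == MISSING)
    prov_arr = prov.to_numpy()
    prov_arr[ma_filled.to_numpy()] = IMPUTED_MA
    still_missing = values.isna().to_numpy()
    prov_arr[still_missing] = IMPUTED_CONST
    out.values = values.fillna(fill_constant)
    out.provenance = pd.DataFrame(
        prov_arr, index=prov.index, columns=prov.columns, dtype=np.int8
    )
    return out


def normalize_minmax(panel: FeaturePanel) -> tuple[FeaturePanel, pd.DataFrame]:
    """Scale each feature to [0, 1] using min/max pooled over all patients.

    Constant-filled sentinel cells are excluded from the fit and left
    untouched, so they remain at the fill constant after scaling.  Constant
    features map to 0.  Returns the scaled panel and a per-feature frame of
    (min, max) scaling parameters for the inverse transform.
    """
    if panel.values.isna().any().any():
        raise ValidationError("panel must be imputed before normalization")
    out = panel.copy()
    arr = out.values.to_numpy(copy=True)
    prov = out.provenance.to_numpy()
    eligible = prov != IMPUTED_CONST
    params = []
    for j, col in enumerate(out.values.columns):
        cells = eligible[:, j]
        if not cells.any():
            params.append((col, np.nan, np.nan))
            continue
        lo = arr[cells, j].min()
        hi = arr[cells, j].max()
        rng = hi - lo
        if rng == 0:
            arr[cells, j] = 0.0
        else:
            arr[cells, j] = (arr[cells, j] - lo) / rng
        params.append((col, lo, hi))
    out.values = pd.DataFrame(arr, index=out.values.index, columns=out.values.columns)
    scaling = pd.DataFrame(params, columns=["feature", "min", "max"]).set_index("feature")
    return out, scaling


def attach_auxiliary(
    panel: FeaturePanel,
    date_index: bool = False,
    trajectories: Mapping[str, RiskTrajectory] | None = None,
    horizon: int = 60,
) -> FeaturePanel:
    """Append the normalised day index and/or previous-day probability.

    The date index column is ``day / horizon``.  The injected probability
    column holds each patient's label trajectory shifted by one day: day
    ``n`` carries the probability of day ``n - 1``; day 1 carries the
    initial probability.
    """
    out = panel.copy()
    idx = out.values.index
    days = idx.get_level_values("day").to_numpy()
    if date_index:
        out.values["date_index"] = days / float(horizon)
        out.provenance["date_index"] = OBSERVED
        out.tags["date_index"] = "date_index"
    if trajectories is not None:
        col = np.empty(len(idx))
        patients = idx.get_level_values("patient_id").to_numpy()
        for patient in out.patients:
            rows = patients == patient
            if patient not in trajectories:
                raise ValidationError(f"no trajectory for patient {patient!r}")
            probs = trajectories[patient].probabilities
            pdays = days[rows]
            if pdays.max() > len(probs):
                raise ValidationError(
                    f"trajectory for patient {patient!r} shorter than panel "
                    f"({len(probs)} < day {pdays.max()})"
                )
            shifted = np.where(pdays > 1, probs[np.maximum(pdays - 2, 0)], probs[0])
            col[rows] = shifted
        out.values["prev_probability"] = col
        out.provenance["prev_probability"] = OBSERVED
        out.tags["prev_probability"] = "injected_probability"
    return out


DataRange = Literal[
    "post_op_to_event", "post_discharge_to_event", "exclude_post_readmission", "full_60"
]


def select_data_range(
    panel: FeaturePanel,
    metas: Iterable[PatientMeta],
    setting: DataRange = "full_60",
) -> FeaturePanel:
    """Truncate each patient's rows per the configured data-range setting.

    ``full_60`` keeps every row.  The other three settings keep only days up
    to the readmission day for readmitted patients; non-readmitted patients
    always keep the full horizon.  On panels anchored at the discharge day
    (no pre-discharge rows) the three truncating settings coincide.
    """
    if setting not in (
        "post_op_to_event",
        "post_discharge_to_event",
        "exclude_post_readmission",
        "full_60",
    ):
        raise ValidationError(f"unknown data range setting {setting!r}")
    if setting == "full_60":
        return panel.copy()
    cutoffs = {
        m.patient_id: m.readmission_day for m in metas if m.readmitted
    }
    idx = panel.values.index
    patients = idx.get_level_values("patient_id")
    days = idx.get_level_values("day")
    keep = np.ones(len(idx), dtype=bool)
    for patient, k in cutoffs.items():
        keep &= ~((patients == patient) & (days > k))
    return FeaturePanel(
        panel.values[keep].copy(), panel.provenance[keep].copy(), dict(panel.tags)
    )
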