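"""End-to-end orchestration: cohort -> processed panel -> fitted models.

Bundles the preprocessing recipe (deviation features, column filtering,
moving-average imputation, min-max normalisation, data-range selection)
and the model fits so that experiments and the command-line interface
share one code path.  Defaults follow the best-performing configuration
of the experiment grid: full 60-day range, average of the two discharge
scores, exponential daily-probability function, 2-day imputation,
first-day feature filtering on, date index on, previous-day predicted
probability injected.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .baselines import BaselineConfig, fit_baseline
from .features import (
    FeaturePanel,
    deviation_features,
    filter_features,
    impute_moving_average,
    normalize_minmax,
    select_data_range,
)
from .labels import PatientMeta, RiskTrajectory
from .model import LOPOResults, ModelConfig, train_lopo
from .synth import SyntheticCohort

__all__ = ["preprocess_panel", "run_pipeline", "run_baselines"]


def preprocess_panel(
    panel: FeaturePanel,
    metas: Sequence[PatientMeta],
    *,
    deviation_window: int = 7,
    sources: Sequence[str] = ("sensor", "symptom", "deviation"),
    max_missing_frac: float = 0.8,
    min_variance: float = 0.3,
    drop_if_first_day_missing: bool = True,
    k_prev: int = 2,
    fill_constant: float = -1.0,
    data_range: str = "full_60",
) -> tuple[FeaturePanel, dict]:
    """Raw daily feature panel -> model-ready panel.

    Steps: append 7-day deviation features, restrict to the configured
    source families, drop unusable columns, truncate rows per the data
    range, impute, normalise.  Returns the processed panel and an info
    dict (filter log, scaling parameters, bookkeeping counts).
    """
    if "deviation" in sources and deviation_window:
        panel = deviation_features(panel, window=deviation_window)
    keep = [c for c in panel.feature_names if panel.tags[c] in sources]
    panel = FeaturePanel(
        panel.values[keep].copy(),
        panel.provenance[keep].copy(),
        {c: panel.tags[c] for c in keep},
    )
    n_before = panel.n_features
    panel, filter_log = filter_features(
        panel,
        max_missing_frac=max_missing_frac,
        min_variance=min_variance,
        drop_if_first_day_missing=drop_if_first_day_missing,
    )
    panel = select_data_range(panel, metas, setting=data_range)
    panel = impute_moving_average(panel, k_prev=k_prev, fill_constant=fill_constant)
    panel, scaling = normalize_minmax(panel)
    info = {
        "n_features_in": n_before,
        "n_features_kept": panel.n_features,
        "n_features_dropped": filter_log["feature"].nunique(),
        "filter_log": filter_log,
        "scaling": scaling,
        "data_range": data_range,
    }
    return panel, info


def run_pipeline(
    cohort: SyntheticCohort,
    model_config: ModelConfig | None = None,
    name: str | None = None,
    **preprocess_kwargs,
) -> LOPOResults:
    """Preprocess a cohort and LOPO-fit the LSTM on it."""
    panel, _ = preprocess_panel(cohort.panel(), cohort.metas, **preprocess_kwargs)
    return train_lopo(
        panel, cohort.trajectories, cohort.metas, config=model_config, name=name
    )


def run_baselines(
    cohort: SyntheticCohort,
    methods: Sequence[str] = ("MLR", "RT", "SVR"),
    seed: int = 0,
    **preprocess_kwargs,
) -> dict[str, LOPOResults]:
    """Preprocess a cohort once and LOPO-fit each classic baseline on it."""
    panel, _ = preprocess_panel(cohort.panel(), cohort.metas, **preprocess_kwargs)
    return {
        method: fit_baseline(
            panel,
            cohort.trajectories,
            cohort.metas,
            config=BaselineConfig(method=method, seed=seed),
        )
        for method in methods
    }
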