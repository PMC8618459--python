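"""Readmission-risk probability trajectories from administrative scores.

A patient's risk of surgery-related readmission is anchored at two points:
an *initial* probability on the first day after discharge, obtained by
linearly normalising the LACE index (0-19) or HOSPITAL score (0-15), and a
*final* probability of 0 on day 60, by which time surgery-related
readmissions are no longer expected.  Readmitted patients additionally have
their risk pinned to 1 on the day of readmission.  Between the anchors the
daily probability is interpolated by one of four parametric families:

* linear          ``p_n = a*n + b``
* exponential     ``p_n = a**n + b``
* logarithmic     ``p_n = log_a(n) + b``
* weighted linear ``p_n = w_n*l_n + (1 - w_n)*p_{n-1}`` with a parabolic
  weight ``w_n`` that equals 1 at both segment endpoints and dips to 0 at
  the segment midpoint (``l_n`` is the plain linear value).

Exponential and logarithmic segments are re-indexed to a local day origin
``n' = n - d1 + 1`` so that each segment starts at ``n' = 1``; this keeps
``log_a(n')`` finite and makes segment fitting well-posed regardless of
where the segment sits in the 60-day window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "LACE_MAX",
    "HOSPITAL_MAX",
    "PatientMeta",
    "TrajectoryConfig",
    "SegmentParams",
    "RiskTrajectory",
    "initial_probability",
    "fit_segment",
    "segment_values",
    "weighted_linear_weights",
    "weighted_linear_segment",
    "build_trajectory",
    "load_patient_meta",
    "trajectories_to_frame",
    "save_trajectories",
]

LACE_MAX = 19
HOSPITAL_MAX = 15

TrajectoryFunction = Literal["linear", "exponential", "logarithmic", "weighted_linear"]
InitialSource = Literal["LACE", "HOSPITAL", "average"]
ReadmittedMode = Literal["reset_to_initial", "continue_from_one"]


class ValidationError(ValueError):
    """Raised when patient metadata or configuration violates its contract."""


@dataclass(frozen=True)
class PatientMeta:
    """Discharge/readmission timeline and administrative risk scores.

    Day indexing: day 1 is the first day after hospital discharge.
    ``readmission_day`` and ``second_discharge_day`` must be present iff the
    patient was readmitted within the horizon.
    """

    patient_id: str
    readmitted: bool
    lace: int
    hospital: int
    readmission_day: int | None = None
    second_discharge_day: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.lace <= LACE_MAX):
            raise ValidationError(
                f"lace score {self.lace} outside [0, {LACE_MAX}] "
                f"for patient {self.patient_id!r}"
            )
        if not (0 <= self.hospital <= HOSPITAL_MAX):
            raise ValidationError(
                f"hospital score {self.hospital} outside [0, {HOSPITAL_MAX}] "
                f"for patient {self.patient_id!r}"
            )
        if self.readmitted:
            if self.readmission_day is None or self.second_discharge_day is None:
                raise ValidationError(
                    "readmitted patient requires readmission_day and "
                    f"second_discharge_day (patient {self.patient_id!r})"
                )
            if self.second_discharge_day <= self.readmission_day:
                raise ValidationError(
                    "second_discharge_day must exceed readmission_day "
                    f"(patient {self.patient_id!r})"
                )
        else:
            if self.readmission_day is not None or self.second_discharge_day is not None:
                raise ValidationError(
                    "non-readmitted patient must not carry readmission days "
                    f"(patient {self.patient_id!r})"
                )


@dataclass(frozen=True)
class TrajectoryConfig:
    """How the daily risk label sequence is generated."""

    function: TrajectoryFunction = "linear"
    initial_source: InitialSource = "average"
    readmitted_mode: ReadmittedMode = "reset_to_initial"
    horizon: int = 60

    def __post_init__(self) -> None:
        if self.horizon < 2:
            raise ValidationError("horizon must be >= 2")
        if self.function not in ("linear", "exponential", "logarithmic", "weighted_linear"):
            raise ValidationError(f"unknown trajectory function {self.function!r}")
        if self.initial_source not in ("LACE", "HOSPITAL", "average"):
            raise ValidationError(f"unknown initial source {self.initial_source!r}")
        if self.readmitted_mode not in ("reset_to_initial", "continue_from_one"):
            raise ValidationError(f"unknown readmitted mode {self.readmitted_mode!r}")


@dataclass(frozen=True)
class SegmentParams:
    """Fitted parameters of one trajectory segment over days ``d1..d2``.

    ``kind`` is ``constant`` when the segment endpoints coincide and the
    exponential/logarithmic forms degenerate.  For exponential and
    logarithmic segments the parameters refer to the local day index
    ``n' = n - d1 + 1``.
    """

    kind: str
    a: float
    b: float
    d1: int
    d2: int


@dataclass
class RiskTrajectory:
    """The per-day probability label sequence for one patient."""

    patient_id: str
    probabilities: np.ndarray
    segments: list[SegmentParams]
    config: TrajectoryConfig

    def __len__(self) -> int:
        return len(self.probabilities)

    def probability_on(self, day: int) -> float:
        """Probability on 1-based day index ``day``."""
        return float(self.probabilities[day - 1])


def initial_probability(meta: PatientMeta, source: InitialSource = "average") -> float:
    """Initial readmission probability from LACE and/or HOSPITAL scores.

    The mapping is linear over each score's index range: LACE ``s`` maps to
    ``s/19``, HOSPITAL ``s`` to ``s/15``, and ``average`` to the arithmetic
    mean of the two normalised values.
    """
    lace_p = meta.lace / LACE_MAX
    hospital_p = meta.hospital / HOSPITAL_MAX
    if source == "LACE":
        return lace_p
    if source == "HOSPITAL":
        return hospital_p
    if source == "average":
        return 0.5 * (lace_p + hospital_p)
    raise ValidationError(f"unknown initial source {source!r}")


def _check_segment_args(p_start: float, p_end: float, d1: int, d2: int) -> None:
    if d2 <= d1:
        raise ValidationError(f"segment requires d2 > d1 (got d1={d1}, d2={d2})")
    for name, p in (("p_start", p_start), ("p_end", p_end)):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"{name}={p} outside [0, 1]")


def _solve_rising_exponential(delta: float, L: int) -> float:
    """Unique root a > 1 of ``a**L - a = delta`` for a rise of size delta > 0."""
    f = lambda a: a**L - a - delta  # noqa: E731
    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, 1.0 + 1e-14, hi, xtol=1e-14, rtol=1e-15)


def fit_segment(
    function: TrajectoryFunction,
    p_start: float,
    p_end: float,
    d1: int,
    d2: int,
) -> SegmentParams:
    """Fit the two parameters (a, b) of one segment from its endpoints.

    The segment must satisfy ``p(d1) = p_start`` and ``p(d2) = p_end``
    exactly (linear) or to ~1e-10 (exponential, solved numerically).

    For the exponential family ``a**n' + b`` with local length
    ``L = d2 - d1 + 1`` the endpoint constraints reduce to
    ``a**L - a = p_end - p_start``, which on the decaying branch
    ``a in (0, 1)`` has two roots; we take the root above the minimiser
    ``a* = (1/L)**(1/(L-1))``, the branch on which the curve decays
    gradually over the whole segment rather than collapsing to ``p_end``
    within the first days.  Rising segments use the unique root ``a > 1``.
    """
    _check_segment_args(p_start, p_end, d1, d2)
    delta = p_end - p_start
    if function == "linear":
        a = delta / (d2 - d1)
        b = p_start - a * d1
        return SegmentParams("linear", a, b, d1, d2)
    if function == "weighted_linear":
        raise ValidationError(
            "weighted_linear segments are generated by weighted_linear_segment, "
            "not fitted via (a, b)"
        )
    if abs(delta) < 1e-15:
        # exponential/logarithmic degenerate to a constant segment
        return SegmentParams("constant", 0.0, p_start, d1, d2)
    L = d2 - d1 + 1
    if function == "exponential":
        f = lambda a: a**L - a - delta  # noqa: E731
        if delta < 0:
            # decaying branch a in (0,1): the drop a - a**L is bounded above
            # (max at the minimiser a*), so steep falls are not representable
            # by a**n' + b directly; those use the time-reversed rising fit,
            # which hits both endpoints and is monotone for any drop.
            a_min = (1.0 / L) ** (1.0 / (L - 1))
            if f(a_min) > 0:
                a = _solve_rising_exponential(-delta, L)
                b = p_end - a
                return SegmentParams("exponential_reversed", a, b, d1, d2)
            a = brentq(f, a_min, 1.0 - 1e-14, xtol=1e-14, rtol=1e-15)
        else:
            a = _solve_rising_exponential(delta, L)
        b = p_start - a
        return SegmentParams("exponential", a, b, d1, d2)
    if function == "logarithmic":
        # log_a(1) = 0 pins b; log_a(L) = delta gives a = L**(1/delta)
        b = p_start
        a = L ** (1.0 / delta)
        return SegmentParams("logarithmic", a, b, d1, d2)
    raise ValidationError(f"unknown trajectory function {function!r}")


def segment_values(params: SegmentParams) -> np.ndarray:
    """Evaluate a fitted segment on its own days ``d1..d2`` (inclusive)."""
    days = np.arange(params.d1, params.d2 + 1)
    if params.kind == "linear":
        return params.a * days + params.b
    if params.kind == "constant":
        return np.full(days.shape, params.b)
    local = days - params.d1 + 1
    if params.kind == "exponential":
        return params.a**local + params.b
    if params.kind == "exponential_reversed":
        L = params.d2 - params.d1 + 1
        return params.a ** (L - local + 1) + params.b
    if params.kind == "logarithmic":
        return np.log(local) / np.log(params.a) + params.b
    raise ValidationError(f"unknown segment kind {params.kind!r}")


def weighted_linear_weights(d1: int, d2: int) -> np.ndarray:
    """Parabolic weights ``w_n = 4/(d1-d2)^2 * (n - (d1+d2)/2)^2`` for n in d1..d2.

    The weight is exactly 1 at both segment endpoints and 0 at the midpoint
    (when the midpoint lands on an integer day).
    """
    if d2 <= d1:
        raise ValidationError(f"weights require d2 > d1 (got d1={d1}, d2={d2})")
    n = np.arange(d1, d2 + 1, dtype=float)
    return 4.0 / (d1 - d2) ** 2 * (n - (d1 + d2) / 2.0) ** 2


def weighted_linear_segment(
    p_start: float, p_end: float, d1: int, d2: int
) -> np.ndarray:
    """Weighted-linear segment ``p_n = w_n*l_n + (1-w_n)*p_{n-1}``.

    ``l_n`` is the plain linear interpolant between the endpoints.  Because
    ``w_{d1} = 1`` the recursion has no dependence on a (undefined) value
    before the segment start, and ``w_{d2} = 1`` forces the endpoint
    ``p_{d2} = l_{d2} = p_end`` exactly.
    """
    _check_segment_args(p_start, p_end, d1, d2)
    w = weighted_linear_weights(d1, d2)
    lin = segment_values(fit_segment("linear", p_start, p_end, d1, d2))
    out = np.empty_like(lin)
    out[0] = lin[0]  # w[0] == 1 exactly
    for i in range(1, len(lin)):
        out[i] = w[i] * lin[i] + (1.0 - w[i]) * out[i - 1]
    return out


def _segment(
    function: TrajectoryFunction, p_start: float, p_end: float, d1: int, d2: int
) -> tuple[np.ndarray, SegmentParams]:
    if function == "weighted_linear":
        values = weighted_linear_segment(p_start, p_end, d1, d2)
        params = SegmentParams("weighted_linear", float("nan"), float("nan"), d1, d2)
        return values, params
    params = fit_segment(function, p_start, p_end, d1, d2)
    return segment_values(params), params


def build_trajectory(meta: PatientMeta, config: TrajectoryConfig) -> RiskTrajectory:
    """Generate the full per-day risk probability sequence for one patient.

    Non-readmitted patients fall from the initial probability to 0 over days
    1..horizon.  Readmitted patients rise from the initial probability to 1
    on the readmission day; while re-hospitalised (readmission day to second
    discharge) the probability either holds at 1 (``continue_from_one``) or
    falls back to the initial probability (``reset_to_initial``); after the
    second discharge it falls to 0 on the final day.
    """
    horizon = config.horizon
    p_init = initial_probability(meta, config.initial_source)
    probs = np.zeros(horizon)
    segments: list[SegmentParams] = []

    def place(values: np.ndarray, d1: int) -> None:
        probs[d1 - 1 : d1 - 1 + len(values)] = values

    if not meta.readmitted:
        values, params = _segment(config.function, p_init, 0.0, 1, horizon)
        place(values, 1)
        segments.append(params)
    else:
        k = meta.readmission_day
        d2nd = meta.second_discharge_day
        if k is None or d2nd is None:  # pragma: no cover - guarded by PatientMeta
            raise ValidationError("readmitted patient lacks timeline days")
        if k >= horizon:
            raise ValidationError(
                f"readmission_day {k} must precede the horizon {horizon} "
                f"(patient {meta.patient_id!r})"
            )
        if k < 2:
            raise ValidationError(f"readmission_day {k} must be >= 2")
        if d2nd > horizon:
            raise ValidationError(
                f"second_discharge_day {d2nd} beyond horizon {horizon}"
            )
        rise, params = _segment(config.function, p_init, 1.0, 1, k)
        place(rise, 1)
        segments.append(params)
        if config.readmitted_mode == "continue_from_one":
            probs[k - 1 : d2nd] = 1.0
            segments.append(SegmentParams("constant", 0.0, 1.0, k, d2nd))
            p_after = 1.0
        else:
            fall, params = _segment(config.function, 1.0, p_init, k, d2nd)
            place(fall, k)
            segments.append(params)
            p_after = p_init
        if d2nd < horizon:
            tail, params = _segment(config.function, p_after, 0.0, d2nd, horizon)
            place(tail, d2nd)
            segments.append(params)
        else:
            # degenerate: second discharge on the final day; the final-day
            # probability is 0 by definition of the horizon
            probs[horizon - 1] = 0.0
    probs = np.clip(probs, 0.0, 1.0)
    # anchor days are exact by definition, not subject to solver round-off
    probs[0] = p_init
    if meta.readmitted:
        probs[meta.readmission_day - 1] = 1.0
    probs[horizon - 1] = 0.0
    return RiskTrajectory(meta.patient_id, probs, segments, config)


# ---------------------------------------------------------------------------
# CSV interfaces


def load_patient_meta(path) -> list[PatientMeta]:
    """Read a patient metadata CSV into validated ``PatientMeta`` records.

    Expected columns: patient_id, readmitted, readmission_day,
    second_discharge_day, lace, hospital.  Empty day cells mean absent.
    """
    df = pd.read_csv(path)
    metas = []
    for row in df.itertuples(index=False):
        readmitted = bool(row.readmitted)

        def _day(value):
            return None if pd.isna(value) else int(value)

        metas.append(
            PatientMeta(
                patient_id=str(row.patient_id),
                readmitted=readmitted,
                lace=int(row.lace),
                hospital=int(row.hospital),
                readmission_day=_day(getattr(row, "readmission_day", None)),
                second_discharge_day=_day(getattr(row, "second_discharge_day", None)),
            )
        )
    return metas


def load_trajectories(path, config: TrajectoryConfig) -> dict[str, RiskTrajectory]:
    """Read a trajectory CSV (patient_id, day, probability) back into objects.

    Segment parameters are not reconstructed from the CSV; pass the config
    the trajectories were generated with (it travels in the JSON sidecar).
    """
    df = pd.read_csv(path)
    out: dict[str, RiskTrajectory] = {}
    for pid, block in df.groupby("patient_id", sort=False):
        block = block.sort_values("day")
        out[str(pid)] = RiskTrajectory(
            str(pid), block["probability"].to_numpy(), [], config
        )
    return out


def trajectories_to_frame(trajectories: Sequence[RiskTrajectory]) -> pd.DataFrame:
    """Long-format frame (patient_id, day, probability) of label trajectories."""
    parts = []
    for traj in trajectories:
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": traj.patient_id,
                    "day": np.arange(1, len(traj) + 1),
                    "probability": traj.probabilities,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def save_trajectories(trajectories: Sequence[RiskTrajectory], csv_path, sidecar_path=None) -> None:
    """Write trajectory CSV and an optional JSON sidecar with segment parameters."""
    trajectories_to_frame(trajectories).to_csv(csv_path, index=False)
    if sidecar_path is not None:
        payload = {
            traj.patient_id: {
                "function": traj.config.function,
                "initial_source": traj.config.initial_source,
                "readmitted_mode": traj.config.readmitted_mode,
                "horizon": traj.config.horizon,
                "segments": [
                    {"kind": s.kind, "a": s.a, "b": s.b, "d1": s.d1, "d2": s.d2}
                    for s in traj.segments
                ],
            }
            for traj in trajectories
        }
        with open(sidecar_path, "w") as fh:
            json.dump(payload, fh, indent=2)
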