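"""Kaplan-Meier curves, restricted mean survival time, and RMST ratios.

The restricted mean survival time (RMST) at a horizon ``t*`` is
``E[min(T, t*)]``, the area under the survival curve S(t) on [0, t*].
Because it does not assume proportional hazards it is the preferred
effect scale for comparing survival between a ketogenic-therapy arm and
a control arm: the RMST ratio ("MR") of treatment to control is
dimensionless and directly interpretable as a relative survival
prolongation, with MR > 1 favouring treatment.

Standard errors of the RMST use the Greenwood-type variance

    Var[RMST] = sum_i A_i^2 * d_i / (n_i (n_i - d_i))

where the sum runs over distinct event times t_i with d_i events and
n_i at risk, and A_i is the area under S from t_i to the horizon; terms
with n_i = d_i are skipped. Log-ratio standard errors follow from the
first-order delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalArm",
    "KMCurve",
    "RMSTEstimate",
    "MREstimate",
    "fit_km",
    "rmst",
    "mr_from_arms",
    "read_survival_table",
    "summarize_survival_table",
]


@dataclass(frozen=True)
class SurvivalArm:
    """Raw time-to-event records for one study arm.

    ``records`` holds ``(time, event)`` pairs: ``event`` is 1 for an
    observed event and 0 for right censoring. Times must be positive and
    share one unit within a study (days for the animal experiments,
    months for the patient cohorts). At least one event is required.
    """

    label: str
    records: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValueError(f"arm {self.label!r} has no records")
        times = np.array([t for t, _ in self.records], dtype=float)
        events = np.array([e for _, e in self.records], dtype=int)
        if np.any(times <= 0) or not np.all(np.isfinite(times)):
            raise ValueError(f"arm {self.label!r} has nonpositive or nonfinite times")
        if not np.all((events == 0) | (events == 1)):
            raise ValueError(f"arm {self.label!r} has event flags outside {{0, 1}}")
        if events.sum() == 0:
            raise ValueError(f"arm {self.label!r} is fully censored; no event observed")

    @classmethod
    def from_arrays(
        cls, label: str, times: Iterable[float], events: Iterable[int]
    ) -> "SurvivalArm":
        return cls(label, tuple(zip((float(t) for t in times), (int(e) for e in events))))

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def max_time(self) -> float:
        return max(t for t, _ in self.records)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function.

    Steps are the distinct event times; S(0) = 1 is implied. ``at_risk``
    and ``events`` are the risk-set size and event count at each step,
    with censorings at a tied time removed from the risk set only after
    the events (events-first tie convention).
    """

    step_times: np.ndarray
    surv_probs: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) for a scalar time (right-continuous)."""
        idx = np.searchsorted(self.step_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv_probs[idx])


@dataclass(frozen=True)
class RMSTEstimate:
    """Restricted mean survival time with its standard error, in time units."""

    value: float
    se: float
    horizon: float

    def __post_init__(self) -> None:
        if not (0 < self.value <= self.horizon * (1 + 1e-12)):
            raise ValueError("RMST must lie in (0, horizon]")
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")


@dataclass(frozen=True)
class MREstimate:
    """RMST ratio (treatment / control) on natural and log scales."""

    mr: float
    se_mr: float
    ln_mr: float = field(default=float("nan"))
    se_ln_mr: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.mr <= 0:
            raise ValueError("MR must be positive")
        if math.isnan(self.ln_mr):
            object.__setattr__(self, "ln_mr", math.log(self.mr))
        if math.isnan(self.se_ln_mr):
            object.__setattr__(self, "se_ln_mr", self.se_mr / self.mr)


def fit_km(arm: SurvivalArm) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one arm.

    Ties of events and censorings at the same time are resolved events
    first, so a censored subject at time t is still at risk for an event
    at t.
    """
    times = np.array([t for t, _ in arm.records], dtype=float)
    events = np.array([e for _, e in arm.records], dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    event_times, d = np.unique(times[events == 1], return_counts=True)
    # events-first tie rule: anyone with time >= t (censored or not) is
    # still at risk at t
    at_risk = len(times) - np.searchsorted(times, event_times, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(step_times=event_times, surv_probs=surv, at_risk=at_risk, events=d)


def rmst(curve: KMCurve, horizon: float) -> RMSTEstimate:
    """Area under the KM step function on [0, horizon], with Greenwood-type SE.

    The default horizon convention of the surrounding pipeline is the
    last recorded time of the arm; callers may pass any positive horizon
    not exceeding it.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    t = curve.step_times
    s = curve.surv_probs
    # integrate the step function: S = 1 on [0, t_1), s_k on [t_k, t_{k+1})
    knots = np.concatenate(([0.0], np.minimum(t, horizon), [horizon]))
    heights = np.concatenate(([1.0], s))
    widths = np.diff(knots)
    area = float(np.sum(heights * np.clip(widths, 0.0, None)))

    # Greenwood-type variance: sum over event times before the horizon of
    # A_i^2 d_i / (n_i (n_i - d_i)), A_i = area under S from t_i to horizon.
    # A_i computed as a suffix sum of the per-segment areas s_k (t_{k+1}-t_k).
    tc = np.minimum(t, horizon)
    seg = s * np.diff(np.append(tc, horizon))  # area of [t_k, t_{k+1}) piece
    a = np.cumsum(seg[::-1])[::-1]  # A_i = area under S on [t_i, horizon]
    n_i = curve.at_risk
    d_i = curve.events
    keep = (t < horizon) & (n_i > d_i)  # skip terms with n_i == d_i
    var = float(np.sum(a[keep] ** 2 * d_i[keep] / (n_i[keep] * (n_i[keep] - d_i[keep]))))
    return RMSTEstimate(value=area, se=math.sqrt(var), horizon=horizon)


def mr_from_arms(treat: RMSTEstimate, ctrl: RMSTEstimate) -> MREstimate:
    """RMST ratio treatment/control with delta-method standard errors.

    ``se_ln_mr`` combines the two relative standard errors in
    quadrature; ``se_mr = mr * se_ln_mr`` to first order.
    """
    if treat.value <= 0 or ctrl.value <= 0:
        raise ValueError("both RMST values must be positive")
    ratio = treat.value / ctrl.value
    se_ln = math.hypot(treat.se / treat.value, ctrl.se / ctrl.value)
    return MREstimate(mr=ratio, se_mr=ratio * se_ln, ln_mr=math.log(ratio), se_ln_mr=se_ln)


def read_survival_table(path) -> pd.DataFrame:
    """Read a delimited per-subject survival table.

    Required columns: ``study_id``, ``arm`` (``treatment``/``control``),
    ``time`` (positive, raw study units), ``event`` (0/1). Comma or tab
    delimited with a header row.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"study_id", "arm", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    bad_arm = set(df["arm"].unique()) - {"treatment", "control"}
    if bad_arm:
        raise ValueError(f"unknown arm labels: {sorted(bad_arm)}")
    return df


def summarize_survival_table(
    df: pd.DataFrame, shared_horizon: bool = False
) -> pd.DataFrame:
    """Per-arm RMST summaries and per-study MR from a raw survival table.

    By default each arm is integrated to its own last recorded time; with
    ``shared_horizon`` both arms of a study use the smaller of the two
    maxima, giving areas over a common window.
    """
    rows = []
    for study, group in df.groupby("study_id", sort=False):
        arms: dict[str, tuple[SurvivalArm, RMSTEstimate]] = {}
        horizons = {
            arm_name: sub["time"].max() for arm_name, sub in group.groupby("arm")
        }
        if shared_horizon:
            h_common = min(horizons.values())
        for arm_name, sub in group.groupby("arm"):
            arm = SurvivalArm.from_arrays(
                f"{study}/{arm_name}", sub["time"].to_numpy(), sub["event"].to_numpy()
            )
            h = h_common if shared_horizon else float(horizons[arm_name])
            arms[arm_name] = (arm, rmst(fit_km(arm), h))
        mr = None
        if {"treatment", "control"} <= arms.keys():
            mr = mr_from_arms(arms["treatment"][1], arms["control"][1])
        for arm_name, (arm, est) in arms.items():
            rows.append(
                {
                    "study": study,
                    "arm": arm_name,
                    "n": arm.n,
                    "horizon": est.horizon,
                    "rmst": est.value,
                    "se": est.se,
                    "mr": mr.mr if mr and arm_name == "treatment" else np.nan,
                    "se_mr": mr.se_mr if mr and arm_name == "treatment" else np.nan,
                    "ln_mr": mr.ln_mr if mr and arm_name == "treatment" else np.nan,
                    "se_ln_mr": mr.se_ln_mr if mr and arm_name == "treatment" else np.nan,
                }
            )
    return pd.DataFrame(rows)
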