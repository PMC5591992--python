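"""Sensitivity estimators for perturbation-trial data.

All four methods operate on a :class:`TrialSet`: the unaltered reference
aperture's (area, signal) pair plus the 30 perturbation trials' (area, signal)
pairs for one segment.  Throughout, X is segment area (cm^2) and Y the chamber
signal.

Methods
-------
scatter_gradient
    Ordinary least-squares slope of Y on X — the scatter-plot trend gradient.
brute_force_si
    Per-trial perturbation index (Y0 - Yi) / (X0 - Xi) against the reference.
var_first_order
    Binned first-order (main-effect) variance index V(E[Y|X]) / V(Y).
src
    Standardized regression coefficient b * s_X / s_Y, plus per-trial
    standardized ratios.

The reference point anchors the brute-force differences but is excluded from
the regression and variance estimators, keeping the sample at the 30 trials.
Indices are reported signed; summaries use magnitudes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Default near-zero-denominator guard: cm^2 for brute force, standardized
#: units for the per-trial SRC ratio.
DEFAULT_EPSILON = 1e-6


class DegenerateTrialSetError(ValueError):
    """The trial data have no usable spread for the requested estimator."""


@dataclass(frozen=True)
class TrialObservation:
    level_mm: float
    trial_index: int
    area_cm2: float
    signal: float


@dataclass(frozen=True)
class TrialSet:
    """Reference (area, signal) plus the perturbation trials for one segment."""

    segment: str
    reference_area_cm2: float
    reference_signal: float
    trials: tuple[TrialObservation, ...]

    def __post_init__(self) -> None:
        if self.reference_area_cm2 <= 0:
            raise ValueError("reference area must be positive")
        areas = self.areas
        if not np.all(np.isfinite(areas)) or np.any(areas <= 0):
            raise ValueError("trial areas must be finite and positive")

    @property
    def areas(self) -> np.ndarray:
        return np.array([t.area_cm2 for t in self.trials])

    @property
    def signals(self) -> np.ndarray:
        return np.array([t.signal for t in self.trials])

    @property
    def n(self) -> int:
        return len(self.trials)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, segment: str) -> "TrialSet":
        """Build from a trials table with columns
        segment, level_mm, trial, area_cm2, signal; level_mm == 0 rows are
        treated as the unaltered reference."""
        sub = df[df["segment"] == segment]
        ref = sub[sub["level_mm"] == 0]
        if len(ref) != 1:
            raise ValueError(
                f"expected exactly one reference row (level_mm == 0) for "
                f"{segment!r}, found {len(ref)}"
            )
        alt = sub[sub["level_mm"] != 0]
        trials = tuple(
            TrialObservation(
                level_mm=float(r.level_mm),
                trial_index=int(r.trial),
                area_cm2=float(r.area_cm2),
                signal=float(r.signal),
            )
            for r in alt.itertuples()
        )
        return cls(
            segment=segment,
            reference_area_cm2=float(ref["area_cm2"].iloc[0]),
            reference_signal=float(ref["signal"].iloc[0]),
            trials=trials,
        )


@dataclass
class SensitivityResult:
    """Outcome of one estimator on one TrialSet.

    ``per_trial`` is aligned with the TrialSet's trials; entries whose value
    is undefined (e.g. a vanishing denominator) are NaN and their indices are
    listed in ``excluded`` rather than dropped.
    """

    method: str
    segment: str
    global_index: float
    per_trial: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    excluded: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "segment": self.segment,
                "trial": np.arange(len(self.per_trial)),
                "value": self.per_trial,
                "excluded": [i in self.excluded for i in range(len(self.per_trial))],
            }
        )


def _require_spread(x: np.ndarray, name: str) -> None:
    if x.size < 3:
        raise DegenerateTrialSetError(f"need at least 3 trials, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateTrialSetError(f"all {name} values identical; estimator undefined")


def scatter_gradient(trial_set: TrialSet) -> SensitivityResult:
    """OLS line of signal on area over the trials (reference excluded).

    The global index is the signed slope (cm^-2 when Y is a relative signal);
    intercept and r^2 are carried in the diagnostics.
    """
    x, y = trial_set.areas, trial_set.signals
    _require_spread(x, "area")
    fit = stats.linregress(x, y)
    return SensitivityResult(
        method="scatter_gradient",
        segment=trial_set.segment,
        global_index=float(fit.slope),
        per_trial=np.full(trial_set.n, np.nan),
        diagnostics={
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue**2),
            "stderr": float(fit.stderr),
        },
    )


def brute_force_si(trial_set: TrialSet, epsilon: float = DEFAULT_EPSILON) -> SensitivityResult:
    """Per-trial perturbation index SI_i = (Y0 - Yi) / (X0 - Xi).

    Trials whose area change |X0 - Xi| falls below ``epsilon`` (cm^2) are
    flagged undefined and excluded from the global summary, which is the
    maximum |SI_i| over the defined trials.
    """
    x0, y0 = trial_set.reference_area_cm2, trial_set.reference_signal
    dx = x0 - trial_set.areas
    dy = y0 - trial_set.signals
    defined = np.abs(dx) >= epsilon
    per_trial = np.full(trial_set.n, np.nan)
    per_trial[defined] = dy[defined] / dx[defined]
    excluded = list(np.flatnonzero(~defined))
    if not defined.any():
        logger.warning(
            "%s: every trial area change below epsilon=%g; brute-force index empty",
            trial_set.segment,
            epsilon,
        )
        global_index = math.nan
    else:
        global_index = float(np.nanmax(np.abs(per_trial)))
    return SensitivityResult(
        method="brute_force",
        segment=trial_set.segment,
        global_index=global_index,
        per_trial=per_trial,
        diagnostics={"epsilon_cm2": epsilon, "n_defined": int(defined.sum())},
        excluded=excluded,
    )


def _binned_main_effect(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """V(E[Y|X]) / V(Y) with E[Y|X] estimated on equal-count bins of X.

    Both variances use the population convention (ddof=0) so the index is the
    between-bin fraction of total variance, bounded by 1 up to ties.
    """
    v_y = float(np.var(y))
    if v_y == 0:
        raise DegenerateTrialSetError("V(Y) = 0; variance index undefined")
    order = np.argsort(x, kind="stable")
    bins = np.array_split(order, n_bins)
    n = len(y)
    mean = float(np.mean(y))
    v_between = sum(len(b) / n * (float(np.mean(y[b])) - mean) ** 2 for b in bins)
    return v_between / v_y


def var_first_order(trial_set: TrialSet, n_bins: int = 5) -> SensitivityResult:
    """First-order (main-effect) variance index of signal with respect to area.

    Global index: V(E[Y|X]) / V(Y), with the conditional expectation estimated
    by averaging Y within ``n_bins`` equal-count bins of X.  The per-trial
    curve applies the same estimator cumulatively over the subset of trials
    with area <= that trial's area, which traces how the explained-variance
    fraction builds up across the area range; prefixes too small to bin
    (fewer than 4 trials or with zero signal variance) are NaN.
    """
    x, y = trial_set.areas, trial_set.signals
    _require_spread(x, "area")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if trial_set.n < 2 * n_bins:
        raise DegenerateTrialSetError(
            f"need >= 2 trials per bin: {trial_set.n} trials for {n_bins} bins"
        )
    global_index = _binned_main_effect(x, y, n_bins)

    order = np.argsort(x, kind="stable")
    per_trial = np.full(trial_set.n, np.nan)
    excluded: list[int] = []
    for rank, idx in enumerate(order):
        subset = order[: rank + 1]
        k = min(n_bins, len(subset) // 2)
        if k < 2 or np.var(y[subset]) == 0:
            excluded.append(int(idx))
            continue
        per_trial[idx] = _binned_main_effect(x[subset], y[subset], k)
    return SensitivityResult(
        method="var_first_order",
        segment=trial_set.segment,
        global_index=float(global_index),
        per_trial=per_trial,
        diagnostics={"n_bins": n_bins},
        excluded=excluded,
    )


def src(trial_set: TrialSet, epsilon: float = DEFAULT_EPSILON) -> SensitivityResult:
    """Standardized regression coefficient of signal on area.

    Global index: OLS slope x s_X / s_Y, which for simple regression equals
    the Pearson correlation and lies in [-1, 1].  The per-trial values are the
    standardized ratios z_Y(i) / z_X(i), flagged undefined where |z_X| falls
    below ``epsilon``, and reported normalized to the largest defined
    magnitude.
    """
    x, y = trial_set.areas, trial_set.signals
    _require_spread(x, "area")
    s_x = float(np.std(x, ddof=1))
    s_y = float(np.std(y, ddof=1))
    if s_x == 0 or s_y == 0:
        raise DegenerateTrialSetError("zero variance in area or signal")
    fit = stats.linregress(x, y)
    global_src = float(fit.slope * s_x / s_y)

    z_x = (x - x.mean()) / s_x
    z_y = (y - y.mean()) / s_y
    defined = np.abs(z_x) >= epsilon
    raw = np.full(trial_set.n, np.nan)
    raw[defined] = z_y[defined] / z_x[defined]
    max_abs = np.nanmax(np.abs(raw)) if defined.any() else math.nan
    per_trial = raw / max_abs if defined.any() and max_abs > 0 else raw
    return SensitivityResult(
        method="src",
        segment=trial_set.segment,
        global_index=global_src,
        per_trial=per_trial,
        diagnostics={
            "slope": float(fit.slope),
            "r_squared": float(fit.rvalue**2),
            "epsilon_std": epsilon,
            "normalization": "max_abs_defined",
        },
        excluded=list(np.flatnonzero(~defined)),
    )


ALL_METHODS = {
    "scatter_gradient": scatter_gradient,
    "brute_force": brute_force_si,
    "var_first_order": var_first_order,
    "src": src,
}


def analyze_trial_set(
    trial_set: TrialSet,
    n_bins: int = 5,
    epsilon: float = DEFAULT_EPSILON,
) -> dict[str, SensitivityResult]:
    """Run all four estimators on one TrialSet.

    An estimator whose preconditions the data cannot meet (e.g. too few
    trials for the requested bin count) is reported as a gap — logged and
    omitted from the mapping — rather than aborting the other methods.
    """
    out: dict[str, SensitivityResult] = {}
    runners = {
        "scatter_gradient": lambda: scatter_gradient(trial_set),
        "brute_force": lambda: brute_force_si(trial_set, epsilon=epsilon),
        "var_first_order": lambda: var_first_order(trial_set, n_bins=n_bins),
        "src": lambda: src(trial_set, epsilon=epsilon),
    }
    for name, runner in runners.items():
        try:
            out[name] = runner()
        except DegenerateTrialSetError as exc:
            logger.warning("%s: %s skipped: %s", trial_set.segment, name, exc)
    return out
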