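"""Power-law trends of sensitivity measures versus original segment area.

Across segments, the scatter-plot gradient falls steeply with segment area
while the first-order variance index is nearly flat; both are summarized by a
power law y = a * x^b fitted by nonlinear least squares on the original scale
(initialized from the log-log OLS solution).  Original-scale fitting is the
default because it weights the large-gradient small-area points as measured;
the log-log fit, which answers a subtly different question on heteroscedastic
data, is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .sensitivity_methods import SensitivityResult


class PowerFitError(ValueError):
    """Power-law fitting failed or the inputs are outside its domain."""


@dataclass(frozen=True)
class PowerFit:
    """Fitted y = a * x^b with residual sum of squares on the fit scale."""

    coefficient: float
    exponent: float
    rss: float
    method: str
    n_points: int
    converged: bool = True

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.coefficient * np.asarray(x, dtype=float) ** self.exponent

    def describe(self) -> str:
        return f"y = {self.coefficient:.4g} * x^{self.exponent:.4g}"


def _loglog_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    return float(np.exp(intercept)), float(slope)


def fit_power(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    method: str = "nls",
) -> PowerFit:
    """Fit y = a * x^b.

    ``method="nls"`` (default) minimizes the residual sum of squares on the
    original scale, started from the log-log OLS solution; ``method="loglog"``
    returns the log-log OLS fit itself.  Requires >= 3 strictly positive
    points in both coordinates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise PowerFitError(f"need >= 3 points, got {x.size}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise PowerFitError("power-law fitting requires strictly positive x and y")
    a0, b0 = _loglog_fit(x, y)
    if method == "loglog":
        rss = float(np.sum((np.log(y) - np.log(a0) - b0 * np.log(x)) ** 2))
        return PowerFit(a0, b0, rss, "loglog", x.size)
    if method != "nls":
        raise ValueError(f"unknown fit method {method!r}")
    try:
        popt, _ = curve_fit(
            lambda xx, a, b: a * xx**b, x, y, p0=[a0, b0], maxfev=10000
        )
    except RuntimeError as exc:
        raise PowerFitError(
            f"nonlinear fit did not converge (log-log fallback: a={a0:.6g}, "
            f"b={b0:.6g})"
        ) from exc
    a, b = (float(v) for v in popt)
    rss = float(np.sum((y - a * x**b) ** 2))
    return PowerFit(a, b, rss, "nls", x.size)


def power_derivative(fit: PowerFit) -> tuple[float, float]:
    """Exact derivative of a * x^b: returns (a*b, b-1) so d/dx = (a*b) * x^(b-1)."""
    if not (np.isfinite(fit.coefficient) and np.isfinite(fit.exponent)):
        raise PowerFitError("fit parameters must be finite")
    return fit.coefficient * fit.exponent, fit.exponent - 1.0


def fit_constant(y: np.ndarray | list[float]) -> PowerFit:
    """Degenerate power law with the exponent pinned at 0: a = mean(y)."""
    y = np.asarray(y, dtype=float)
    a = float(np.mean(y))
    return PowerFit(a, 0.0, float(np.sum((y - a) ** 2)), "constant", y.size)


def summarize_segments(
    per_segment: dict[str, dict[str, "SensitivityResult"]],
    areas: dict[str, float],
    fit_method: str = "nls",
) -> tuple[pd.DataFrame, dict[str, PowerFit]]:
    """Cross-segment summary table plus power-law fits of the trends.

    ``per_segment`` maps segment label -> {method name -> SensitivityResult};
    ``areas`` maps segment label -> original area (cm^2).  The table carries
    one row per segment, sorted by area, with the scatter-plot gradient, the
    variance index, the brute-force maximum and the SRC.  A missing method
    appears as NaN rather than being silently dropped.  Power laws are fitted
    to the scatter-gradient and variance-index columns (magnitudes) where at
    least 3 segments supply positive values.
    """
    if len(per_segment) < 2:
        raise ValueError("need results for at least 2 segments")
    rows = []
    for label, results in per_segment.items():
        def _get(name: str) -> float:
            res = results.get(name)
            return float(res.global_index) if res is not None else np.nan

        rows.append(
            {
                "segment": label,
                "area_cm2": areas[label],
                "sp_gradient": _get("scatter_gradient"),
                "var_index": _get("var_first_order"),
                "brute_force_max": _get("brute_force"),
                "src": _get("src"),
            }
        )
    table = pd.DataFrame(rows).sort_values("area_cm2", ignore_index=True)

    fits: dict[str, PowerFit] = {}
    for column in ("sp_gradient", "var_index"):
        vals = table[column].abs()
        ok = vals.notna() & (vals > 0)
        if ok.sum() >= 3:
            fits[column] = fit_power(
                table.loc[ok, "area_cm2"].to_numpy(), vals[ok].to_numpy(), method=fit_method
            )
    return table, fits
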