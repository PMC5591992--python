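"""Parametric surrogate for the double-wedge transmission chamber signal.

The physical device is a large-area transmission ionization chamber whose
wedge-shaped electrodes make the local response grow along one axis (the
*gradient* axis, Y, perpendicular to leaf travel) until a plateau is reached
near the thick end of the wedge.  Here that behaviour is captured by a spatial
sensitivity weight

    w(y) = w0 + g * y          for y <= y_plateau
    w(y) = w0 + g * y_plateau  for y >  y_plateau

and the noise-free signal for an aperture is the integral of w over the open
aperture, with uniform fluence inside the aperture and zero outside.  Optional
multiplicative Gaussian noise N(1, relative_sigma) emulates Monte Carlo
scoring uncertainty (kept below 1% relative in the study).

This is a geometric stand-in for full radiation transport: it reproduces the
qualitative behaviours the sensitivity analysis depends on (area-dominated
signal, rising gradient profile, plateau) without modelling the beam.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mlc_segments import Segment


class ApertureOutsideChamberError(ValueError):
    """The projected aperture does not lie within the chamber's active span."""


@dataclass
class NoiseModel:
    """Multiplicative Gaussian noise N(1, relative_sigma) on each signal."""

    relative_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sigma < 0:
            raise ValueError("relative_sigma must be >= 0")
        self._rng = np.random.default_rng(self.seed)

    def factor(self) -> float:
        return float(self._rng.normal(1.0, self.relative_sigma))


@dataclass(frozen=True)
class ChamberModel:
    """Ramp-plus-plateau spatial sensitivity model of the chamber.

    Parameters
    ----------
    span_cm
        Active extent along the gradient axis, centered on the beam axis;
        default 40 cm (+/-20 cm at isocenter, the maximum monitorable field).
    w0
        Relative weight at y = 0 (arbitrary units).
    gradient_per_cm
        Slope g of the ramp.  Must keep w positive over the whole span.
    plateau_fraction
        Fraction of the span, at the thick (+Y) end, over which the weight is
        constant at its y_plateau value.
    """

    span_cm: float = 40.0
    w0: float = 1.0
    gradient_per_cm: float = 0.02
    plateau_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.span_cm <= 0:
            raise ValueError("span_cm must be positive")
        if not 0.0 <= self.plateau_fraction < 1.0:
            raise ValueError("plateau_fraction must be in [0, 1)")
        if self.weight(-self.half_span) <= 0:
            raise ValueError(
                "sensitivity weight must stay positive over the active span; "
                f"w({-self.half_span:g}) <= 0 for w0={self.w0}, g={self.gradient_per_cm}"
            )

    @property
    def half_span(self) -> float:
        return self.span_cm / 2.0

    @property
    def y_plateau(self) -> float:
        """Gradient-axis position where the ramp saturates."""
        return self.half_span - self.plateau_fraction * self.span_cm

    def weight(self, y: float | np.ndarray) -> np.ndarray:
        """Relative sensitivity w(y): linear ramp saturating at y_plateau."""
        y_eff = np.minimum(np.asarray(y, dtype=float), self.y_plateau)
        return self.w0 + self.gradient_per_cm * y_eff

    def _weight_antiderivative(self, y: np.ndarray) -> np.ndarray:
        yp = self.y_plateau
        y = np.asarray(y, dtype=float)
        ramp = self.w0 * y + 0.5 * self.gradient_per_cm * y**2
        plateau_w = self.w0 + self.gradient_per_cm * yp
        at_yp = self.w0 * yp + 0.5 * self.gradient_per_cm * yp**2
        return np.where(y <= yp, ramp, at_yp + plateau_w * (y - yp))

    def weight_integral(self, y_lo: np.ndarray, y_hi: np.ndarray) -> np.ndarray:
        """Exact integral of w over [y_lo, y_hi] (piecewise polynomial).

        Intervals lying entirely in the plateau are handled directly so the
        integral is exactly invariant to translation there.
        """
        y_lo = np.asarray(y_lo, dtype=float)
        y_hi = np.asarray(y_hi, dtype=float)
        yp = self.y_plateau
        plateau_w = self.w0 + self.gradient_per_cm * yp
        general = self._weight_antiderivative(y_hi) - self._weight_antiderivative(y_lo)
        return np.where(y_lo >= yp, plateau_w * (y_hi - y_lo), general)


@dataclass(frozen=True)
class SignalRecord:
    """One scored trial: aperture identity, area and chamber signal."""

    segment: str
    level_mm: float
    trial_index: int
    area_cm2: float
    signal: float
    offset_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("signal must be non-negative")


def signal(
    chamber: ChamberModel,
    segment: Segment,
    offset_cm: float = 0.0,
    noise: NoiseModel | None = None,
) -> float:
    """Chamber signal for an aperture displaced by ``offset_cm`` along the gradient.

    Noise-free value: sum over leaf pairs of (open gap) x integral of w(y)
    over the pair's gradient-axis strip.  Exact for the piecewise-linear w.
    With ``noise``, the value is multiplied by one draw of N(1, relative_sigma).
    """
    n = segment.n_pairs
    if n:
        lo0, _ = segment.pair_span_cm(0)
        _, hi_last = segment.pair_span_cm(n - 1)
        y_lo = lo0 + offset_cm
        y_hi = hi_last + offset_cm
        if y_lo < -chamber.half_span - 1e-9 or y_hi > chamber.half_span + 1e-9:
            raise ApertureOutsideChamberError(
                f"aperture spans [{y_lo:.3f}, {y_hi:.3f}] cm along the gradient axis "
                f"but the chamber covers +/-{chamber.half_span:g} cm"
            )
    gaps = np.array([r - l for l, r in segment.leaf_pairs])
    spans = np.array([segment.pair_span_cm(i) for i in range(n)]).reshape(n, 2)
    integrals = chamber.weight_integral(spans[:, 0] + offset_cm, spans[:, 1] + offset_cm)
    value = float(np.dot(gaps, integrals)) if n else 0.0
    if noise is not None and noise.relative_sigma > 0:
        value *= noise.factor()
    return max(value, 0.0)


def relative_signal(
    chamber: ChamberModel,
    altered: Segment,
    reference: Segment,
    offset_cm: float = 0.0,
    noise: NoiseModel | None = None,
    reference_signal: float | None = None,
) -> float:
    """Signal of ``altered`` normalized to the reference (unaltered) aperture.

    The reference signal may be supplied to reuse one noisy reference score
    across a batch of trials; otherwise it is computed here (noise-free).
    Equals 1 exactly for altered == reference in the noise-free case.
    """
    if reference_signal is None:
        reference_signal = signal(chamber, reference, offset_cm, noise=None)
    if reference_signal <= 0:
        raise ValueError("reference signal must be positive")
    return signal(chamber, altered, offset_cm, noise=noise) / reference_signal


def gradient_profile(
    chamber: ChamberModel,
    segment: Segment,
    offsets_cm: Sequence[float],
    noise: NoiseModel | None = None,
) -> list[tuple[float, float]]:
    """Signal versus displacement along the gradient axis.

    Noise-free, the profile is non-decreasing along +Y and constant once the
    whole aperture sits inside the plateau region.
    """
    return [(float(off), signal(chamber, segment, off, noise=noise)) for off in offsets_cm]
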