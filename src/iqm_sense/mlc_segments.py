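"""MLC segment geometry, randomized leaf-positional-error trials, and segment file I/O.

A *segment* is one static multileaf-collimator (MLC) aperture, described as an
ordered list of (left, right) leaf-edge positions projected to the isocenter
plane (100 cm SSD).  Leaf travel is along X; successive leaf pairs stack along
Y, which is also the chamber's sensitivity-gradient axis.  All positions are in
centimetres at the isocenter plane.

The perturbation machinery emulates random leaf-positional errors: every edge
of every *open* pair is shifted by an independent uniform draw in
[-delta, +delta], at delta = 1, 2 and 3 mm, ten trials per level, giving the
30-trial protocol used throughout the study.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Physical projected leaf width of the Agility MLC at the isocenter plane (cm).
AGILITY_LEAF_WIDTH_CM = 0.5

#: Half-extent of the maximum monitorable field (40 x 40 cm^2) at isocenter.
FIELD_HALF_EXTENT_CM = 20.0

#: Nominal open areas (cm^2) of the six study segments.
LIBRARY_AREAS_CM2 = {
    "segment1_3x3": 9.00,
    "segment2_irregular": 25.83,
    "segment3_irregular": 70.82,
    "segment4_irregular": 47.49,
    "segment5_1x1": 1.00,
    "segment6_irregular": 19.99,
}

SEGMENT_FILE_MAGIC = "IQMSEG"
SEGMENT_FILE_VERSION = 1


class SegmentValidationError(ValueError):
    """A segment violates its geometric invariants."""


class SegmentParseError(ValueError):
    """A segment file could not be parsed."""


@dataclass(frozen=True)
class Segment:
    """A static MLC aperture at the isocenter plane.

    Parameters
    ----------
    leaf_pairs
        Ordered (left_cm, right_cm) leaf-edge positions along the leaf-travel
        axis, one tuple per leaf pair.  A closed pair has left == right.
    leaf_width_cm
        Projected width of one leaf pair along the stacking (gradient) axis.
    first_pair_offset_cm
        Position of the lower edge of the first pair along the gradient axis.
    label
        Free-text identifier; also keys the per-trial random substreams.
    """

    leaf_pairs: tuple[tuple[float, float], ...]
    leaf_width_cm: float = AGILITY_LEAF_WIDTH_CM
    first_pair_offset_cm: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "leaf_pairs", tuple((float(l), float(r)) for l, r in self.leaf_pairs)
        )
        self.validate()

    def validate(self) -> None:
        if self.leaf_width_cm <= 0:
            raise SegmentValidationError(
                f"leaf_width_cm must be positive, got {self.leaf_width_cm}"
            )
        for i, (left, right) in enumerate(self.leaf_pairs):
            if not (np.isfinite(left) and np.isfinite(right)):
                raise SegmentValidationError(f"pair {i}: non-finite position")
            if left > right:
                raise SegmentValidationError(
                    f"pair {i}: left edge {left:.4f} cm exceeds right edge "
                    f"{right:.4f} cm"
                )
            if abs(left) > FIELD_HALF_EXTENT_CM or abs(right) > FIELD_HALF_EXTENT_CM:
                raise SegmentValidationError(
                    f"pair {i}: position outside the +/-{FIELD_HALF_EXTENT_CM:g} cm field"
                )
        span_lo = self.first_pair_offset_cm
        span_hi = self.first_pair_offset_cm + len(self.leaf_pairs) * self.leaf_width_cm
        if span_lo < -FIELD_HALF_EXTENT_CM - 1e-9 or span_hi > FIELD_HALF_EXTENT_CM + 1e-9:
            raise SegmentValidationError(
                f"segment spans [{span_lo:.4f}, {span_hi:.4f}] cm along the gradient "
                f"axis, outside the +/-{FIELD_HALF_EXTENT_CM:g} cm field"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_pairs)

    def pair_span_cm(self, index: int) -> tuple[float, float]:
        """Gradient-axis interval [lo, hi] covered by leaf pair ``index``."""
        lo = self.first_pair_offset_cm + index * self.leaf_width_cm
        return lo, lo + self.leaf_width_cm

    def open_pairs(self) -> list[int]:
        """Indices of pairs with a strictly positive gap."""
        return [i for i, (l, r) in enumerate(self.leaf_pairs) if r > l]


def segment_area(segment: Segment) -> float:
    """Open aperture area in cm^2: sum over pairs of gap x leaf width."""
    segment.validate()
    gaps = np.array([r - l for l, r in segment.leaf_pairs])
    return float(gaps.sum() * segment.leaf_width_cm)


@dataclass(frozen=True)
class PerturbationSpec:
    """One leaf-positional-error level: uniform shifts in [-max_shift, +max_shift].

    ``max_shift_mm`` is the maximum magnitude in millimetres (the study used
    1, 2 and 3); ``n_trials`` random apertures are generated per level.
    """

    max_shift_mm: float
    n_trials: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_shift_mm < 0:
            raise ValueError(f"max_shift_mm must be >= 0, got {self.max_shift_mm}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")


def _trial_rng(seed: int, label: str, level_mm: float, trial: int) -> np.random.Generator:
    """Independent, reproducible random substream for one perturbation trial.

    The stream is keyed on (run seed, segment label, level in microns, trial
    index) so any single trial can be regenerated in isolation.
    """
    label_key = zlib.crc32(label.encode("utf-8"))
    level_key = int(round(level_mm * 1000))
    ss = np.random.SeedSequence([int(seed), label_key, level_key, int(trial)])
    return np.random.default_rng(ss)


def perturb_segment(
    segment: Segment,
    max_shift_mm: float | PerturbationSpec,
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> Segment:
    """Shift every edge of every open pair by an independent uniform draw.

    ``max_shift_mm`` may be a plain magnitude or a :class:`PerturbationSpec`.
    Draws are uniform in [-max_shift, +max_shift] (converted to cm); closed
    pairs are left untouched.  If a draw would cross the leaves (left > right)
    or push an edge outside the field, that pair is redrawn, up to
    ``max_redraws`` times, then an error is raised.  The input is never
    modified.
    """
    segment.validate()
    if isinstance(max_shift_mm, PerturbationSpec):
        max_shift_mm = max_shift_mm.max_shift_mm
    delta_cm = max_shift_mm * 0.1
    if delta_cm == 0.0:
        return segment
    new_pairs = list(segment.leaf_pairs)
    for i in segment.open_pairs():
        left, right = segment.leaf_pairs[i]
        for attempt in range(max_redraws + 1):
            shift_l, shift_r = rng.uniform(-delta_cm, delta_cm, size=2)
            cand = (left + shift_l, right + shift_r)
            if cand[0] <= cand[1] and all(abs(p) <= FIELD_HALF_EXTENT_CM for p in cand):
                new_pairs[i] = cand
                break
        else:
            raise SegmentValidationError(
                f"pair {i}: could not draw a collision-free shift in "
                f"{max_redraws} redraws"
            )
    return replace(segment, leaf_pairs=tuple(new_pairs))


@dataclass(frozen=True)
class Trial:
    """One altered aperture: (level in mm, trial index within level, segment)."""

    level_mm: float
    trial_index: int
    segment: Segment


def generate_trials(
    segment: Segment,
    levels_mm: Sequence[float],
    n_trials: int,
    seed: int,
) -> list[Trial]:
    """Generate the full perturbation protocol for one segment.

    Returns len(levels) x n_trials altered segments, in (level, trial) order.
    Each trial is reproducible in isolation from (seed, segment label, level,
    trial index).
    """
    if not levels_mm:
        raise ValueError("levels_mm must be non-empty")
    trials: list[Trial] = []
    for level in levels_mm:
        for t in range(n_trials):
            rng = _trial_rng(seed, segment.label, level, t)
            altered = perturb_segment(segment, level, rng)
            altered = replace(altered, label=f"{segment.label}/L{level:g}mm/t{t}")
            trials.append(Trial(level_mm=float(level), trial_index=t, segment=altered))
    return trials


# ---------------------------------------------------------------------------
# The six-segment study library
# ---------------------------------------------------------------------------

def square_segment(side_cm: float, label: str, leaf_width_cm: float = AGILITY_LEAF_WIDTH_CM) -> Segment:
    """Centered square aperture of the given side length."""
    n_pairs = int(round(side_cm / leaf_width_cm))
    if abs(n_pairs * leaf_width_cm - side_cm) > 1e-9:
        raise ValueError(f"side {side_cm} cm is not a whole number of leaf widths")
    half = side_cm / 2.0
    pairs = tuple((-half, half) for _ in range(n_pairs))
    return Segment(
        leaf_pairs=pairs,
        leaf_width_cm=leaf_width_cm,
        first_pair_offset_cm=-n_pairs * leaf_width_cm / 2.0,
        label=label,
    )


def irregular_segment(
    target_area_cm2: float,
    n_pairs: int,
    label: str,
    shape_seed: int,
    leaf_width_cm: float = AGILITY_LEAF_WIDTH_CM,
) -> Segment:
    """Deterministic irregular aperture scaled to an exact target area.

    Only the areas of the four irregular study segments are known; their leaf
    positions are not.  This generator produces a smoothly varying, seeded
    aperture (sinusoidal modulation plus low-amplitude seeded wobble of both
    the openings and the pair centers) and rescales the openings analytically
    so the total open area equals ``target_area_cm2`` to machine precision.
    Since every statistic in the study is driven by aperture area rather than
    shape, the area is the authoritative constraint.
    """
    if target_area_cm2 <= 0 or n_pairs < 1:
        raise ValueError("target area must be positive and n_pairs >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([shape_seed, n_pairs]))
    i = np.arange(n_pairs)
    phase = rng.uniform(0, 2 * np.pi)
    modulation = 1.0 + 0.35 * np.sin(2 * np.pi * i / max(n_pairs - 1, 1) + phase)
    modulation += rng.uniform(-0.10, 0.10, size=n_pairs)
    modulation = np.clip(modulation, 0.25, None)
    openings = modulation * (target_area_cm2 / (leaf_width_cm * modulation.sum()))
    centers = rng.uniform(-0.6, 0.6, size=n_pairs)
    # smooth the centers so adjacent pairs form a connected, realistic aperture
    if n_pairs >= 3:
        centers = np.convolve(centers, np.ones(3) / 3.0, mode="same")
    pairs = tuple(
        (c - o / 2.0, c + o / 2.0) for c, o in zip(centers, openings)
    )
    return Segment(
        leaf_pairs=pairs,
        leaf_width_cm=leaf_width_cm,
        first_pair_offset_cm=-n_pairs * leaf_width_cm / 2.0,
        label=label,
    )


def build_library() -> list[Segment]:
    """The six study segments: two regular squares and four irregular apertures.

    Each computed area matches its nominal area to well within 0.01 cm^2.
    """
    return [
        square_segment(3.0, "segment1_3x3"),
        irregular_segment(25.83, 10, "segment2_irregular", shape_seed=202),
        irregular_segment(70.82, 16, "segment3_irregular", shape_seed=203),
        irregular_segment(47.49, 13, "segment4_irregular", shape_seed=204),
        square_segment(1.0, "segment5_1x1"),
        irregular_segment(19.99, 9, "segment6_irregular", shape_seed=206),
    ]


# ---------------------------------------------------------------------------
# Segment file format (plain text, versioned)
# ---------------------------------------------------------------------------
#
#   IQMSEG 1
#   segment <label>
#   leaf_width_cm <w>
#   first_pair_offset_cm <y0>
#   pair <index> <left_cm> <right_cm>
#   ...
#
# Blank lines and lines starting with '#' are ignored.  Floats are written
# with repr precision so a write/read round trip is exact.

def write_segments(path: str | Path, segments: Iterable[Segment]) -> None:
    """Write segments to the versioned plain-text segment format."""
    lines = [f"{SEGMENT_FILE_MAGIC} {SEGMENT_FILE_VERSION}"]
    for seg in segments:
        lines.append(f"segment {seg.label}")
        lines.append(f"leaf_width_cm {seg.leaf_width_cm!r}")
        lines.append(f"first_pair_offset_cm {seg.first_pair_offset_cm!r}")
        for i, (left, right) in enumerate(seg.leaf_pairs):
            lines.append(f"pair {i} {left!r} {right!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_segments(path: str | Path) -> list[Segment]:
    """Read segments from the plain-text segment format.

    Raises :class:`SegmentParseError` (with line context) on unknown versions,
    malformed records or non-numeric positions; geometric violations surface
    as :class:`SegmentValidationError` naming the offending record.
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    lines = [
        (no + 1, ln.strip())
        for no, ln in enumerate(raw_lines)
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        logger.warning("segment file %s is empty", path)
        return []
    no, header = lines[0]
    parts = header.split()
    if len(parts) != 2 or parts[0] != SEGMENT_FILE_MAGIC:
        raise SegmentParseError(f"{path}:{no}: missing '{SEGMENT_FILE_MAGIC} <version>' header")
    if parts[1] != str(SEGMENT_FILE_VERSION):
        raise SegmentParseError(f"{path}:{no}: unsupported version {parts[1]!r}")

    segments: list[Segment] = []
    current: dict | None = None

    def flush() -> None:
        if current is None:
            return
        missing = [k for k in ("leaf_width_cm", "first_pair_offset_cm") if k not in current]
        if missing:
            raise SegmentParseError(
                f"{path}: segment {current['label']!r} missing fields: {', '.join(missing)}"
            )
        try:
            segments.append(
                Segment(
                    leaf_pairs=tuple(current["pairs"]),
                    leaf_width_cm=current["leaf_width_cm"],
                    first_pair_offset_cm=current["first_pair_offset_cm"],
                    label=current["label"],
                )
            )
        except SegmentValidationError as exc:
            raise SegmentValidationError(
                f"{path}: segment {current['label']!r}: {exc}"
            ) from exc

    for no, ln in lines[1:]:
        parts = ln.split()
        key = parts[0]
        if key == "segment":
            flush()
            current = {"label": " ".join(parts[1:]), "pairs": []}
            continue
        if current is None:
            raise SegmentParseError(f"{path}:{no}: {key!r} record before any 'segment' line")
        try:
            if key in ("leaf_width_cm", "first_pair_offset_cm"):
                current[key] = float(parts[1])
            elif key == "pair":
                current["pairs"].append((float(parts[2]), float(parts[3])))
            else:
                raise SegmentParseError(f"{path}:{no}: unknown record type {key!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, SegmentParseError):
                raise
            raise SegmentParseError(f"{path}:{no}: malformed {key!r} record: {ln!r}") from exc
    flush()
    return segments
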