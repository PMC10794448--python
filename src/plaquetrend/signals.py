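"""Longitudinal signals along an IVUS pullback.

Frame-wise features sampled at the (unevenly spaced) annotated frames are
linearly interpolated onto a uniform axial grid of 60 frames/mm, baseline
and follow-up pullbacks are co-registered by an integer grid shift, and
first derivatives are taken by central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import AlignmentError, NoOverlapError, TooFewSamplesError

__all__ = [
    "GRID_SPACING_MM",
    "LongitudinalSignal",
    "RegistrationResult",
    "interpolate_uniform",
    "coregister",
    "derivative",
    "moving_average",
]

#: Uniform interpolated frame spacing: 60 frames per mm.
GRID_SPACING_MM = 1.0 / 60.0


@dataclass(frozen=True)
class LongitudinalSignal:
    """One frame-wise feature sampled on the uniform interpolated grid."""

    values: np.ndarray
    origin_mm: float
    name: str
    grid_spacing: float = GRID_SPACING_MM

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise TooFewSamplesError("a longitudinal signal needs at least 2 grid values")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in signal {self.name!r}")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def positions_mm(self) -> np.ndarray:
        return self.origin_mm + self.grid_spacing * np.arange(len(self))

    def slice(self, start: int, end: int) -> "LongitudinalSignal":
        """Restrict to the half-open interpolated-frame interval [start, end)."""
        if not (0 <= start < end <= len(self)):
            raise AlignmentError(f"slice [{start},{end}) outside signal of length {len(self)}")
        return replace(
            self,
            values=self.values[start:end].copy(),
            origin_mm=self.origin_mm + start * self.grid_spacing,
        )


@dataclass(frozen=True)
class RegistrationResult:
    """Integer shift aligning FU onto BL, with retained equal-length ranges.

    ``shift_frames`` is the number of frames the FU signal lags behind BL:
    a FU copy of BL delayed by 30 frames registers with shift +30.  Aligned
    samples pair ``bl[i]`` with ``fu[i + shift]``.
    """

    shift_frames: int
    bl_range: tuple
    fu_range: tuple
    score: float

    def apply(self, bl: LongitudinalSignal, fu: LongitudinalSignal):
        return bl.slice(*self.bl_range), fu.slice(*self.fu_range)


def interpolate_uniform(
    positions_mm,
    values,
    name: str = "f",
    grid_spacing: float = GRID_SPACING_MM,
) -> LongitudinalSignal:
    """Linearly interpolate irregular samples onto the uniform grid.

    The grid starts at the first sample position and never extends past the
    last sample (no extrapolation).
    """
    pos = np.asarray(positions_mm, dtype=float)
    val = np.asarray(values, dtype=float)
    if pos.size != val.size:
        raise AlignmentError("positions and values differ in length")
    if pos.size < 2:
        raise TooFewSamplesError("interpolation needs at least 2 samples")
    if np.any(np.diff(pos) <= 0):
        raise AlignmentError("sample positions must be strictly increasing")
    n = int(np.floor((pos[-1] - pos[0]) / grid_spacing + 1e-9)) + 1
    grid = pos[0] + grid_spacing * np.arange(n)
    return LongitudinalSignal(np.interp(grid, pos, val), float(pos[0]), name, grid_spacing)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa < 1e-15 or sb < 1e-15:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def coregister(
    bl: dict,
    fu: dict,
    manual_shift: int | None = None,
    min_overlap: int = 300,
    max_shift: int | None = None,
) -> RegistrationResult:
    """Align FU onto BL by an integer frame shift.

    ``bl`` and ``fu`` map the registration feature names (plaque burden and
    vessel area, by convention ``"pb"`` and ``"vessel_area"``) to
    :class:`LongitudinalSignal`.  Unless ``manual_shift`` is given, the shift
    maximizing the mean Pearson correlation of the two features over the
    overlap is chosen among shifts leaving at least ``min_overlap`` frames
    (300 frames = 5 mm by default); ties go to the smallest |shift|.  Tails
    outside the overlap are clipped.
    """
    keys = sorted(bl)
    if sorted(fu) != keys or not keys:
        raise AlignmentError("BL and FU must provide the same registration features")
    n_bl = len(next(iter(bl.values())))
    n_fu = len(next(iter(fu.values())))
    if any(len(s) != n_bl for s in bl.values()) or any(len(s) != n_fu for s in fu.values()):
        raise AlignmentError("registration signals must share a common grid per phase")

    def _ranges(shift: int):
        # bl[i] pairs fu[i + shift]
        lo = max(0, -shift)
        hi = min(n_bl, n_fu - shift)
        return lo, hi

    if manual_shift is not None:
        lo, hi = _ranges(manual_shift)
        if hi - lo < 2:
            raise NoOverlapError(f"manual shift {manual_shift} leaves no overlap")
        score = np.mean(
            [
                _pearson(
                    bl[k].values[lo:hi], fu[k].values[lo + manual_shift : hi + manual_shift]
                )
                for k in keys
            ]
        )
        return RegistrationResult(
            manual_shift, (lo, hi), (lo + manual_shift, hi + manual_shift), float(score)
        )

    max_shift_pos = n_bl - min_overlap
    max_shift_neg = n_fu - min_overlap
    if max_shift is not None:
        max_shift_pos = min(max_shift_pos, max_shift)
        max_shift_neg = min(max_shift_neg, max_shift)
    if max_shift_pos < 0 or max_shift_neg < 0:
        raise NoOverlapError(
            f"signals shorter than the minimum overlap of {min_overlap} frames"
        )
    candidates = sorted(range(-max_shift_pos, max_shift_neg + 1), key=lambda s: (abs(s), s))
    best = None
    for s in candidates:
        lo, hi = _ranges(s)
        if hi - lo < min_overlap:
            continue
        score = float(
            np.mean([_pearson(bl[k].values[lo:hi], fu[k].values[lo + s : hi + s]) for k in keys])
        )
        if best is None or score > best[0] + 1e-12:
            best = (score, s, lo, hi)
    if best is None:
        raise NoOverlapError("no admissible shift leaves the minimum overlap")
    score, s, lo, hi = best
    return RegistrationResult(s, (lo, hi), (lo + s, hi + s), score)


def derivative(signal: LongitudinalSignal) -> LongitudinalSignal:
    """First derivative by central differences (one-sided at the endpoints)."""
    v = signal.values
    if v.size < 3:
        raise TooFewSamplesError("derivative needs at least 3 samples")
    h = signal.grid_spacing
    out = np.empty_like(v)
    out[1:-1] = (v[2:] - v[:-2]) / (2.0 * h)
    out[0] = (v[1] - v[0]) / h
    out[-1] = (v[-1] - v[-2]) / h
    return replace(signal, values=out, name=f"d_{signal.name}")


def moving_average(signal: LongitudinalSignal, window: int) -> LongitudinalSignal:
    """Optional centered moving-average smoothing (off by default in the pipeline)."""
    if window <= 1:
        return signal
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(signal.values, pad, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="same")[pad : pad + len(signal)]
    return replace(signal, values=smoothed)
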