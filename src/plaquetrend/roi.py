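"""Partition co-registered pullbacks into regions of interest (ROIs).

Six criteria are supported:

- ``FP``      — the full pullback, one ROI.
- ``ChPAV``   — maximal runs of constant sign of PB_FU − PB_BL; runs whose
  peak |difference| is below 0.5 % and runs shorter than 15 interpolated
  frames (0.25 mm) are discarded.  Uses follow-up data, so it is an oracle
  partition, not a clinically applicable one.
- ``PBR``     — baseline plaque burden binned into [0,30), [30,60), [60,100];
  maximal constant-bin runs, short runs discarded as above.
- ``W30O10``, ``W60O20``, ``W120O20`` — fixed windows of 30/60/120 frames
  tiled at stride = window size, repeated at several start offsets and
  pooled.

Each ROI's regression target is the change in percent atheroma volume
ΔPAV = PAV_FU − PAV_BL, with PAV = 100·TAV/TVV and the volumes obtained by
trapezoidal integration of the area signals over the ROI.  With the
threshold ε = 0, ΔPAV > 0 is plaque progression and ΔPAV ≤ 0 regression
(the measure-zero tie is assigned to regression so the two classes
partition outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ConfigError, InvalidSignalError
from .signals import GRID_SPACING_MM, LongitudinalSignal

__all__ = [
    "ROI",
    "ROITarget",
    "CRITERIA",
    "WINDOW_SPECS",
    "MIN_ROI_FRAMES",
    "partition_fp",
    "partition_chpav",
    "partition_pbr",
    "partition_windows",
    "partition",
    "roi_target",
]

CRITERIA = ("FP", "ChPAV", "PBR", "W30O10", "W60O20", "W120O20")

#: window length (frames) and start offsets per windowed criterion
WINDOW_SPECS = {
    "W30O10": (30, (0, 10, 20)),
    "W60O20": (60, (0, 20, 40)),
    "W120O20": (120, (0, 20, 40, 60, 80, 100)),
}

#: runs shorter than 15 interpolated frames (0.25 mm) are discarded
MIN_ROI_FRAMES = 15

#: ChPAV runs whose peak |PB_FU − PB_BL| is below this (%) are discarded
CHPAV_MIN_DELTA = 0.5


@dataclass(frozen=True)
class ROI:
    """Half-open interpolated-frame interval on a pullback."""

    pullback_id: str
    criterion: str
    start: int
    end: int
    offset_id: int | None = None
    label: str | None = None  # criterion-specific tag (sign or PB bin)

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ConfigError(f"unknown ROI criterion {self.criterion!r}")
        if self.end <= self.start:
            raise ConfigError("ROI must have positive length")

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    @property
    def length_mm(self) -> float:
        return self.n_frames * GRID_SPACING_MM


@dataclass(frozen=True)
class ROITarget:
    """Per-phase volumes, PAV and the ΔPAV regression/classification target."""

    tlv_bl: float
    tvv_bl: float
    tav_bl: float
    tlv_fu: float
    tvv_fu: float
    tav_fu: float
    pav_bl: float
    pav_fu: float
    dpav: float

    @property
    def progression(self) -> bool:
        return self.dpav > 0.0

    @property
    def cls(self) -> str:
        return "progression" if self.progression else "regression"


def partition_fp(pullback_id: str, n_frames: int) -> list:
    """Single ROI spanning the whole pullback."""
    if n_frames < MIN_ROI_FRAMES:
        raise ConfigError(f"pullback of {n_frames} frames is shorter than {MIN_ROI_FRAMES}")
    return [ROI(pullback_id, "FP", 0, n_frames)]


def _runs(labels: np.ndarray) -> list:
    """Maximal runs of constant value: list of (start, end, value)."""
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    return [(int(bounds[i]), int(bounds[i + 1]), labels[bounds[i]]) for i in range(len(bounds) - 1)]


def partition_chpav(
    pullback_id: str,
    pb_bl: LongitudinalSignal,
    pb_fu: LongitudinalSignal,
    min_frames: int = MIN_ROI_FRAMES,
    min_delta: float = CHPAV_MIN_DELTA,
    amplitude_mode: str = "max",
) -> list:
    """Sign-pure runs of the plaque-burden change PB_FU − PB_BL.

    Frames where the difference is exactly zero belong to no run.  Runs
    shorter than ``min_frames`` are discarded, as are runs whose peak
    (or mean, with ``amplitude_mode="mean"``) |difference| is below
    ``min_delta`` percent.
    """
    if len(pb_bl) != len(pb_fu):
        raise AlignmentError("BL and FU plaque-burden signals must be aligned")
    d = pb_fu.values - pb_bl.values
    sign = np.sign(d).astype(int)
    rois = []
    for start, end, value in _runs(sign):
        if value == 0 or end - start < min_frames:
            continue
        seg = np.abs(d[start:end])
        amplitude = float(seg.mean() if amplitude_mode == "mean" else seg.max())
        if amplitude < min_delta:
            continue
        rois.append(
            ROI(pullback_id, "ChPAV", start, end, label="+" if value > 0 else "-")
        )
    return rois


def partition_pbr(
    pullback_id: str,
    pb_bl: LongitudinalSignal,
    min_frames: int = MIN_ROI_FRAMES,
) -> list:
    """Runs of constant baseline plaque-burden bin: [0,30), [30,60), [60,100]."""
    pb = pb_bl.values
    if np.any(pb < 0.0) or np.any(pb > 100.0):
        raise InvalidSignalError("plaque burden outside [0, 100]")
    bins = np.digitize(pb, [30.0, 60.0])  # 0: [0,30), 1: [30,60), 2: [60,100]
    names = {0: "low", 1: "mid", 2: "high"}
    return [
        ROI(pullback_id, "PBR", start, end, label=names[int(value)])
        for start, end, value in _runs(bins)
        if end - start >= min_frames
    ]


def partition_windows(
    pullback_id: str,
    n_frames: int,
    criterion: str,
    window: int | None = None,
    offsets=None,
) -> list:
    """Fixed windows tiled at stride = window size, pooled over start offsets.

    Trailing partial windows are dropped (the fixed window size is
    definitional).  ROIs from different offsets overlap by construction and
    are tagged with ``offset_id``.
    """
    if criterion in WINDOW_SPECS:
        default_window, default_offsets = WINDOW_SPECS[criterion]
        window = default_window if window is None else window
        offsets = default_offsets if offsets is None else offsets
    elif window is None or offsets is None:
        raise ConfigError(f"criterion {criterion!r} needs explicit window and offsets")
    if window <= 0:
        raise ConfigError("window must be positive")
    rois = []
    for offset_id, offset in enumerate(offsets):
        for start in range(offset, n_frames - window + 1, window):
            rois.append(ROI(pullback_id, criterion, start, start + window, offset_id=offset_id))
    return rois


def partition(
    pullback_id: str,
    criterion: str,
    n_frames: int,
    pb_bl: LongitudinalSignal | None = None,
    pb_fu: LongitudinalSignal | None = None,
) -> list:
    """Dispatch to the requested partition criterion."""
    if criterion == "FP":
        return partition_fp(pullback_id, n_frames)
    if criterion == "ChPAV":
        if pb_bl is None or pb_fu is None:
            raise ConfigError("ChPAV needs aligned BL and FU plaque-burden signals")
        return partition_chpav(pullback_id, pb_bl, pb_fu)
    if criterion == "PBR":
        if pb_bl is None:
            raise ConfigError("PBR needs the BL plaque-burden signal")
        return partition_pbr(pullback_id, pb_bl)
    if criterion in WINDOW_SPECS:
        return partition_windows(pullback_id, n_frames, criterion)
    raise ConfigError(f"unknown ROI criterion {criterion!r}")


def _integrate(values: np.ndarray, start: int, end: int, spacing: float) -> float:
    # integrate over the continuous interval [start, end); the boundary sample
    # at `end` is included when it exists so disjoint exhaustive partitions
    # conserve the full-pullback integral exactly
    stop = min(end, values.size - 1)
    return float(np.trapezoid(values[start : stop + 1], dx=spacing))


def roi_target(
    roi: ROI,
    areas_bl: dict,
    areas_fu: dict,
) -> ROITarget:
    """Volumes, PAV per phase and ΔPAV for one ROI.

    ``areas_bl``/``areas_fu`` map ``"lumen_area"``, ``"vessel_area"`` and
    ``"plaque_area"`` to aligned :class:`LongitudinalSignal` covering the ROI.
    """
    for areas in (areas_bl, areas_fu):
        n = len(areas["vessel_area"])
        if roi.start < 0 or roi.end > n:
            raise AlignmentError(f"ROI [{roi.start},{roi.end}) outside signal support [0,{n})")
    h = areas_bl["vessel_area"].grid_spacing
    vols = {}
    for phase, areas in (("bl", areas_bl), ("fu", areas_fu)):
        vols[f"tlv_{phase}"] = _integrate(areas["lumen_area"].values, roi.start, roi.end, h)
        vols[f"tvv_{phase}"] = _integrate(areas["vessel_area"].values, roi.start, roi.end, h)
        vols[f"tav_{phase}"] = _integrate(areas["plaque_area"].values, roi.start, roi.end, h)
    pav_bl = 100.0 * vols["tav_bl"] / vols["tvv_bl"]
    pav_fu = 100.0 * vols["tav_fu"] / vols["tvv_fu"]
    return ROITarget(pav_bl=pav_bl, pav_fu=pav_fu, dpav=pav_fu - pav_bl, **vols)
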