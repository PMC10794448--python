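"""End-to-end orchestration: contours → signals → ROIs → feature dataset.

For one pullback the stages are: compute the 18 frame-wise descriptors at
every annotated frame of each phase, interpolate them onto the uniform
60 frames/mm grid, co-register baseline and follow-up on the plaque-burden
and vessel-area signals, differentiate, partition the aligned region into
ROIs under the chosen criterion, and condense each ROI into its feature
vector with its ΔPAV target.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .condense import assemble_features
from .errors import DataError
from .geometry import compute_frame_features
from .roi import MIN_ROI_FRAMES, partition, roi_target
from .signals import LongitudinalSignal, coregister, derivative, interpolate_uniform
from .synthetic import PullbackRecord, SyntheticCohort

__all__ = [
    "AREA_FEATURES",
    "AlignedPullback",
    "frame_feature_table",
    "pullback_signals",
    "align_phases",
    "build_dataset",
]

AREA_FEATURES = ("lumen_area", "vessel_area", "plaque_area", "pb")


@dataclass
class AlignedPullback:
    """Co-registered signals of one pullback on a common grid."""

    pullback_id: str
    shift_frames: int
    bl: dict  # 36 aligned BL signals (features + derivatives)
    fu_areas: dict  # aligned FU area signals (for targets and ChPAV)
    fu_pb: LongitudinalSignal
    n_frames: int


def frame_feature_table(record: PullbackRecord, phase: str, anchor=(0.0, 0.0)) -> pd.DataFrame:
    """Frame-wise features at the annotated frames of one phase.

    Uses rendered contours when present, otherwise falls back to the
    generator's truth areas (area features only).
    """
    contours = record.contours_bl if phase == "BL" else record.contours_fu
    positions = record.positions_bl if phase == "BL" else record.positions_fu
    if contours is not None:
        rows = [
            compute_frame_features(lumen, vessel, anchor).as_dict()
            for lumen, vessel in contours
        ]
        df = pd.DataFrame(rows)
    else:
        suffix = "bl" if phase == "BL" else "fu"
        la = getattr(record, f"true_lumen_area_{suffix}")
        va = getattr(record, f"true_vessel_area_{suffix}")
        df = pd.DataFrame(
            {
                "lumen_area": la,
                "vessel_area": va,
                "plaque_area": va - la,
                "pb": 100.0 * (va - la) / va,
            }
        )
    df.insert(0, "position_mm", positions)
    return df


def pullback_signals(record: PullbackRecord, phase: str, anchor=(0.0, 0.0)) -> dict:
    """Interpolate every frame-wise feature of one phase onto the uniform grid."""
    table = frame_feature_table(record, phase, anchor)
    pos = table["position_mm"].to_numpy()
    return {
        name: interpolate_uniform(pos, table[name].to_numpy(), name=name)
        for name in table.columns
        if name != "position_mm"
    }


def align_phases(
    bl_signals: dict,
    fu_signals: dict,
    manual_shift: int | None = None,
    min_overlap: int = 300,
    max_shift: int | None = None,
    pullback_id: str = "",
) -> AlignedPullback:
    """Co-register the phases on (PB, vessel area), slice all signals to the
    overlap and append first derivatives of every BL feature signal."""
    reg = coregister(
        {k: bl_signals[k] for k in ("pb", "vessel_area")},
        {k: fu_signals[k] for k in ("pb", "vessel_area")},
        manual_shift=manual_shift,
        min_overlap=min_overlap,
        max_shift=max_shift,
    )
    bl = {name: sig.slice(*reg.bl_range) for name, sig in bl_signals.items()}
    fu_areas = {
        name: fu_signals[name].slice(*reg.fu_range) for name in AREA_FEATURES
    }
    for name in list(bl):
        bl[f"d_{name}"] = derivative(bl[name])
    return AlignedPullback(
        pullback_id=pullback_id,
        shift_frames=reg.shift_frames,
        bl=bl,
        fu_areas=fu_areas,
        fu_pb=fu_areas["pb"],
        n_frames=len(fu_areas["pb"]),
    )


def _area_signals(signals: dict) -> dict:
    return {k: signals[k] for k in ("lumen_area", "vessel_area", "plaque_area")}


def build_dataset(
    cohort: SyntheticCohort,
    criterion: str,
    set_id: str = "Sd",
    anchor=(0.0, 0.0),
    min_overlap: int = 300,
    max_shift: int | None = None,
) -> tuple:
    """Assemble the ROI feature matrix and metadata table for one criterion.

    Returns ``(features, meta)``: one row per ROI.  ``meta`` carries the
    pullback and patient identifiers, artery, ROI bounds and length, the
    ΔPAV target and class, and the pullback-level ΔPAV used for fold
    stratification.  Pullbacks whose aligned overlap is shorter than the
    minimum ROI length are skipped.
    """
    feature_rows = []
    meta_rows = []
    for record in cohort.pullbacks:
        bl_sig = pullback_signals(record, "BL", anchor)
        fu_sig = pullback_signals(record, "FU", anchor)
        aligned = align_phases(
            bl_sig,
            fu_sig,
            min_overlap=min_overlap,
            max_shift=max_shift,
            pullback_id=record.pullback_id,
        )
        if aligned.n_frames < MIN_ROI_FRAMES:
            continue
        clinical = cohort.clinical.loc[record.patient_id].to_dict()
        areas_bl = _area_signals(aligned.bl)
        areas_fu = _area_signals(aligned.fu_areas)
        fp_roi = partition(record.pullback_id, "FP", aligned.n_frames)[0]
        pullback_dpav = roi_target(fp_roi, areas_bl, areas_fu).dpav
        rois = partition(
            record.pullback_id,
            criterion,
            aligned.n_frames,
            pb_bl=aligned.bl["pb"],
            pb_fu=aligned.fu_pb,
        )
        for roi in rois:
            target = roi_target(roi, areas_bl, areas_fu)
            feature_rows.append(
                assemble_features(
                    roi, target, aligned.bl, clinical, artery=record.artery, set_id=set_id
                )
            )
            meta_rows.append(
                {
                    "pullback_id": record.pullback_id,
                    "patient_id": record.patient_id,
                    "artery": record.artery,
                    "criterion": roi.criterion,
                    "offset_id": roi.offset_id,
                    "start": roi.start,
                    "end": roi.end,
                    "length_mm": roi.length_mm,
                    "pav_bl": target.pav_bl,
                    "pav_fu": target.pav_fu,
                    "dpav": target.dpav,
                    "cls": target.cls,
                    "pullback_dpav": pullback_dpav,
                    "shift_frames": aligned.shift_frames,
                }
            )
    if not feature_rows:
        raise DataError("no ROIs produced for the requested criterion")
    features = pd.DataFrame(feature_rows).reset_index(drop=True)
    meta = pd.DataFrame(meta_rows)
    return features, meta
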