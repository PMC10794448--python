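"""Plain-text serialization of contours, signals, ROI tables and features.

Contour files are long-format CSV with one row per polygon vertex::

    pullback_id, phase{BL,FU}, frame_index, position_mm, role{lumen,vessel},
    vertex_index, x_mm, y_mm

plus one JSON sidecar per pullback with the artery label and patient id.
Vertex coordinates are written with ``repr`` precision so a write/read cycle
is bit-exact for finite doubles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .geometry import Contour
from .synthetic import PullbackRecord, SyntheticCohort

__all__ = [
    "write_cohort",
    "read_pullbacks",
    "write_signals",
    "read_signals",
    "write_roi_table",
    "write_feature_matrix",
]

_CONTOUR_COLUMNS = [
    "pullback_id",
    "phase",
    "frame_index",
    "position_mm",
    "role",
    "vertex_index",
    "x_mm",
    "y_mm",
]


def _contour_rows(record: PullbackRecord, phase: str):
    contours = record.contours_bl if phase == "BL" else record.contours_fu
    positions = record.positions_bl if phase == "BL" else record.positions_fu
    if contours is None:
        raise DataError(f"pullback {record.pullback_id} has no rendered {phase} contours")
    for frame_index, ((lumen, vessel), pos) in enumerate(zip(contours, positions)):
        for contour in (lumen, vessel):
            for v, (x, y) in enumerate(contour.points):
                yield (
                    record.pullback_id,
                    phase,
                    frame_index,
                    repr(float(pos)),
                    contour.role,
                    v,
                    repr(float(x)),
                    repr(float(y)),
                )


def write_cohort(cohort: SyntheticCohort, directory) -> None:
    """Write contour CSVs, JSON sidecars and the clinical covariate table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(directory / "clinical.csv", index=False)
    for record in cohort.pullbacks:
        rows = list(_contour_rows(record, "BL")) + list(_contour_rows(record, "FU"))
        pd.DataFrame(rows, columns=_CONTOUR_COLUMNS).to_csv(
            directory / f"{record.pullback_id}_contours.csv", index=False
        )
        sidecar = {
            "pullback_id": record.pullback_id,
            "artery_label": record.artery,
            "patient_id": record.patient_id,
            "true_shift_frames": int(record.true_shift_frames),
        }
        (directory / f"{record.pullback_id}.json").write_text(json.dumps(sidecar, indent=1))


def read_pullbacks(directory) -> tuple:
    """Read contour CSVs + sidecars back into records and the clinical table."""
    directory = Path(directory)
    clinical_path = directory / "clinical.csv"
    if not clinical_path.exists():
        raise DataError(f"missing clinical table {clinical_path}")
    clinical = pd.read_csv(clinical_path, float_precision="round_trip")
    clinical = clinical.set_index("patient_id", drop=False)
    records = []
    for sidecar_path in sorted(directory.glob("*.json")):
        sidecar = json.loads(sidecar_path.read_text())
        pb_id = sidecar["pullback_id"]
        # round_trip parsing: the default pandas float parser can be 1 ulp off
        df = pd.read_csv(directory / f"{pb_id}_contours.csv", float_precision="round_trip")
        phases = {}
        for phase, pdf in df.groupby("phase"):
            contours, positions = [], []
            for frame_index, fdf in pdf.groupby("frame_index"):
                pos = float(fdf["position_mm"].iloc[0])
                pair = {}
                for role, rdf in fdf.groupby("role"):
                    rdf = rdf.sort_values("vertex_index")
                    pair[role] = Contour(
                        rdf[["x_mm", "y_mm"]].to_numpy(float), role, pos
                    )
                if set(pair) != {"lumen", "vessel"}:
                    raise DataError(f"frame {frame_index} of {pb_id} lacks a contour pair")
                contours.append((pair["lumen"], pair["vessel"]))
                positions.append(pos)
            order = np.argsort(positions)
            phases[phase] = (
                [contours[i] for i in order],
                np.asarray(positions, dtype=float)[order],
            )
        if set(phases) != {"BL", "FU"}:
            raise DataError(f"pullback {pb_id} lacks a BL/FU pair")
        records.append(
            PullbackRecord(
                pullback_id=pb_id,
                patient_id=sidecar["patient_id"],
                artery=sidecar["artery_label"],
                positions_bl=phases["BL"][1],
                positions_fu=phases["FU"][1],
                true_shift_frames=int(sidecar.get("true_shift_frames", 0)),
                contours_bl=phases["BL"][0],
                contours_fu=phases["FU"][0],
            )
        )
    if not records:
        raise DataError(f"no pullback sidecars found in {directory}")
    return records, clinical


def write_signals(signals: dict, pullback_id: str, phase: str, path) -> None:
    """Long-format signal CSV: pullback_id, phase, feature_name, frame, value."""
    rows = []
    for name, sig in signals.items():
        for frame, value in enumerate(sig.values):
            rows.append((pullback_id, phase, name, frame, repr(float(value))))
    pd.DataFrame(
        rows, columns=["pullback_id", "phase", "feature_name", "frame", "value"]
    ).to_csv(path, index=False)


def read_signals(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_roi_table(meta: pd.DataFrame, path) -> None:
    """ROI table CSV in the standard column layout."""
    out = meta.rename(
        columns={"start": "start_frame", "end": "end_frame", "cls": "class"}
    )[
        [
            "pullback_id",
            "criterion",
            "offset_id",
            "start_frame",
            "end_frame",
            "length_mm",
            "artery",
            "dpav",
            "class",
        ]
    ]
    out.to_csv(path, index=False)


def write_feature_matrix(features: pd.DataFrame, path) -> None:
    """Feature matrix CSV: header = feature names, one row per ROI."""
    features.to_csv(path, index=False)
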