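"""Condense frame-wise longitudinal signals into ROI-wise feature vectors.

Each of the 18 frame-wise geometric features and their 18 first derivatives
is condensed over the ROI by six scalar statistics:

- ``MED`` — median,
- ``IQR`` — interquartile range (percentile 75 − 25),
- ``ICR`` — central 80 % range (percentile 90 − 10),
- ``H``   — Shannon entropy (bits) of a 16-bin equal-width histogram over
  the segment's own range,
- ``FFTm``/``FFTp`` — magnitude and phase of the first Fourier harmonic,
  with magnitude normalized by 2/N so a unit-amplitude single-cycle
  sinusoid has magnitude 1.

Three nested feature sets are assembled per ROI:

- ``Sa`` — the 20 patient-level clinical covariates (baseline demographics,
  lipids, risk factors and medications);
- ``Sb`` — ``Sa`` plus the four baseline volumetrics of the ROI
  (TLV, TVV, TAV, PAV);
- ``Sd`` — ``Sb`` plus the 216 condensed statistics (6 × 36 signals), the
  artery label and the ROI length: 242 features in total.

Condensation always uses baseline signals only; follow-up data enters the
dataset solely through the ΔPAV target (and the ChPAV partition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, MissingDataError, TooFewSamplesError
from .geometry import FRAME_FEATURE_NAMES
from .roi import ROI, ROITarget

__all__ = [
    "CLINICAL_VARIABLES",
    "VOLUME_FEATURES",
    "CONDENSE_STATS",
    "SIGNAL_NAMES",
    "FEATURE_SETS",
    "feature_names",
    "condense_statistics",
    "shannon_entropy",
    "fft_first_harmonic",
    "condense_segment",
    "assemble_features",
]

#: Patient-level clinical covariates (age, sex, body-mass index, lipids,
#: risk factors, prior events and medications at 30 days).
CLINICAL_VARIABLES = (
    "AGE", "MSX", "BMI", "HDL", "LDL", "DIA", "HYT", "HYC", "CSK", "FHC",
    "RFL", "PMI", "PPI", "STA", "ASP", "PRA", "CLO", "DAPT", "BB", "ACE",
)

#: Baseline ROI volumetrics shared with classical IVUS progression studies.
VOLUME_FEATURES = ("TLV", "TVV", "TAV", "PAV")

CONDENSE_STATS = ("MED", "IQR", "ICR", "H", "FFTm", "FFTp")

#: The 36 longitudinal signals: 18 frame-wise features and their derivatives.
SIGNAL_NAMES = tuple(FRAME_FEATURE_NAMES) + tuple(f"d_{n}" for n in FRAME_FEATURE_NAMES)

FEATURE_SETS = ("Sa", "Sb", "Sd")

_ENTROPY_BINS = 16


def feature_names(set_id: str) -> list:
    """Ordered feature names of a set: Sa (20), Sb (24) or Sd (242)."""
    if set_id not in FEATURE_SETS:
        raise DataError(f"unknown feature set {set_id!r}")
    names = list(CLINICAL_VARIABLES)
    if set_id in ("Sb", "Sd"):
        names += list(VOLUME_FEATURES)
    if set_id == "Sd":
        for signal in SIGNAL_NAMES:
            names += [f"{stat}({signal})" for stat in CONDENSE_STATS]
        names += ["artery", "roi_length_mm"]
    return names


def condense_statistics(segment) -> dict:
    """Median, interquartile range and central-80% range of a segment.

    Percentiles use linear interpolation between order statistics.
    """
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise DataError("cannot condense an empty segment")
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    return {"MED": float(p50), "IQR": float(p75 - p25), "ICR": float(p90 - p10)}


def shannon_entropy(segment, n_bins: int = _ENTROPY_BINS) -> float:
    """Shannon entropy (bits) of the equal-width histogram of a segment.

    Bins span the segment's own [min, max]; a constant segment has zero
    entropy.  Bounded by log2(n_bins).
    """
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise DataError("cannot compute entropy of an empty segment")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12 * max(1.0, abs(hi), abs(lo)):
        return 0.0  # constant to rounding: a single occupied bin
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def fft_first_harmonic(segment) -> dict:
    """Magnitude and phase of the first discrete Fourier harmonic.

    ``FFTm`` = (2/N)·|X₁| so a unit-amplitude single-cycle cosine has
    magnitude 1 and phase 0; ``FFTp`` = arg(X₁) ∈ (−π, π], defined as 0
    when the magnitude vanishes.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise TooFewSamplesError("first harmonic needs at least 2 samples")
    x1 = np.fft.fft(x)[1]
    n = x.size
    scale = max(1.0, float(np.max(np.abs(x))))
    if np.abs(x1) < 1e-12 * n * scale:
        return {"FFTm": 0.0, "FFTp": 0.0}
    phase = float(np.angle(x1))
    if phase <= -np.pi:
        phase = np.pi
    return {"FFTm": float(2.0 * np.abs(x1) / n), "FFTp": phase}


def condense_segment(segment) -> dict:
    """All six condensed statistics of one signal segment."""
    out = condense_statistics(segment)
    out["H"] = shannon_entropy(segment)
    out.update(fft_first_harmonic(segment))
    return out


def assemble_features(
    roi: ROI,
    target: ROITarget,
    bl_signals: dict,
    clinical: dict,
    artery: str = "NA",
    set_id: str = "Sd",
) -> pd.Series:
    """Assemble one ROI's feature vector for the requested feature set.

    ``bl_signals`` maps each of the 36 signal names to an aligned baseline
    :class:`~plaquetrend.signals.LongitudinalSignal`; condensed statistics
    are computed on the half-open frame slice of the ROI.  ``clinical`` must
    provide every patient-level covariate (missing values raise, no
    imputation).  The artery label is carried as a categorical column and
    one-hot expanded by the model stage.
    """
    names = feature_names(set_id)
    row: dict = {}
    for var in CLINICAL_VARIABLES:
        if var not in clinical or pd.isna(clinical[var]):
            raise MissingDataError(f"clinical variable {var!r} missing for ROI {roi}")
        row[var] = float(clinical[var])
    if set_id in ("Sb", "Sd"):
        row["TLV"] = target.tlv_bl
        row["TVV"] = target.tvv_bl
        row["TAV"] = target.tav_bl
        row["PAV"] = target.pav_bl
    if set_id == "Sd":
        for signal in SIGNAL_NAMES:
            if signal not in bl_signals:
                raise DataError(f"baseline signal {signal!r} missing")
            seg = bl_signals[signal].values[roi.start : roi.end]
            stats = condense_segment(seg)
            for stat in CONDENSE_STATS:
                row[f"{stat}({signal})"] = stats[stat]
        row["artery"] = artery
        row["roi_length_mm"] = roi.length_mm
    series = pd.Series(row)[names]
    expected = {"Sa": 20, "Sb": 24, "Sd": 242}[set_id]
    if len(series) != expected:
        raise DataError(f"{set_id} assembled {len(series)} features, expected {expected}")
    return series
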