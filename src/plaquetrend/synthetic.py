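"""Synthetic IVUS cohort generator with plantable progression structure.

No public dataset of paired baseline/follow-up IVUS contour annotations
exists, so every pipeline stage is exercised on simulated pullbacks that
reproduce the statistical structure the analysis assumes:

- axial plaque-burden fields that are smooth sums of Gaussian bumps on a
  baseline level, confined to the 20–80 % range typical of diseased
  segments;
- irregularly annotated frames (mean spacing ≈ 0.4 mm) carrying lumen and
  vessel contours with the lumen strictly inside the vessel and polygon
  areas matching the field values exactly;
- follow-up fields equal to baseline plus focal, sign-coherent progression
  or regression bumps whose amplitude can be tied to local baseline plaque
  burden (and, optionally, patient covariates) plus Gaussian noise;
- an optional planted integer-frame registration shift between the phases;
- patient-level clinical covariates drawn to match a secondary-prevention
  IVUS trial population (81 patients, 140 arteries; e.g. age ~ N(58.6, 9.9²),
  93 % male).

The default progression model ties the local change in plaque burden to the
local baseline burden with equal signal and noise standard deviations, so
that region-level ΔPAV is a monotone function of the region's median plaque
burden with R² ≈ 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geometry import Contour, _shoelace
from .signals import GRID_SPACING_MM

__all__ = [
    "ClinicalMarginal",
    "CLINICAL_MARGINALS",
    "ProgressionModel",
    "CohortConfig",
    "PullbackRecord",
    "SyntheticCohort",
    "simulate_contour",
    "simulate_clinical",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ClinicalMarginal:
    kind: str  # "normal" or "bernoulli"
    a: float
    b: float = 0.0
    lo: float | None = None


#: Marginal distributions of the 20 patient-level covariates, matching a
#: secondary-prevention IVUS trial population.
CLINICAL_MARGINALS = {
    "AGE": ClinicalMarginal("normal", 58.6, 9.9, lo=18.0),
    "MSX": ClinicalMarginal("bernoulli", 0.93),
    "BMI": ClinicalMarginal("normal", 27.5, 3.8, lo=15.0),
    "HDL": ClinicalMarginal("normal", 1.1, 0.3, lo=0.3),
    "LDL": ClinicalMarginal("normal", 3.4, 0.9, lo=0.5),
    "DIA": ClinicalMarginal("bernoulli", 0.10),
    "HYT": ClinicalMarginal("bernoulli", 0.47),
    "HYC": ClinicalMarginal("bernoulli", 0.43),
    "CSK": ClinicalMarginal("bernoulli", 0.42),
    "FHC": ClinicalMarginal("bernoulli", 0.31),
    "RFL": ClinicalMarginal("bernoulli", 0.04),
    "PMI": ClinicalMarginal("bernoulli", 0.02),
    "PPI": ClinicalMarginal("bernoulli", 0.01),
    "STA": ClinicalMarginal("bernoulli", 0.09),
    "ASP": ClinicalMarginal("bernoulli", 1.00),
    "PRA": ClinicalMarginal("bernoulli", 0.78),
    "CLO": ClinicalMarginal("bernoulli", 0.21),
    "DAPT": ClinicalMarginal("bernoulli", 0.99),
    "BB": ClinicalMarginal("bernoulli", 0.95),
    "ACE": ClinicalMarginal("bernoulli", 0.74),
}

ARTERY_LABELS = ("LAD", "LCx", "RCA")
ARTERY_PROBS = (0.4, 0.3, 0.3)


@dataclass(frozen=True)
class ProgressionModel:
    """Drivers of the follow-up change in plaque burden.

    The change field is a sum of focal Gaussian bumps; each bump's amplitude
    is ``pb_slope·(PB_BL(center) − pb_ref) − statin_effect·STA + N(0, noise_sd²)``.
    With the defaults the deterministic part and the noise have comparable
    spread, giving R² ≈ 0.5 between region ΔPAV and local baseline burden.
    Set ``pb_slope = noise_sd = 0`` for a null cohort (no change at all).
    """

    pb_slope: float = 0.5
    pb_ref: float = 50.0
    noise_sd: float = 4.0
    statin_effect: float = 0.0
    bump_spacing_mm: float = 1.6
    bump_sigma_range: tuple = (0.4, 1.0)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator settings: 81 patients, 140 arteries, 20–45 mm pullbacks."""

    n_patients: int = 81
    n_arteries: int = 140
    length_range_mm: tuple = (20.0, 45.0)
    frame_spacing_range_mm: tuple = (0.3, 0.5)  # mean 0.4 mm
    pb_base_range: tuple = (42.0, 58.0)
    pb_bump_amp: float = 14.0
    pb_bump_spacing_mm: float = 2.0
    pb_bump_sigma_range: tuple = (0.8, 2.0)
    vessel_area_range: tuple = (12.0, 18.0)
    progression: ProgressionModel = field(default_factory=ProgressionModel)
    eccentricity_range: tuple = (0.0, 0.5)
    perturbation_amplitude: float = 0.04
    n_vertices: int = 96
    # serial IVUS protocols match annotated frames anatomically between
    # phases, so the default cohort is already co-registered; set a nonzero
    # range to plant an integer-frame misalignment for registration tests
    shift_frames_range: tuple = (0, 0)
    max_arteries_per_patient: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_arteries < self.n_patients:
            raise ConfigError("need at least one artery per patient")
        if self.n_arteries > self.n_patients * self.max_arteries_per_patient:
            raise ConfigError("too many arteries for the patient count")
        if not (0 < self.frame_spacing_range_mm[0] <= self.frame_spacing_range_mm[1]):
            raise ConfigError("invalid frame spacing range")


@dataclass(frozen=True)
class _BumpField:
    """base + Σ amp·exp(−(x−c)²/2σ²), defined for all x."""

    base: float
    centers: np.ndarray
    amps: np.ndarray
    sigmas: np.ndarray

    def __call__(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.full(x.shape, self.base)
        for c, a, s in zip(self.centers, self.amps, self.sigmas):
            out += a * np.exp(-0.5 * ((x - c) / s) ** 2)
        return out


@dataclass
class PullbackRecord:
    """One artery: paired BL/FU annotated frames plus ground truth."""

    pullback_id: str
    patient_id: str
    artery: str
    positions_bl: np.ndarray  # annotated axial positions, mm
    positions_fu: np.ndarray
    true_pb_bl: np.ndarray | None = None  # plaque burden at the annotated frames, %
    true_pb_fu: np.ndarray | None = None
    true_lumen_area_bl: np.ndarray | None = None
    true_vessel_area_bl: np.ndarray | None = None
    true_lumen_area_fu: np.ndarray | None = None
    true_vessel_area_fu: np.ndarray | None = None
    true_shift_frames: int = 0
    contours_bl: list | None = None  # [(lumen Contour, vessel Contour)]
    contours_fu: list | None = None

    @property
    def length_mm(self) -> float:
        return float(self.positions_bl[-1] - self.positions_bl[0])


@dataclass
class SyntheticCohort:
    config: CohortConfig
    clinical: pd.DataFrame  # one row per patient, indexed by patient_id
    pullbacks: list


def simulate_contour(
    center,
    area_target: float,
    eccentricity: float,
    perturbation_amplitude: float,
    seed: int | np.random.Generator = 0,
    n_vertices: int = 192,
) -> Contour:
    """Perturbed-ellipse contour with exact polygon area.

    An ellipse of the requested eccentricity is expressed in polar form,
    perturbed by random low-order Fourier harmonics (clipped to keep the
    boundary star-shaped, hence simple), and radially rescaled so the
    polygon area equals ``area_target`` exactly.
    """
    if area_target <= 0:
        raise ConfigError("area_target must be positive")
    if not 0.0 <= eccentricity <= 0.95:
        raise ConfigError("eccentricity must be in [0, 0.95]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    b_over_a = np.sqrt(1.0 - eccentricity**2)
    rot = rng.uniform(0.0, np.pi)
    r = b_over_a / np.sqrt(
        (b_over_a * np.cos(theta - rot)) ** 2 + np.sin(theta - rot) ** 2
    )
    pert = np.zeros_like(r)
    for m in range(2, 6):
        pert += rng.uniform(0.0, perturbation_amplitude) * np.cos(
            m * theta + rng.uniform(0.0, 2.0 * np.pi)
        )
    r = r * (1.0 + np.clip(pert, -0.3, 0.3))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    scale = np.sqrt(area_target / _shoelace(pts))
    pts = pts * scale + np.asarray(center, dtype=float)
    return Contour(pts)


def simulate_clinical(n_patients: int, rng: np.random.Generator) -> pd.DataFrame:
    """Patient covariate table drawn from the configured marginals."""
    rows = {}
    for name, m in CLINICAL_MARGINALS.items():
        if m.kind == "normal":
            v = rng.normal(m.a, m.b, size=n_patients)
            if m.lo is not None:
                v = np.clip(v, m.lo, None)
            rows[name] = np.round(v, 3)
        else:
            rows[name] = (rng.random(n_patients) < m.a).astype(float)
    df = pd.DataFrame(rows)
    df.insert(0, "patient_id", [f"P{i:04d}" for i in range(n_patients)])
    return df.set_index("patient_id", drop=False)


def _polar_area_coeffs(r: np.ndarray, t: np.ndarray, theta: np.ndarray):
    # shoelace area of vertices (r + s·t)·u(θ) is quadratic in s
    u = np.column_stack([np.cos(theta), np.sin(theta)])
    cross = (
        u[:, 0] * np.roll(u[:, 1], -1) - np.roll(u[:, 0], -1) * u[:, 1]
    )  # sin of angular step, per edge
    rn, tn = np.roll(r, -1), np.roll(t, -1)
    c0 = 0.5 * np.sum(r * rn * cross)
    c1 = 0.5 * np.sum((r * tn + t * rn) * cross)
    c2 = 0.5 * np.sum(t * tn * cross)
    return c0, c1, c2


def _frame_contours(
    rng_shape: dict,
    x: float,
    lumen_area: float,
    vessel_area: float,
    n_vertices: int,
) -> tuple:
    """Lumen/vessel polygons at axial position x with exact areas.

    Shape parameters vary smoothly along the pullback (harmonic tracks), so
    derivative signals of the shape descriptors are well behaved.  Both
    boundaries are star-shaped around the image origin (the catheter), which
    therefore lies inside the lumen.
    """
    theta = rng_shape["theta"]
    r = np.ones_like(theta)
    for m, (amp, wl, ph, ph_th) in rng_shape["lumen_harmonics"].items():
        a_m = amp * np.cos(2.0 * np.pi * x / wl + ph)
        r = r + a_m * np.cos(m * theta + ph_th)
    r = np.clip(r, 0.35, None)
    w_amp, w_wl, w_ph, w_th = rng_shape["thickness_track"]
    w = w_amp * np.cos(2.0 * np.pi * x / w_wl + w_ph)
    t = 1.0 + np.clip(w, -0.9, 0.9) * np.cos(theta - w_th)
    t = np.clip(t, 0.1, None)

    pts_dir = np.column_stack([np.cos(theta), np.sin(theta)])
    lumen_raw_area = 0.5 * np.sum(
        r * np.roll(r, -1) * (
            pts_dir[:, 0] * np.roll(pts_dir[:, 1], -1)
            - np.roll(pts_dir[:, 0], -1) * pts_dir[:, 1]
        )
    )
    r = r * np.sqrt(lumen_area / lumen_raw_area)
    c0, c1, c2 = _polar_area_coeffs(r, t, theta)
    # solve c2 s² + c1 s + c0 = vessel_area for the positive root
    disc = c1**2 - 4.0 * c2 * (c0 - vessel_area)
    s = (-c1 + np.sqrt(disc)) / (2.0 * c2)
    rv = r + s * t
    lumen = Contour(np.column_stack([r * pts_dir[:, 0], r * pts_dir[:, 1]]), "lumen", x)
    vessel = Contour(np.column_stack([rv * pts_dir[:, 0], rv * pts_dir[:, 1]]), "vessel", x)
    return lumen, vessel


def _artery_fields(cfg: CohortConfig, length: float, rng: np.random.Generator, statin: float):
    base = rng.uniform(*cfg.pb_base_range)
    n_bumps = max(1, int(round(length / cfg.pb_bump_spacing_mm)))
    pb_bl = _BumpField(
        base=base,
        centers=rng.uniform(0.0, length, n_bumps),
        amps=rng.uniform(-cfg.pb_bump_amp, cfg.pb_bump_amp, n_bumps),
        sigmas=rng.uniform(*cfg.pb_bump_sigma_range, n_bumps),
    )
    vessel = _BumpField(
        base=rng.uniform(*cfg.vessel_area_range),
        centers=rng.uniform(0.0, length, max(1, int(round(length / 8.0)))),
        amps=rng.uniform(-2.0, 2.0, max(1, int(round(length / 8.0)))),
        sigmas=rng.uniform(3.0, 8.0, max(1, int(round(length / 8.0)))),
    )
    pm = cfg.progression
    n_d = max(1, int(round(length / pm.bump_spacing_mm)))
    centers = rng.uniform(0.0, length, n_d)
    pb_at = np.clip(pb_bl(centers), 20.0, 80.0)
    amps = (
        pm.pb_slope * (pb_at - pm.pb_ref)
        - pm.statin_effect * statin
        + (rng.normal(0.0, pm.noise_sd, n_d) if pm.noise_sd > 0 else 0.0)
    )
    delta = _BumpField(
        base=0.0,
        centers=centers,
        amps=np.asarray(amps, dtype=float),
        sigmas=rng.uniform(*pm.bump_sigma_range, n_d),
    )
    return pb_bl, vessel, delta


def _identical_progression(pm: ProgressionModel) -> bool:
    return pm.pb_slope == 0.0 and pm.noise_sd == 0.0 and pm.statin_effect == 0.0


def simulate_cohort(config: CohortConfig | None = None, render_contours: bool = True) -> SyntheticCohort:
    """Generate a full paired BL/FU cohort.

    With ``render_contours=False`` only the per-frame truth areas are
    produced (fast path for protocol-level tests); otherwise every annotated
    frame carries a lumen/vessel polygon pair whose areas equal the truth
    exactly.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    clinical = simulate_clinical(cfg.n_patients, rng)

    # assign arteries to patients: everyone gets one, extras go to random
    # patients up to the cap
    owners = list(range(cfg.n_patients))
    counts = np.ones(cfg.n_patients, dtype=int)
    for _ in range(cfg.n_arteries - cfg.n_patients):
        avail = np.flatnonzero(counts < cfg.max_arteries_per_patient)
        pick = int(rng.choice(avail))
        counts[pick] += 1
        owners.append(pick)
    rng.shuffle(owners)

    pullbacks = []
    theta = 2.0 * np.pi * np.arange(cfg.n_vertices) / cfg.n_vertices
    for k, owner in enumerate(owners):
        patient_id = f"P{owner:04d}"
        artery = rng.choice(ARTERY_LABELS, p=ARTERY_PROBS)
        length = rng.uniform(*cfg.length_range_mm)
        statin = float(clinical.loc[patient_id, "STA"])
        pb_bl_f, vessel_f, delta_f = _artery_fields(cfg, length, rng, statin)
        spacing = rng.uniform(*cfg.frame_spacing_range_mm, size=256)
        pos = np.concatenate([[0.0], np.cumsum(spacing)])
        pos = pos[pos <= length]
        shift_frames = int(
            rng.integers(cfg.shift_frames_range[0], cfg.shift_frames_range[1] + 1)
        )
        identical = _identical_progression(cfg.progression) and shift_frames == 0
        shift_mm = shift_frames * GRID_SPACING_MM

        pb_bl = np.clip(pb_bl_f(pos), 20.0, 80.0)
        va_bl = np.clip(vessel_f(pos), 6.0, None)
        la_bl = va_bl * (1.0 - pb_bl / 100.0)
        x_fu = pos - shift_mm  # FU content is the field delayed by the shift
        pb_fu = np.clip(np.clip(pb_bl_f(x_fu), 20.0, 80.0) + delta_f(x_fu), 5.0, 95.0)
        va_fu = np.clip(vessel_f(x_fu), 6.0, None)
        la_fu = va_fu * (1.0 - pb_fu / 100.0)

        record = PullbackRecord(
            pullback_id=f"PB{k:04d}",
            patient_id=patient_id,
            artery=str(artery),
            positions_bl=pos,
            positions_fu=pos.copy(),
            true_pb_bl=pb_bl,
            true_pb_fu=pb_fu,
            true_lumen_area_bl=la_bl,
            true_vessel_area_bl=va_bl,
            true_lumen_area_fu=la_fu,
            true_vessel_area_fu=va_fu,
            true_shift_frames=shift_frames,
        )
        if render_contours:
            shape = {
                "theta": theta,
                "lumen_harmonics": {
                    1: (rng.uniform(0.0, 0.10), rng.uniform(10.0, 25.0),
                        rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
                    2: (rng.uniform(0.0, 0.25 * cfg.eccentricity_range[1] + 1e-9),
                        rng.uniform(10.0, 25.0),
                        rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
                    3: (rng.uniform(0.0, cfg.perturbation_amplitude),
                        rng.uniform(8.0, 20.0),
                        rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
                    4: (rng.uniform(0.0, cfg.perturbation_amplitude),
                        rng.uniform(8.0, 20.0),
                        rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
                },
                "thickness_track": (
                    rng.uniform(0.2, 0.8),
                    rng.uniform(12.0, 30.0),
                    rng.uniform(0, 2 * np.pi),
                    rng.uniform(0, 2 * np.pi),
                ),
            }
            record.contours_bl = [
                _frame_contours(shape, x, la, va, cfg.n_vertices)
                for x, la, va in zip(pos, la_bl, va_bl)
            ]
            if identical:
                record.contours_fu = record.contours_bl
            else:
                record.contours_fu = [
                    _frame_contours(shape, x, la, va, cfg.n_vertices)
                    for x, la, va in zip(x_fu, la_fu, va_fu)
                ]
        pullbacks.append(record)
    return SyntheticCohort(config=cfg, clinical=clinical, pullbacks=pullbacks)
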