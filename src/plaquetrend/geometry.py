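"""Frame-wise geometric descriptors of IVUS lumen/vessel contour pairs.

A *frame* is one cross-sectional image of the artery on which two closed
planar polygons were delineated: the lumen boundary and the vessel (external
elastic membrane) boundary, both in millimetres in the image coordinate
system whose origin is the catheter position.

From one lumen/vessel pair this module computes 18 descriptors:

====================  =========================================================
``lumen_area``        area enclosed by the lumen contour, mm²
``vessel_area``       area enclosed by the vessel contour, mm²
``plaque_area``       vessel_area − lumen_area, mm²
``pb``                plaque burden, 100·plaque_area/vessel_area, %
``xi_l``, ``xi_v``    max/min diameter ratio through the image origin
``xi_p``              centroid offset, ‖c_L − c_V‖ / mean lumen diameter
``rho_l``, ``rho_v``  % of circumferential angle with plaque thickness over
                      0.2 of the lumen (resp. vessel) radius
``thickness_ratio``   max plaque thickness / mean plaque thickness
``psi_l``, ``psi_v``  ellipse-style eccentricity √(1−(min/max)²), own centroid
``phi_l``, ``phi_v``  circularity 4πA/P²
``tau_l``, ``tau_v``  curvature irregularity max(ϰ)−min(ϰ), 1/mm
``kappa_l``,
``kappa_v``           curvature roughness √((r/2π)Σϰ²Δl); 1 for a circle
====================  =========================================================

Diameters through the image origin measure shape relative to the catheter;
the eccentricities ψ use diameters through the contour's own centroid and
therefore measure intrinsic shape.  Curvature is estimated on an
arclength-resampled copy of the contour so the result does not depend on the
annotation vertex density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, Point, Polygon

from .errors import AnchorError, GeometryInconsistencyError, InvalidContourError

__all__ = [
    "Contour",
    "ContourMetrics",
    "CurvatureProfile",
    "FrameFeatures",
    "FRAME_FEATURE_NAMES",
    "contour_basic_metrics",
    "frame_areas",
    "diameter_extremes",
    "eccentricity_features",
    "plaque_distribution_features",
    "shape_complexity_features",
    "curvature_profile",
    "resample_arclength",
    "compute_frame_features",
]

#: Canonical order of the 18 frame-wise features.
FRAME_FEATURE_NAMES = (
    "lumen_area",
    "vessel_area",
    "plaque_area",
    "pb",
    "xi_l",
    "xi_v",
    "xi_p",
    "rho_l",
    "rho_v",
    "thickness_ratio",
    "psi_l",
    "psi_v",
    "phi_l",
    "phi_v",
    "tau_l",
    "tau_v",
    "kappa_l",
    "kappa_v",
)

_DEFAULT_RAYS = 360
_DEFAULT_RESAMPLE = 256


def _shoelace(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


@dataclass(frozen=True)
class Contour:
    """A simple closed polygon (mm) delineated on one IVUS frame.

    Vertices are stored open (first vertex not repeated) and are normalized
    to counter-clockwise orientation on construction.
    """

    points: np.ndarray
    role: str = "lumen"
    frame_position: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise InvalidContourError(
                f"contour needs >=3 two-dimensional vertices, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidContourError("contour vertices must be finite")
        # drop a duplicated closing vertex if present
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
            if pts.shape[0] < 3:
                raise InvalidContourError("contour needs >=3 distinct vertices")
        area = _shoelace(pts)
        if area < 0.0:
            pts = pts[::-1].copy()
            area = -area
        if area <= 0.0:
            raise InvalidContourError("contour encloses zero area")
        if not LinearRing(pts).is_simple:
            raise InvalidContourError("contour is self-intersecting")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def n_vertices(self) -> int:
        return self.points.shape[0]

    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def scaled(self, factor: float) -> "Contour":
        return Contour(self.points * factor, self.role, self.frame_position)


@dataclass(frozen=True)
class ContourMetrics:
    """Area, perimeter, area centroid and best-fit-circle radius of a contour."""

    area: float
    perimeter: float
    centroid: np.ndarray
    r_fit: float


@dataclass(frozen=True)
class CurvatureProfile:
    """Per-vertex signed curvature (1/mm) and local segment length (mm).

    ``sum(delta_l)`` equals the contour perimeter; curvature is positive on
    convex arcs of a counter-clockwise contour.
    """

    varkappa: np.ndarray
    delta_l: np.ndarray


@dataclass(frozen=True)
class FrameFeatures:
    """All 18 frame-wise descriptors of a lumen/vessel pair.

    Invariants (checked on construction): plaque_area ≥ 0; pb ∈ [0,100);
    ξ ≥ 1; ψ ∈ [0,1); φ ∈ (0,1]; τ ≥ 0; κ > 0; ρ ∈ [0,100]; ϱ ≥ 1.
    """

    lumen_area: float
    vessel_area: float
    plaque_area: float
    pb: float
    xi_l: float
    xi_v: float
    xi_p: float
    rho_l: float
    rho_v: float
    thickness_ratio: float
    psi_l: float
    psi_v: float
    phi_l: float
    phi_v: float
    tau_l: float
    tau_v: float
    kappa_l: float
    kappa_v: float

    _TOL = 1e-9

    def __post_init__(self) -> None:
        t = self._TOL
        checks = [
            self.plaque_area >= -t,
            -t <= self.pb < 100.0,
            self.xi_l >= 1.0 - t and self.xi_v >= 1.0 - t,
            self.xi_p >= -t,
            0.0 - t <= self.psi_l < 1.0 and 0.0 - t <= self.psi_v < 1.0,
            0.0 < self.phi_l <= 1.0 + t and 0.0 < self.phi_v <= 1.0 + t,
            self.tau_l >= -t and self.tau_v >= -t,
            self.kappa_l > 0.0 and self.kappa_v > 0.0,
            -t <= self.rho_l <= 100.0 + t and -t <= self.rho_v <= 100.0 + t,
            self.thickness_ratio >= 1.0 - t,
        ]
        if not all(checks):
            raise GeometryInconsistencyError(
                f"frame feature invariants violated: {self.as_dict()}"
            )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FRAME_FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FRAME_FEATURE_NAMES])


def contour_basic_metrics(contour: Contour) -> ContourMetrics:
    """Area (shoelace), perimeter, area centroid and least-squares circle radius."""
    pts = contour.points
    nxt = np.roll(pts, -1, axis=0)
    cross = pts[:, 0] * nxt[:, 1] - nxt[:, 0] * pts[:, 1]
    area = 0.5 * float(np.sum(cross))
    perimeter = float(np.sum(np.linalg.norm(nxt - pts, axis=1)))
    cx = float(np.sum((pts[:, 0] + nxt[:, 0]) * cross) / (6.0 * area))
    cy = float(np.sum((pts[:, 1] + nxt[:, 1]) * cross) / (6.0 * area))
    r_fit = _fit_circle_radius(pts)
    return ContourMetrics(area, perimeter, np.array([cx, cy]), r_fit)


def _fit_circle_radius(pts: np.ndarray) -> float:
    # Kasa algebraic fit: minimize ||x² + y² - 2ax - 2by - c||
    A = np.column_stack([2.0 * pts[:, 0], 2.0 * pts[:, 1], np.ones(len(pts))])
    b = np.sum(pts**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    a, bb, c = sol
    r2 = c + a * a + bb * bb
    if r2 <= 0.0:
        raise InvalidContourError("degenerate circle fit")
    return float(np.sqrt(r2))


def frame_areas(lumen: Contour, vessel: Contour) -> dict:
    """Lumen/vessel/plaque areas and plaque burden (%) from a contour pair."""
    lm = contour_basic_metrics(lumen)
    vm = contour_basic_metrics(vessel)
    if lm.area > vm.area + 1e-12 or not vessel.polygon().buffer(1e-9).covers(
        lumen.polygon()
    ):
        raise GeometryInconsistencyError("lumen contour is not contained in vessel contour")
    plaque = max(vm.area - lm.area, 0.0)
    return {
        "lumen_area": lm.area,
        "vessel_area": vm.area,
        "plaque_area": plaque,
        "pb": 100.0 * plaque / vm.area,
    }


def _ray_crossings(pts: np.ndarray, anchor: np.ndarray, directions: np.ndarray):
    """Signed distances of boundary crossings along each direction line.

    Returns, per direction, the outermost positive and negative crossing
    distances and a flag marking directions with multiple distinct crossings
    on one side.  ``directions`` is an (M,2) array of unit vectors.
    """
    p = pts - anchor  # (E,2)
    q = np.roll(p, -1, axis=0)
    d = q - p  # edge vectors
    # segment param s: p + s*d on the line through origin with direction u
    # cross(u, p + s*d) = 0  ->  s = cross(p,u) / cross(u,d)
    ux, uy = directions[:, 0][:, None], directions[:, 1][:, None]  # (M,1)
    cross_pu = p[None, :, 0] * uy - p[None, :, 1] * ux  # (M,E)
    cross_ud = ux * d[None, :, 1] - uy * d[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = cross_pu / cross_ud
    # small negative tolerance so a ray through a vertex cannot miss both
    # adjacent edges to rounding; the duplicate hit it may create has the
    # same distance and is collapsed by the spread test below
    valid = np.isfinite(s) & (s >= -1e-9) & (s < 1.0)
    hx = p[None, :, 0] + s * d[None, :, 0]
    hy = p[None, :, 1] + s * d[None, :, 1]
    t = hx * ux + hy * uy  # signed distance along u
    t = np.where(valid, t, np.nan)
    tp = np.where(t > 1e-12, t, np.nan)
    tn = np.where(t < -1e-12, -t, np.nan)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_pos = np.nanmax(tp, axis=1)
        t_neg = np.nanmax(tn, axis=1)
        multi = (t_pos - np.nanmin(tp, axis=1) > 1e-9) | (
            t_neg - np.nanmin(tn, axis=1) > 1e-9
        )
    return t_pos, t_neg, multi


def diameter_extremes(contour: Contour, anchor, n_directions: int = _DEFAULT_RAYS) -> dict:
    """Min/max chord length through ``anchor`` over uniformly spaced directions.

    The chord at angle θ ∈ [0,π) joins the outermost boundary crossings on
    the two sides of the anchor.
    """
    anchor = np.asarray(anchor, dtype=float)
    if not contour.polygon().contains(Point(anchor)):
        raise AnchorError(f"anchor {anchor} lies outside the {contour.role} contour")
    theta = np.linspace(0.0, np.pi, n_directions, endpoint=False)
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    t_pos, t_neg, _ = _ray_crossings(contour.points, anchor, dirs)
    if np.any(~np.isfinite(t_pos)) or np.any(~np.isfinite(t_neg)):
        raise GeometryInconsistencyError("a chord direction failed to cross the boundary")
    chords = t_pos + t_neg
    return {"d_min": float(np.min(chords)), "d_max": float(np.max(chords))}


def eccentricity_features(
    lumen: Contour, vessel: Contour, anchor, n_directions: int = _DEFAULT_RAYS
) -> dict:
    """Diameter-ratio and eccentricity descriptors.

    ξ_L, ξ_V use diameters through the image origin (``anchor``, the catheter
    position); ψ_L, ψ_V use diameters through each contour's own centroid;
    ξ_P normalizes the lumen–vessel centroid offset by the mean lumen
    diameter (through the lumen centroid).
    """
    out = {}
    cl = contour_basic_metrics(lumen)
    cv = contour_basic_metrics(vessel)
    for key, contour in (("l", lumen), ("v", vessel)):
        d = diameter_extremes(contour, anchor, n_directions)
        out[f"xi_{key}"] = d["d_max"] / d["d_min"]
    dl_cen = diameter_extremes(lumen, cl.centroid, n_directions)
    dv_cen = diameter_extremes(vessel, cv.centroid, n_directions)
    for key, d in (("l", dl_cen), ("v", dv_cen)):
        ratio = min(d["d_min"] / d["d_max"], 1.0)
        out[f"psi_{key}"] = float(np.sqrt(1.0 - ratio**2))
    mean_lumen_diam = 0.5 * (dl_cen["d_min"] + dl_cen["d_max"])
    out["xi_p"] = float(np.linalg.norm(cl.centroid - cv.centroid) / mean_lumen_diam)
    return out


def plaque_distribution_features(
    lumen: Contour, vessel: Contour, n_angles: int = _DEFAULT_RAYS
) -> dict:
    """Circumferential plaque-thickness descriptors.

    Rays are cast from the lumen centroid at ``n_angles`` uniform angles;
    thickness(θ) is the vessel-hit distance minus the lumen-hit distance.
    ρ_L/ρ_V are the percentage of angles where thickness exceeds 0.2 of the
    lumen/vessel radius; ``thickness_ratio`` is max/mean thickness (1 when
    there is no plaque).
    """
    cl = contour_basic_metrics(lumen)
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    r_l = _single_crossing(lumen, cl.centroid, dirs)
    r_v = _single_crossing(vessel, cl.centroid, dirs)
    thickness = r_v - r_l
    if np.any(thickness < -1e-9):
        raise GeometryInconsistencyError("negative plaque thickness: contours cross")
    thickness = np.clip(thickness, 0.0, None)
    rho_l = 100.0 * float(np.mean(thickness / r_l > 0.2))
    rho_v = 100.0 * float(np.mean(thickness / r_v > 0.2))
    mean_th = float(np.mean(thickness))
    if mean_th < 1e-12:
        ratio = 1.0  # no plaque: max=mean=0 convention
    else:
        ratio = float(np.max(thickness)) / mean_th
    return {"rho_l": rho_l, "rho_v": rho_v, "thickness_ratio": ratio}


def _single_crossing(contour: Contour, anchor: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    t_pos, _, multi = _ray_crossings(contour.points, anchor, dirs)
    if np.any(~np.isfinite(t_pos)):
        raise GeometryInconsistencyError(
            f"a ray from the anchor failed to cross the {contour.role} boundary"
        )
    if np.any(multi):
        raise GeometryInconsistencyError(
            f"a ray crosses the {contour.role} boundary more than once per side"
        )
    return t_pos


def resample_arclength(points: np.ndarray, n: int = _DEFAULT_RESAMPLE) -> np.ndarray:
    """Resample a closed polygon to ``n`` points equally spaced in arclength."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])


def curvature_profile(contour: Contour, n: int = _DEFAULT_RESAMPLE) -> CurvatureProfile:
    """Signed local curvature on the arclength-resampled contour.

    The tangent angle at each resampled vertex is estimated from the central
    difference of positions, unwrapped, and differentiated centrally over
    arclength.  ``delta_l`` is the constant arclength step, summing to the
    perimeter exactly.
    """
    pts = resample_arclength(contour.points, n)
    perimeter = contour_basic_metrics(contour).perimeter
    ds = perimeter / n
    tangent = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    angle = np.unwrap(np.arctan2(tangent[:, 1], tangent[:, 0]))
    # periodic central difference of the tangent angle; the wrap-around step
    # closes the total turning of 2π for a counter-clockwise contour
    dtheta = np.empty(n)
    dtheta[1:-1] = angle[2:] - angle[:-2]
    dtheta[0] = angle[1] - (angle[-1] - 2.0 * np.pi)
    dtheta[-1] = (angle[0] + 2.0 * np.pi) - angle[-2]
    varkappa = dtheta / (2.0 * ds)
    return CurvatureProfile(varkappa=varkappa, delta_l=np.full(n, ds))


def shape_complexity_features(contour: Contour, n_resample: int = _DEFAULT_RESAMPLE) -> dict:
    """Circularity 4πA/P², curvature irregularity max(ϰ)−min(ϰ), and
    curvature roughness √((r_fit/2π)·Σϰ²Δl) (1 for a perfect circle)."""
    m = contour_basic_metrics(contour)
    prof = curvature_profile(contour, n_resample)
    phi = 4.0 * np.pi * m.area / m.perimeter**2
    tau = float(np.max(prof.varkappa) - np.min(prof.varkappa))
    kappa = float(np.sqrt((m.r_fit / (2.0 * np.pi)) * np.sum(prof.varkappa**2 * prof.delta_l)))
    return {"phi": min(phi, 1.0), "tau": tau, "kappa": kappa}


def compute_frame_features(
    lumen: Contour,
    vessel: Contour,
    anchor=(0.0, 0.0),
    n_directions: int = _DEFAULT_RAYS,
    n_resample: int = _DEFAULT_RESAMPLE,
) -> FrameFeatures:
    """Assemble all 18 frame-wise descriptors for one lumen/vessel pair."""
    areas = frame_areas(lumen, vessel)
    ecc = eccentricity_features(lumen, vessel, anchor, n_directions)
    dist = plaque_distribution_features(lumen, vessel, n_directions)
    cl = shape_complexity_features(lumen, n_resample)
    cv = shape_complexity_features(vessel, n_resample)
    return FrameFeatures(
        lumen_area=areas["lumen_area"],
        vessel_area=areas["vessel_area"],
        plaque_area=areas["plaque_area"],
        pb=areas["pb"],
        xi_l=ecc["xi_l"],
        xi_v=ecc["xi_v"],
        xi_p=ecc["xi_p"],
        rho_l=dist["rho_l"],
        rho_v=dist["rho_v"],
        thickness_ratio=dist["thickness_ratio"],
        psi_l=ecc["psi_l"],
        psi_v=ecc["psi_v"],
        phi_l=cl["phi"],
        phi_v=cv["phi"],
        tau_l=cl["tau"],
        tau_v=cv["tau"],
        kappa_l=cl["kappa"],
        kappa_v=cv["kappa"],
    )
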