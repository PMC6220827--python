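"""Outline processing: heteropolarity-aware alignment, elliptic Fourier
descriptors with harmonic calibration, and all outline-derived features.

Heteropolar valve outlines (one rounded, one pointed apex) produce bimodal
within-group EFD distributions unless outlines are consistently oriented.
The alignment therefore rotates each outline's principal axis onto x,
centers it on the midpoint of its major axis, and flips it so the broader
apex (diagnosed by the sign of the OLS slope of |y| on x) lies at +x.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box

from .io import Unit, ValveOutline

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedOutline",
    "EFDSet",
    "align_outline",
    "compute_efd",
    "reconstruct_efd",
    "calibrate_harmonic_power",
    "basic_measures",
    "heteropolarity_index",
    "eccentricity_broadest",
    "convexity_indices",
    "heuristic_descriptors",
    "extract_outline_features",
    "polygon_moments",
    "NON_EFD_FEATURES",
]

#: The morphometric variables used (besides EFDs) in the classification
#: experiments: basic measures, five heuristic shape descriptors, five
#: convexity indices, aspect ratio, stria descriptors, the relative location
#: of the broadest position, and the heteropolarity index (19 variables).
NON_EFD_FEATURES = [
    "area",
    "perimeter",
    "length",
    "width",
    "rectangularity",
    "compactness",
    "ellipticity",
    "triangularity",
    "roundness",
    "convexity_by_perimeter",
    "convexity_by_area",
    "CDF",
    "PCAF",
    "CHMDF",
    "aspect_ratio",
    "stria_density",
    "stria_orientation",
    "eccentricity_broadest",
    "heteropolarity_index",
]


class DegenerateOutlineError(ValueError):
    """Raised for collinear or zero-area point sets."""


@dataclass
class AlignedOutline:
    """An outline after rotation/translation/flip normalization.

    Major axis lies on x, the midpoint of the major-axis endpoints is at the
    origin, traversal is counterclockwise starting at the vertex nearest the
    +x apex, and the broader apex (positive |y|-on-x regression slope) is at
    +x.
    """

    specimen_id: str
    points: np.ndarray
    flipped: bool
    regression_slope: float


def _as_um_points(outline: ValveOutline) -> np.ndarray:
    return outline.to_micrometers().points


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _principal_angle(pts: np.ndarray) -> float:
    """Angle of the principal axis of the point set, in (-pi/2, pi/2]."""
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
        raise DegenerateOutlineError("degenerate point set")
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[-1] < 1e-12 * max(1.0, abs(evals).max()):
        raise DegenerateOutlineError("collinear point set")
    v = evecs[:, -1]
    angle = np.arctan2(v[1], v[0])
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return float(angle)


def _normalize_start(pts: np.ndarray) -> np.ndarray:
    """Roll the point order so the vertex nearest angle 0 (the +x apex) is first."""
    ang = np.abs(np.arctan2(pts[:, 1], pts[:, 0]))
    return np.roll(pts, -int(np.argmin(ang)), axis=0)


def align_outline(outline: ValveOutline) -> AlignedOutline:
    """Align an outline: principal axis to x, major-axis midpoint to origin,
    broader apex to +x (flip diagnosed by the OLS slope of |y| against x)."""
    pts = _as_um_points(outline).copy()
    if len(pts) < 3:
        raise DegenerateOutlineError(f"{outline.specimen_id}: need >= 3 points")
    extent = float(np.ptp(pts, axis=0).max())
    if extent <= 0 or abs(_signed_area(pts)) < 1e-12 * extent**2:
        raise DegenerateOutlineError(f"{outline.specimen_id}: zero-area point set")
    angle = _principal_angle(pts)
    c, s = np.cos(-angle), np.sin(-angle)
    pts = pts @ np.array([[c, -s], [s, c]]).T
    # center on the midpoint of the major-axis endpoints
    i_max, i_min = int(np.argmax(pts[:, 0])), int(np.argmin(pts[:, 0]))
    pts -= (pts[i_max] + pts[i_min]) / 2.0
    if _signed_area(pts) < 0:
        pts = pts[::-1]
    # OLS slope of |y| on x: negative means the broader apex sits at -x
    x, ay = pts[:, 0], np.abs(pts[:, 1])
    vx = np.sum((x - x.mean()) ** 2)
    if vx <= 0:
        raise DegenerateOutlineError(f"{outline.specimen_id}: degenerate x spread")
    slope = float(np.sum((x - x.mean()) * (ay - ay.mean())) / vx)
    flipped = slope < 0
    if flipped:
        pts = pts.copy()
        pts[:, 0] = -pts[:, 0]
        pts = pts[::-1]  # mirror reverses orientation; restore CCW
        x, ay = pts[:, 0], np.abs(pts[:, 1])
        slope = float(np.sum((x - x.mean()) * (ay - ay.mean())) / vx)
    pts = _normalize_start(pts)
    return AlignedOutline(
        specimen_id=outline.specimen_id,
        points=pts,
        flipped=flipped,
        regression_slope=slope,
    )


# ---------------------------------------------------------------------------
# Elliptic Fourier descriptors (Kuhl & Giardina formulation)


@dataclass
class EFDSet:
    """Elliptic Fourier coefficients (a_n, b_n, c_n, d_n), n = 1..N, plus the
    DC offsets A0, C0; arc-length parameterized over the closed polyline."""

    harmonics: np.ndarray  # (N, 4)
    a0: float
    c0: float

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    def power(self) -> np.ndarray:
        """Harmonic power (a^2 + b^2 + c^2 + d^2)/2 per harmonic."""
        return 0.5 * np.sum(self.harmonics**2, axis=1)


def compute_efd(
    outline: AlignedOutline | np.ndarray,
    n_harmonics: int,
    parameterization: str = "uniform",
) -> EFDSet:
    """Elliptic Fourier coefficients of a closed polyline.

    With the default uniform parameterization the sampled vertices are taken
    as equally spaced in the Fourier parameter, so an ellipse sampled at
    uniform angles is captured exactly by its first harmonic with
    (a1, d1) equal to the semi-axes; ``parameterization="arc_length"``
    selects constant-speed traversal instead. No additional normalization is
    applied: the alignment already fixes pose, which keeps coefficients
    comparable across specimens.
    """
    pts = outline.points if isinstance(outline, AlignedOutline) else np.asarray(outline)
    n_pts = len(pts)
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if n_harmonics > n_pts // 2:
        raise ValueError(
            f"n_harmonics={n_harmonics} exceeds points/2={n_pts // 2} (aliasing)"
        )
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)  # (n, 2) edge vectors
    if parameterization == "uniform":
        dt = np.ones(len(d))
    elif parameterization == "arc_length":
        dt = np.hypot(d[:, 0], d[:, 1])
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    if np.any(dt == 0):
        keep = dt > 0
        d, dt = d[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T == 0:
        raise DegenerateOutlineError("zero-perimeter outline")
    n = np.arange(1, n_harmonics + 1)[:, None]  # (N, 1)
    phi = 2.0 * np.pi * t / T  # (n+1,)
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (N, n)
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    coef = T / (2.0 * (n.ravel() ** 2) * np.pi**2)
    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    a = coef * (dx_dt * dcos).sum(axis=1)
    b = coef * (dx_dt * dsin).sum(axis=1)
    c = coef * (dy_dt * dcos).sum(axis=1)
    e = coef * (dy_dt * dsin).sum(axis=1)
    # DC terms by direct arc-length integration of the polyline
    xi = np.cumsum(d[:, 0]) - d[:, 0]  # x at segment starts, relative to p0
    yi = np.cumsum(d[:, 1]) - d[:, 1]
    a0 = pts[0, 0] + np.sum((xi + d[:, 0] / 2.0) * dt) / T
    c0 = pts[0, 1] + np.sum((yi + d[:, 1] / 2.0) * dt) / T
    return EFDSet(np.column_stack([a, b, c, e]), float(a0), float(c0))


def reconstruct_efd(efd: EFDSet, n_points: int = 360) -> np.ndarray:
    """Evaluate the Fourier series on a uniform parameter grid."""
    phi = 2.0 * np.pi * np.arange(n_points) / n_points
    n = np.arange(1, efd.n_harmonics + 1)[:, None]
    cos_t, sin_t = np.cos(n * phi), np.sin(n * phi)
    a, b, c, d = efd.harmonics.T
    x = efd.a0 + a @ cos_t + b @ sin_t
    y = efd.c0 + c @ cos_t + d @ sin_t
    return np.column_stack([x, y])


def calibrate_harmonic_power(
    outlines: list[AlignedOutline], threshold: float = 0.999
) -> int:
    """Smallest N whose mean cumulative harmonic power reaches ``threshold``
    of the mean total power (total taken at N_max = points/2)."""
    if not outlines:
        raise ValueError("empty outline list")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n_max = min(len(o.points) // 2 for o in outlines)
    spectra = np.array([compute_efd(o, n_max).power() for o in outlines])
    mean_cum = spectra.mean(axis=0).cumsum()
    total = mean_cum[-1]
    return int(np.searchsorted(mean_cum, threshold * total - 1e-15) + 1)


# ---------------------------------------------------------------------------
# Scalar shape features


def polygon_moments(pts: np.ndarray) -> dict:
    """Area, centroid, and second-order central moments of a simple polygon."""
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * np.sum(cross)
    if area == 0:
        raise DegenerateOutlineError("zero-area polygon")
    cx = np.sum((x + x1) * cross) / (6.0 * area)
    cy = np.sum((y + y1) * cross) / (6.0 * area)
    m20 = np.sum((x**2 + x * x1 + x1**2) * cross) / 12.0
    m02 = np.sum((y**2 + y * y1 + y1**2) * cross) / 12.0
    m11 = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    sign = 1.0 if area > 0 else -1.0
    a = abs(area)
    return {
        "area": a,
        "centroid": (cx, cy),
        "mu20": sign * m20 - a * cx**2,
        "mu02": sign * m02 - a * cy**2,
        "mu11": sign * m11 - a * cx * cy,
    }


def _ensure_aligned(outline: ValveOutline | AlignedOutline) -> AlignedOutline:
    if isinstance(outline, AlignedOutline):
        return outline
    return align_outline(outline)


def basic_measures(outline: ValveOutline | AlignedOutline) -> dict:
    """Length and width (extents along the principal axes, um), shoelace
    area (um^2), closed perimeter (um), and aspect ratio."""
    aligned = _ensure_aligned(outline)
    pts = aligned.points
    length = float(pts[:, 0].max() - pts[:, 0].min())
    width = float(pts[:, 1].max() - pts[:, 1].min())
    if length <= 0 or width <= 0:
        raise DegenerateOutlineError("degenerate extent")
    closed = np.vstack([pts, pts[:1]])
    perimeter = float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))
    return {
        "length": length,
        "width": width,
        "area": abs(_signed_area(pts)),
        "perimeter": perimeter,
        "aspect_ratio": length / width,
    }


def heteropolarity_index(outline: ValveOutline | AlignedOutline) -> float:
    """Area asymmetry of the valve about its transapical split line.

    The outline is split along the minor-axis direction of its best-fitting
    ellipse, placed at the midpoint of the major axis; the index is the
    absolute difference of the two part areas over total area (exact polygon
    clipping). 0 for isopolar shapes, toward 1 for extreme heteropolarity.
    """
    aligned = _ensure_aligned(outline)
    poly = Polygon(aligned.points)
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    total = poly.area
    if total <= 0:
        raise DegenerateOutlineError("zero-area outline")
    xs = aligned.points[:, 0]
    span = float(np.abs(xs).max()) * 4 + 1
    right = poly.intersection(box(0.0, -span, span, span)).area
    left = total - right
    return float(abs(right - left) / total)


def eccentricity_broadest(
    outline: ValveOutline | AlignedOutline, n_samples: int = 512
) -> float:
    """Relative distance of the broadest valve position from the broader apex.

    The width profile w(x) is sampled at ``n_samples`` equally spaced apical
    positions (linear interpolation of contour crossings); the result is
    (x_apex - x_broadest) / L measured from the +x (broader) apex, ties broken
    toward the valve center.
    """
    aligned = _ensure_aligned(outline)
    pts = aligned.points
    x_min, x_max = pts[:, 0].min(), pts[:, 0].max()
    L = x_max - x_min
    if L <= 0:
        raise DegenerateOutlineError("degenerate outline")
    eps = L / (2.0 * n_samples)
    xs = np.linspace(x_min + eps, x_max - eps, n_samples)
    closed = np.vstack([pts, pts[:1]])
    p, q = closed[:-1], closed[1:]
    widths = np.zeros(n_samples)
    for k, xq in enumerate(xs):
        lo = np.minimum(p[:, 0], q[:, 0])
        hi = np.maximum(p[:, 0], q[:, 0])
        hit = (lo <= xq) & (xq < hi)
        if hit.sum() < 2:
            continue
        frac = (xq - p[hit, 0]) / (q[hit, 0] - p[hit, 0])
        ys = p[hit, 1] + frac * (q[hit, 1] - p[hit, 1])
        widths[k] = ys.max() - ys.min()
    if not widths.any():
        raise DegenerateOutlineError("no interior crossings")
    w_max = widths.max()
    candidates = np.flatnonzero(widths >= w_max - 1e-12 * max(w_max, 1.0))
    center = (x_min + x_max) / 2.0
    best = candidates[np.argmin(np.abs(xs[candidates] - center))]
    return float((x_max - xs[best]) / L)


def convexity_indices(outline: ValveOutline | AlignedOutline) -> dict:
    """Convexity defect measures against the convex hull.

    convexity_by_perimeter = hull perimeter / outline perimeter;
    convexity_by_area = outline area / hull area;
    PCAF = percent concave area fraction, (hull - outline)/hull * 100;
    CHMDF = max vertex-to-hull distance / L; CDF = mean vertex-to-hull
    distance / L.
    """
    aligned = _ensure_aligned(outline)
    pts = aligned.points
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    hull = poly.convex_hull
    if poly.area <= 0 or hull.area <= 0:
        raise DegenerateOutlineError("zero-area outline")
    L = pts[:, 0].max() - pts[:, 0].min()
    dists = np.array([hull.exterior.distance(Point(p)) for p in pts])
    return {
        "convexity_by_perimeter": hull.length / poly.length,
        "convexity_by_area": poly.area / hull.area,
        "PCAF": (hull.area - poly.area) / hull.area * 100.0,
        "CHMDF": float(dists.max()) / L,
        "CDF": float(dists.mean()) / L,
    }


_I1_ELLIPSE = 1.0 / (16.0 * np.pi**2)
_I1_TRIANGLE = 1.0 / 108.0


def heuristic_descriptors(outline: ValveOutline | AlignedOutline) -> dict:
    """Dimensionless heuristic shape descriptors.

    rectangularity = area/(L*W); form_factor = 4*pi*area/perimeter^2;
    compactness = its reciprocal; roundness = 4*area/(pi*L^2); ellipticity
    and triangularity from the affine moment invariant
    I1 = (mu20*mu02 - mu11^2)/mu00^4, normalized to peak at 1 for the ideal
    ellipse (I1 = 1/(16*pi^2)) and triangle (I1 = 1/108) respectively.
    """
    aligned = _ensure_aligned(outline)
    m = basic_measures(aligned)
    mom = polygon_moments(aligned.points)
    i1 = (mom["mu20"] * mom["mu02"] - mom["mu11"] ** 2) / mom["area"] ** 4
    ellipticity = i1 / _I1_ELLIPSE if i1 <= _I1_ELLIPSE else _I1_ELLIPSE / i1
    triangularity = i1 / _I1_TRIANGLE if i1 <= _I1_TRIANGLE else _I1_TRIANGLE / i1
    form_factor = 4.0 * np.pi * m["area"] / m["perimeter"] ** 2
    return {
        "rectangularity": m["area"] / (m["length"] * m["width"]),
        "compactness": 1.0 / form_factor,
        "ellipticity": float(ellipticity),
        "triangularity": float(triangularity),
        "roundness": 4.0 * m["area"] / (np.pi * m["length"] ** 2),
        "form_factor": form_factor,
    }


def efd_columns(n_harmonics: int) -> list[str]:
    return [f"{letter}{n}" for n in range(1, n_harmonics + 1) for letter in "ABCD"]


def extract_outline_features(
    outlines: list[ValveOutline], n_harmonics: int = 14, n_samples: int = 512
) -> pd.DataFrame:
    """Per-specimen feature table: all scalar shape features plus EFD
    coefficient columns A1..D{n_harmonics}. Per-specimen failures are logged
    and recorded as missing values, never raised."""
    rows = []
    cols = efd_columns(n_harmonics)
    for outline in outlines:
        row: dict = {"specimen_id": outline.specimen_id}
        try:
            aligned = align_outline(outline)
            row.update(basic_measures(aligned))
            row["heteropolarity_index"] = heteropolarity_index(aligned)
            row["eccentricity_broadest"] = eccentricity_broadest(aligned, n_samples)
            row.update(convexity_indices(aligned))
            row.update(heuristic_descriptors(aligned))
            efd = compute_efd(aligned, n_harmonics)
            row.update(dict(zip(cols, efd.harmonics.ravel())))
        except (DegenerateOutlineError, ValueError) as exc:
            logger.warning("outline %s failed: %s", outline.specimen_id, exc)
            warnings.warn(
                f"outline {outline.specimen_id} failed feature extraction: {exc}",
                stacklevel=2,
            )
        rows.append(row)
    return pd.DataFrame(rows)
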