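"""Quantification of *Habenaria radiata* lip (labellum) shape.

The lip is described by seven measured factors — whole-lip area and
perimeter, body length, body width, wing length, body–wing angle, and the
serration number of the left wing — plus the dissection index
(perimeter/sqrt(area), a dimensionless outline-complexity measure minimised
at ``2*sqrt(pi)`` by a circle) computed on the left-wing outline.  Six of
these are normalised against fixed maxima to give a radar-chart profile
comparable across populations.

Inputs are vector contours (ordered 2D vertex lists in mm) plus landmark
annotations; image segmentation is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from shapely.geometry import LineString, Polygon


class GeometryError(ValueError):
    """Raised for degenerate or invalid geometric input."""


# ---------------------------------------------------------------------------
# contours and annotations
# ---------------------------------------------------------------------------


@dataclass
class Contour:
    """Ordered polygon/polyline vertices in mm.

    Closed contours are normalised to counter-clockwise orientation on
    construction; the closing edge is implicit (the last vertex is not a
    repeat of the first).
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array")
        if self.closed:
            if len(v) >= 2 and np.allclose(v[0], v[-1]):
                v = v[:-1]
            if len(v) < 3:
                raise GeometryError("a closed contour needs >= 3 vertices")
            if _signed_area(v) < 0:  # normalise to counter-clockwise
                v = v[::-1].copy()
        elif len(v) < 2:
            raise GeometryError("an open contour needs >= 2 vertices")
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)

    def as_polygon(self) -> Polygon:
        if not self.closed:
            raise GeometryError("open contour has no polygon")
        return Polygon(self.vertices)

    def is_simple(self) -> bool:
        if self.closed:
            return self.as_polygon().is_valid
        return LineString(self.vertices).is_simple

    def transformed(self, matrix: np.ndarray, shift=(0.0, 0.0)) -> "Contour":
        """Apply an affine map ``x -> matrix @ x + shift``."""
        v = self.vertices @ np.asarray(matrix, float).T + np.asarray(shift, float)
        return Contour(v, closed=self.closed)


@dataclass
class LipAnnotation:
    """A whole-lip contour with its landmark decomposition.

    The middle part of the lip is the body (axis from ``body_base`` to
    ``body_tip``); the two lateral lobes are the wings.  The left wing has
    its own closed sub-contour, with ``serrated_margin`` a half-open 0-based
    vertex-index range marking the fringed distal margin.
    """

    lip_contour: Contour
    left_wing_contour: Contour
    body_base: np.ndarray
    body_tip: np.ndarray
    body_width_segment: tuple[np.ndarray, np.ndarray]
    wing_base: np.ndarray
    wing_tip: np.ndarray
    serrated_margin: tuple[int, int]

    def __post_init__(self) -> None:
        self.body_base = np.asarray(self.body_base, float)
        self.body_tip = np.asarray(self.body_tip, float)
        self.wing_base = np.asarray(self.wing_base, float)
        self.wing_tip = np.asarray(self.wing_tip, float)
        self.body_width_segment = (
            np.asarray(self.body_width_segment[0], float),
            np.asarray(self.body_width_segment[1], float),
        )
        lo, hi = self.serrated_margin
        if not (0 <= lo < hi <= len(self.left_wing_contour)):
            raise GeometryError(
                f"serrated_margin {self.serrated_margin} invalid for a "
                f"{len(self.left_wing_contour)}-vertex wing contour"
            )

    def margin_vertices(self) -> np.ndarray:
        lo, hi = self.serrated_margin
        return self.left_wing_contour.vertices[lo:hi]

    def transformed(self, matrix: np.ndarray, shift=(0.0, 0.0)) -> "LipAnnotation":
        m = np.asarray(matrix, float)
        s = np.asarray(shift, float)
        pt = lambda p: m @ p + s

        wing = self.left_wing_contour
        new_wing_v = wing.vertices @ m.T + s
        lo, hi = self.serrated_margin
        if _signed_area(new_wing_v) < 0:
            # Contour() will reverse vertex order; remap the margin range.
            n = len(new_wing_v)
            lo, hi = n - hi, n - lo
        return LipAnnotation(
            lip_contour=self.lip_contour.transformed(m, s),
            left_wing_contour=Contour(new_wing_v, closed=wing.closed),
            body_base=pt(self.body_base),
            body_tip=pt(self.body_tip),
            body_width_segment=(pt(self.body_width_segment[0]), pt(self.body_width_segment[1])),
            wing_base=pt(self.wing_base),
            wing_tip=pt(self.wing_tip),
            serrated_margin=(lo, hi),
        )


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------


@dataclass
class LipMeasurements:
    """The seven measured factors plus the left-wing dissection index."""

    area: float
    perimeter: float
    dissection_index: float
    body_length: float
    body_width: float
    wing_length: float
    angle: float
    serration_number: int


@dataclass
class NormalizationConstants:
    """Per-trait maxima used to scale measurements into radar values."""

    di_max: float = 40.0
    body_length_max: float = 30.0
    body_width_max: float = 10.0
    wing_length_max: float = 40.0
    angle_max: float = 90.0
    serration_max: float = 50.0

    def __post_init__(self) -> None:
        for name in ("di_max", "body_length_max", "body_width_max",
                     "wing_length_max", "angle_max", "serration_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Radar-profile trait codes, in display order.
RADAR_TRAITS = ("DI", "BL", "BW", "WL", "A", "Se")


@dataclass
class RadarProfile:
    """Six normalised trait values (measurement / trait maximum)."""

    di: float
    bl: float
    bw: float
    wl: float
    a: float
    se: float

    def as_array(self) -> np.ndarray:
        return np.array([self.di, self.bl, self.bw, self.wl, self.a, self.se])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(RADAR_TRAITS, self.as_array()))


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(contour: Contour) -> float:
    """Shoelace area (mm^2) of a closed simple polygon."""
    if not contour.closed:
        raise GeometryError("area requires a closed contour")
    if not contour.is_simple():
        raise GeometryError("self-intersecting contour")
    a = abs(_signed_area(contour.vertices))
    if a == 0.0:
        raise GeometryError("degenerate contour with zero area")
    return a


def polygon_perimeter(contour: Contour) -> float:
    """Total edge length (mm); includes the closing edge when closed."""
    v = contour.vertices
    seg = np.diff(v, axis=0)
    total = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if contour.closed:
        total += float(np.hypot(*(v[0] - v[-1])))
    return total


def dissection_index(contour: Contour) -> float:
    """perimeter / sqrt(area); >= 2*sqrt(pi), with equality for a circle."""
    area = polygon_area(contour)
    return polygon_perimeter(contour) / math.sqrt(area)


def measure_body(annotation: LipAnnotation) -> tuple[float, float]:
    """(body_length, body_width) from the landmark points, in mm."""
    for name in ("body_base", "body_tip"):
        if getattr(annotation, name) is None:
            raise GeometryError(f"missing landmark {name}")
    length = float(np.hypot(*(annotation.body_tip - annotation.body_base)))
    p, q = annotation.body_width_segment
    width = float(np.hypot(*(q - p)))
    return length, width


def measure_wing(annotation: LipAnnotation) -> tuple[float, float]:
    """(wing_length, angle_deg) — wing axis length and unsigned body–wing angle.

    The angle is taken in the open interval (0, 180); parallel or
    anti-parallel axes are degenerate and rejected.
    """
    body = annotation.body_tip - annotation.body_base
    wing = annotation.wing_tip - annotation.wing_base
    nb, nw = np.hypot(*body), np.hypot(*wing)
    if nb == 0 or nw == 0:
        raise GeometryError("zero-length body or wing axis")
    cosang = float(np.clip(np.dot(body, wing) / (nb * nw), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    if angle < 1e-9 or angle > 180 - 1e-9:
        raise GeometryError("degenerate body–wing angle (parallel axes)")
    return float(nw), angle


def _fit_circle(points: np.ndarray):
    """Least-squares (Kåsa) circle fit; returns (center, radius) or None."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover - lstsq rarely fails
        return None
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        return None
    span = float(np.ptp(points, axis=0).max())
    r = math.sqrt(r2)
    if not np.isfinite(r) or r > 1e6 * max(span, 1.0):
        return None
    return np.array([cx, cy]), r


def count_serrations(margin: np.ndarray, prominence_threshold: float = 0.2) -> int:
    """Count marginal teeth on a wing-margin vertex path.

    The margin's low-frequency sweep (a smooth lobe outline) is removed by a
    least-squares circular baseline; teeth are then the local maxima of the
    residual clearance whose topographic prominence is at least
    ``prominence_threshold`` (mm).  A smooth arc therefore counts zero teeth,
    however strongly it bulges above its chord.  Plateaus count once.
    Falls back to the perpendicular chord-clearance profile when the margin
    is too flat for a stable circle fit.
    """
    if prominence_threshold <= 0:
        raise ValueError("prominence_threshold must be > 0")
    margin = np.asarray(margin, float)
    if margin.ndim != 2 or margin.shape[1] != 2 or len(margin) < 5:
        raise GeometryError("margin needs >= 5 (x, y) vertices")

    fit = _fit_circle(margin)
    if fit is not None:
        center, radius = fit
        profile = np.hypot(*(margin - center).T) - radius
    else:
        # Nearly straight margin: the chord itself is the baseline.
        chord = margin[-1] - margin[0]
        n = np.hypot(*chord)
        if n == 0:
            raise GeometryError("margin endpoints coincide")
        normal = np.array([-chord[1], chord[0]]) / n
        profile = (margin - margin[0]) @ normal

    peaks, _ = find_peaks(profile, prominence=prominence_threshold)
    return int(len(peaks))


def measure_lip(annotation: LipAnnotation,
                prominence_threshold: float = 0.2) -> LipMeasurements:
    """All lip measurements for one annotated flower.

    Area and perimeter are taken on the whole-lip contour; the dissection
    index and serration number on the left-wing sub-contour.
    """
    area = polygon_area(annotation.lip_contour)
    perimeter = polygon_perimeter(annotation.lip_contour)
    di = dissection_index(annotation.left_wing_contour)
    body_length, body_width = measure_body(annotation)
    wing_length, angle = measure_wing(annotation)
    serr = count_serrations(annotation.margin_vertices(), prominence_threshold)
    return LipMeasurements(
        area=area,
        perimeter=perimeter,
        dissection_index=di,
        body_length=body_length,
        body_width=body_width,
        wing_length=wing_length,
        angle=angle,
        serration_number=serr,
    )


def normalize_profile(m: LipMeasurements,
                      constants: NormalizationConstants | None = None) -> RadarProfile:
    """Scale six measurements by their trait maxima (DI/40, BL/30, BW/10,
    WL/40, A/90, Se/50 by default)."""
    c = constants or NormalizationConstants()
    return RadarProfile(
        di=m.dissection_index / c.di_max,
        bl=m.body_length / c.body_length_max,
        bw=m.body_width / c.body_width_max,
        wl=m.wing_length / c.wing_length_max,
        a=m.angle / c.angle_max,
        se=m.serration_number / c.serration_max,
    )


def summarize_population(profiles: list[RadarProfile]) -> pd.DataFrame:
    """Per-trait mean, sample SD (ddof=1; 0 when n=1) and n, radar-ready.

    Returns a DataFrame indexed by trait code with columns mean, sd, n.
    """
    if not profiles:
        raise ValueError("no profiles to summarise")
    arr = np.stack([p.as_array() for p in profiles])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1])
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "n": len(arr)},
        index=pd.Index(RADAR_TRAITS, name="trait"),
    )
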