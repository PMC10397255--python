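"""Dot-array stimulus generation.

Stimuli are arrays of dots placed in a circular field centred on fixation,
either at random or mirror-symmetric about the vertical axis.  All coordinates
are in degrees of visual angle, origin at fixation, x positive rightward and
y positive upward.  A central rectangular region is kept free of dots so that
a foveal distractor can be displayed without overlap, and a minimum
edge-to-edge separation between dots prevents fusion of neighbouring items.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "FieldGeometry",
    "DotArray",
    "PlacementError",
    "Violation",
    "sample_random_array",
    "sample_symmetric_array",
    "convex_hull_area",
    "validate_array",
]

ARRANGEMENTS = ("random", "symmetric")


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a dot (infeasible density)."""


@dataclass(frozen=True)
class FieldGeometry:
    """Geometry of the stimulus field, in degrees of visual angle.

    Parameters
    ----------
    field_diameter
        Diameter of the virtual circle containing all dots.
    dot_diameter
        Diameter of a single dot.
    min_separation
        Minimum *edge-to-edge* distance between dots, so centres must be at
        least ``dot_diameter + min_separation`` apart.
    exclusion_width, exclusion_height
        Size of the central dot-free rectangle reserved for the distractor.
    """

    field_diameter: float = 10.0
    dot_diameter: float = 0.3
    min_separation: float = 0.3
    exclusion_width: float = 1.6
    exclusion_height: float = 1.6

    def __post_init__(self) -> None:
        for name in (
            "field_diameter",
            "dot_diameter",
            "min_separation",
            "exclusion_width",
            "exclusion_height",
        ):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        half_diag = math.hypot(self.exclusion_width / 2, self.exclusion_height / 2)
        if half_diag >= self.field_radius:
            raise ValueError("exclusion rectangle does not fit inside the field circle")
        if self.min_separation + self.dot_diameter >= self.field_diameter:
            raise ValueError("min_separation + dot_diameter must be < field_diameter")

    @property
    def field_radius(self) -> float:
        return self.field_diameter / 2

    @property
    def dot_radius(self) -> float:
        return self.dot_diameter / 2

    @property
    def min_center_distance(self) -> float:
        """Minimum centre-to-centre distance between two dots."""
        return self.dot_diameter + self.min_separation

    @property
    def placement_radius(self) -> float:
        """Largest centre radius keeping a dot fully inside the field."""
        return self.field_radius - self.dot_radius


@dataclass(frozen=True)
class DotArray:
    """An ordered set of dot centres with an arrangement label."""

    points: np.ndarray
    arrangement: str

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        object.__setattr__(self, "points", pts)
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"arrangement must be one of {ARRANGEMENTS}")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def to_dataframe(self, trial_id: int = 0) -> pd.DataFrame:
        """Long-format export: one row per dot."""
        return pd.DataFrame(
            {
                "trial_id": trial_id,
                "dot_index": np.arange(self.n),
                "x_deg": self.points[:, 0],
                "y_deg": self.points[:, 1],
                "arrangement": self.arrangement,
                "n": self.n,
            }
        )


def _in_exclusion(x: float, y: float, geom: FieldGeometry) -> bool:
    # Rectangle inflated by the dot radius: dot *extents* stay clear of it.
    return (
        abs(x) < geom.exclusion_width / 2 + geom.dot_radius
        and abs(y) < geom.exclusion_height / 2 + geom.dot_radius
    )


def _draw_in_disc(rng: np.random.Generator, radius: float) -> tuple[float, float]:
    r = radius * math.sqrt(rng.random())
    theta = 2 * math.pi * rng.random()
    return r * math.cos(theta), r * math.sin(theta)


def _too_close(x: float, y: float, accepted: list[tuple[float, float]], d_min: float) -> bool:
    d2 = d_min * d_min
    for ax, ay in accepted:
        dx, dy = x - ax, y - ay
        if dx * dx + dy * dy < d2:
            return True
    return False


def sample_random_array(
    n: int,
    geom: FieldGeometry = FieldGeometry(),
    rng: np.random.Generator | None = None,
    max_attempts: int = 10_000,
) -> DotArray:
    """Draw ``n`` dots uniformly over the admissible region by rejection.

    Raises
    ------
    PlacementError
        If any dot cannot be placed within ``max_attempts`` proposals,
        signalling an infeasible dot density for this geometry.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    pts: list[tuple[float, float]] = []
    for i in range(n):
        for _ in range(max_attempts):
            x, y = _draw_in_disc(rng, geom.placement_radius)
            if _in_exclusion(x, y, geom):
                continue
            if _too_close(x, y, pts, geom.min_center_distance):
                continue
            pts.append((x, y))
            break
        else:
            raise PlacementError(
                f"could not place dot {i + 1}/{n} after {max_attempts} attempts"
            )
    return DotArray(points=np.array(pts), arrangement="random")


def sample_symmetric_array(
    n: int,
    geom: FieldGeometry = FieldGeometry(),
    rng: np.random.Generator | None = None,
    max_attempts: int = 10_000,
) -> DotArray:
    """Draw a vertically mirror-symmetric array.

    ``floor(n/2)`` dots are drawn in the left half-plane (kept at least half
    the minimum centre distance from the axis so a dot and its mirror never
    collide) and reflected about x = 0.  For odd ``n`` one unpaired dot is
    placed exactly on the symmetry axis, outside the exclusion zone.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    half_margin = geom.min_center_distance / 2
    pts: list[tuple[float, float]] = []
    n_pairs = n // 2
    for i in range(n_pairs):
        for _ in range(max_attempts):
            x, y = _draw_in_disc(rng, geom.placement_radius)
            if x > -half_margin:
                continue
            if _in_exclusion(x, y, geom):
                continue
            # Checking against all accepted points (mirrors included) also
            # guarantees the mirror partner's separations by symmetry.
            if _too_close(x, y, pts, geom.min_center_distance):
                continue
            pts.append((x, y))
            pts.append((-x, y))
            break
        else:
            raise PlacementError(
                f"could not place mirror pair {i + 1}/{n_pairs} after {max_attempts} attempts"
            )
    if n % 2 == 1:
        y_min = geom.exclusion_height / 2 + geom.dot_radius
        for _ in range(max_attempts):
            y = rng.uniform(-geom.placement_radius, geom.placement_radius)
            if abs(y) < y_min:
                continue
            if _too_close(0.0, y, pts, geom.min_center_distance):
                continue
            pts.append((0.0, y))
            break
        else:
            raise PlacementError("could not place the on-axis dot")
    return DotArray(points=np.array(pts), arrangement="symmetric")


def convex_hull_area(array: DotArray) -> float:
    """Area (deg^2) of the convex hull of dot centres; 0 for degenerate sets."""
    pts = array.points
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # "volume" is area in 2-D
    except QhullError:
        return 0.0  # collinear points span zero area


@dataclass(frozen=True)
class Violation:
    """One violated placement constraint, for auditing generated arrays."""

    kind: str  # out_of_field | in_exclusion | pair_too_close | asymmetric
    detail: str


def validate_array(
    array: DotArray, geom: FieldGeometry = FieldGeometry(), tol: float = 1e-9
) -> list[Violation]:
    """Check every placement invariant; empty list means the array is valid."""
    out: list[Violation] = []
    pts = array.points
    radii = np.hypot(pts[:, 0], pts[:, 1])
    for i in np.nonzero(radii > geom.placement_radius + tol)[0]:
        out.append(Violation("out_of_field", f"dot {i} at radius {radii[i]:.4f}"))
    for i, (x, y) in enumerate(pts):
        if (
            abs(x) < geom.exclusion_width / 2 + geom.dot_radius - tol
            and abs(y) < geom.exclusion_height / 2 + geom.dot_radius - tol
        ):
            out.append(Violation("in_exclusion", f"dot {i} at ({x:.3f}, {y:.3f})"))
    d_min = geom.min_center_distance
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.hypot(*(pts[i] - pts[j]))
            if d < d_min - tol:
                out.append(
                    Violation("pair_too_close", f"dots {i},{j} at distance {d:.4f}")
                )
    if array.arrangement == "symmetric":
        mirrored = pts * np.array([-1.0, 1.0])
        unmatched = _unmatched_count(pts, mirrored, tol=max(tol, 1e-9))
        if unmatched:
            out.append(
                Violation("asymmetric", f"{unmatched} dot(s) without a mirror partner")
            )
    return out


def _unmatched_count(a: np.ndarray, b: np.ndarray, tol: float) -> int:
    """Greedy multiset match between point sets a and b at tolerance tol."""
    remaining = list(range(len(b)))
    misses = 0
    for p in a:
        best, best_d = None, tol
        for idx in remaining:
            d = math.hypot(*(p - b[idx]))
            if d <= best_d:
                best, best_d = idx, d
        if best is None:
            misses += 1
        else:
            remaining.remove(best)
    return misses


def mean_hull_areas(
    numerosities: Iterable[int],
    n_arrays: int,
    geom: FieldGeometry = FieldGeometry(),
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Mean convex-hull area per arrangement over matched numerosities.

    Used to audit that symmetric and random arrays cover comparable spatial
    extents, so hull area cannot act as a numerosity cue differing between
    arrangements.
    """
    rng = np.random.default_rng() if rng is None else rng
    numerosities = list(numerosities)
    areas: dict[str, list[float]] = {"random": [], "symmetric": []}
    for i in range(n_arrays):
        n = numerosities[i % len(numerosities)]
        areas["random"].append(convex_hull_area(sample_random_array(n, geom, rng)))
        areas["symmetric"].append(convex_hull_area(sample_symmetric_array(n, geom, rng)))
    return {k: float(np.mean(v)) for k, v in areas.items()}
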