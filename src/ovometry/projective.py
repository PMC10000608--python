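"""Homogeneous 2-D projective geometry and the cross-ratio machinery.

Points and lines live in the real projective plane, represented by homogeneous
triples defined up to scale.  Image coordinates are 0-based pixels, x to the
right, y down, with pixel centers at integer coordinates.  An ideal point
(``h3 = 0``) represents a direction — e.g. the vanishing point of a family of
world-parallel lines when the camera is fronto-parallel to them.

The cross-ratio is the projective invariant of four collinear points and is
the basis of every length transfer in this package.  The ordering convention
is fixed once and for all::

    CR(p1, p2; p3, p4) = [d(p1,p3) * d(p2,p4)] / [d(p2,p3) * d(p1,p4)]

with *signed* distances measured along the common line.  Ideal points are
handled by the limit: each distance factor involving the (unique) ideal point
of the line cancels against its partner, so e.g. CR with p4 ideal reduces to
d(p1,p3)/d(p2,p3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    CollinearityError,
    DegenerateInputError,
    GeometryError,
    IdealPointError,
)

__all__ = [
    "PlanePoint",
    "PlaneLine",
    "join",
    "meet",
    "euclidean_distance",
    "cross_ratio",
    "ratio_with_possible_ideal",
]

#: relative tolerance used for "equal up to scale" and ideal-point tests
_SCALE_TOL = 1e-12
#: collinearity tolerance for cross-ratio inputs, |p . l| after max-abs
#: normalization of both point and line
COLLINEARITY_TOL = 1e-6


def _normalize_triple(v: np.ndarray) -> np.ndarray:
    """Rescale a homogeneous triple so its largest-magnitude entry is 1."""
    m = np.abs(v).max()
    if m == 0.0:
        raise DegenerateInputError("homogeneous triple is identically zero")
    return v / m


@dataclass(frozen=True)
class PlanePoint:
    """A point of the projective image plane in homogeneous coordinates."""

    h1: float
    h2: float
    h3: float

    def __post_init__(self) -> None:
        if self.h1 == 0.0 and self.h2 == 0.0 and self.h3 == 0.0:
            raise DegenerateInputError("(0, 0, 0) is not a projective point")
        if not all(math.isfinite(c) for c in (self.h1, self.h2, self.h3)):
            raise DegenerateInputError("homogeneous coordinates must be finite")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_xy(cls, x: float, y: float) -> "PlanePoint":
        """Finite image point at pixel coordinates (x, y)."""
        return cls(float(x), float(y), 1.0)

    @classmethod
    def from_direction(cls, dx: float, dy: float) -> "PlanePoint":
        """Ideal point (point at infinity) in image direction (dx, dy)."""
        if dx == 0.0 and dy == 0.0:
            raise DegenerateInputError("direction vector must be nonzero")
        return cls(float(dx), float(dy), 0.0)

    @classmethod
    def from_array(cls, v) -> "PlanePoint":
        a = np.asarray(v, dtype=float).reshape(3)
        return cls(a[0], a[1], a[2])

    # -- basic queries -----------------------------------------------------
    def to_array(self) -> np.ndarray:
        return np.array([self.h1, self.h2, self.h3], dtype=float)

    @property
    def is_ideal(self) -> bool:
        v = self.to_array()
        return abs(self.h3) <= _SCALE_TOL * np.abs(v).max()

    @property
    def x(self) -> float:
        if self.is_ideal:
            raise IdealPointError("ideal point has no affine x coordinate")
        return self.h1 / self.h3

    @property
    def y(self) -> float:
        if self.is_ideal:
            raise IdealPointError("ideal point has no affine y coordinate")
        return self.h2 / self.h3

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])

    @property
    def direction(self) -> np.ndarray:
        """Unit direction vector of an ideal point."""
        if not self.is_ideal:
            raise GeometryError("finite point has no direction")
        d = np.array([self.h1, self.h2])
        return d / np.linalg.norm(d)

    def normalized(self) -> "PlanePoint":
        return PlanePoint.from_array(_normalize_triple(self.to_array()))

    def is_same(self, other: "PlanePoint", tol: float = 1e-9) -> bool:
        """Scale-invariant equality: the cross product of the triples is ~0."""
        a = _normalize_triple(self.to_array())
        b = _normalize_triple(other.to_array())
        return bool(np.linalg.norm(np.cross(a, b)) <= tol)


@dataclass(frozen=True)
class PlaneLine:
    """A line of the projective image plane: points p with l . p = 0."""

    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        if self.l1 == 0.0 and self.l2 == 0.0 and self.l3 == 0.0:
            raise DegenerateInputError("(0, 0, 0) is not a projective line")
        if not all(math.isfinite(c) for c in (self.l1, self.l2, self.l3)):
            raise DegenerateInputError("line coefficients must be finite")

    @classmethod
    def from_array(cls, v) -> "PlaneLine":
        a = np.asarray(v, dtype=float).reshape(3)
        return cls(a[0], a[1], a[2])

    def to_array(self) -> np.ndarray:
        return np.array([self.l1, self.l2, self.l3], dtype=float)

    @property
    def is_ideal_line(self) -> bool:
        v = self.to_array()
        m = np.abs(v).max()
        return abs(self.l1) <= _SCALE_TOL * m and abs(self.l2) <= _SCALE_TOL * m

    def normalized(self) -> "PlaneLine":
        return PlaneLine.from_array(_normalize_triple(self.to_array()))

    def is_same(self, other: "PlaneLine", tol: float = 1e-9) -> bool:
        a = _normalize_triple(self.to_array())
        b = _normalize_triple(other.to_array())
        return bool(np.linalg.norm(np.cross(a, b)) <= tol)

    def incidence_residual(self, p: PlanePoint) -> float:
        """|l . p| after max-abs normalization of both triples."""
        a = _normalize_triple(self.to_array())
        b = _normalize_triple(p.to_array())
        return float(abs(a @ b))

    def contains(self, p: PlanePoint, tol: float = COLLINEARITY_TOL) -> bool:
        return self.incidence_residual(p) <= tol


def join(p: PlanePoint, q: PlanePoint) -> PlaneLine:
    """Line through two distinct points (cross product of the triples)."""
    if p.is_same(q):
        raise DegenerateInputError("join of coincident points is undefined")
    v = np.cross(_normalize_triple(p.to_array()), _normalize_triple(q.to_array()))
    return PlaneLine.from_array(_normalize_triple(v))


def meet(m: PlaneLine, n: PlaneLine) -> PlanePoint:
    """Intersection point of two distinct lines (dual of :func:`join`).

    Parallel (but distinct) lines meet in an ideal point.
    """
    if m.is_same(n):
        raise DegenerateInputError("meet of identical lines is undefined")
    v = np.cross(_normalize_triple(m.to_array()), _normalize_triple(n.to_array()))
    return PlanePoint.from_array(_normalize_triple(v))


def euclidean_distance(p: PlanePoint, q: PlanePoint) -> float:
    """Unsigned pixel distance between two finite points."""
    if p.is_ideal or q.is_ideal:
        raise IdealPointError(
            "euclidean distance to an ideal point is undefined; "
            "use the ratio-limit form instead"
        )
    return float(np.linalg.norm(p.xy - q.xy))


def _line_through(points: list[PlanePoint]) -> PlaneLine:
    """Common line through a list of points, defined by the two best-separated
    finite members (or one finite member and the ideal direction)."""
    finite = [p for p in points if not p.is_ideal]
    ideal = [p for p in points if p.is_ideal]
    if len(finite) >= 2:
        # pick the farthest-apart finite pair for numerical stability
        best, pair = -1.0, None
        for i in range(len(finite)):
            for j in range(i + 1, len(finite)):
                d = float(np.linalg.norm(finite[i].xy - finite[j].xy))
                if d > best:
                    best, pair = d, (finite[i], finite[j])
        if best <= 0.0:
            raise DegenerateInputError("all finite points coincide")
        return join(*pair)
    if len(finite) == 1 and ideal:
        return join(finite[0], ideal[0])
    raise GeometryError("cannot define a common affine line from these points")


def _signed_params(points: list[PlanePoint], tol: float = COLLINEARITY_TOL):
    """Signed 1-D parameters of collinear points along their common line.

    Returns a list with a float parameter per finite point and ``None`` for
    the (at most one) ideal point.  The orientation is induced by the line
    direction; it is consistent across all returned parameters, so any
    cross-ratio built from differences is orientation-independent.
    """
    line = _line_through(points)
    for k, p in enumerate(points):
        if not line.contains(p, tol):
            raise CollinearityError(
                f"point {k} is off the common line "
                f"(residual {line.incidence_residual(p):.3g} > {tol:g})"
            )
    ideal_count = sum(p.is_ideal for p in points)
    if ideal_count > 1:
        raise GeometryError("at most one ideal point is supported on an affine line")
    # direction of the line l1*x + l2*y + l3 = 0 is (-l2, l1)
    u = np.array([-line.l2, line.l1])
    u = u / np.linalg.norm(u)
    origin = next(p for p in points if not p.is_ideal).xy
    return [None if p.is_ideal else float((p.xy - origin) @ u) for p in points]


def _check_distinct(points: list[PlanePoint], tol: float = 1e-9) -> None:
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if points[i].is_same(points[j], tol):
                raise DegenerateInputError(f"points {i} and {j} coincide")


def cross_ratio(
    p1: PlanePoint,
    p2: PlanePoint,
    p3: PlanePoint,
    p4: PlanePoint,
    collinearity_tol: float = COLLINEARITY_TOL,
) -> float:
    """Signed cross-ratio CR(p1,p2;p3,p4) of four collinear points.

    CR = [d(p1,p3) * d(p2,p4)] / [d(p2,p3) * d(p1,p4)] with signed distances
    along the common line; invariant under any projective transform of the
    line.  If one of the points is ideal the two factors containing it cancel
    to 1 in the limit (it is the same point at infinity in both).
    """
    pts = [p1, p2, p3, p4]
    _check_distinct(pts)
    t = _signed_params(pts, collinearity_tol)

    def factor(i: int, j: int):
        # signed distance t_i - t_j, or None when the pair straddles infinity
        if t[i] is None or t[j] is None:
            return None
        return t[i] - t[j]

    num = [factor(0, 2), factor(1, 3)]
    den = [factor(1, 2), factor(0, 3)]
    n_inf_num = num.count(None)
    n_inf_den = den.count(None)
    # the ideal point appears once in num and once in den (any position of the
    # single ideal point yields exactly one infinite factor on each side)
    if n_inf_num != n_inf_den:  # pragma: no cover - unreachable with one ideal
        raise GeometryError("unbalanced ideal factors in cross-ratio")
    num_val = math.prod(f for f in num if f is not None)
    den_val = math.prod(f for f in den if f is not None)
    if den_val == 0.0:
        raise DegenerateInputError("cross-ratio denominator vanishes")
    return num_val / den_val


def ratio_with_possible_ideal(g: PlanePoint, f: PlanePoint, a: PlanePoint) -> float:
    """Signed ratio d(g,f)/d(g,a) along the common line, with the limit 1 when
    g is ideal (a point at infinity is equidistant, in the ratio sense, from
    every finite point of its line)."""
    if f.is_ideal or a.is_ideal:
        raise IdealPointError("f and a must be finite")
    if g.is_ideal:
        return 1.0
    if g.is_same(a):
        raise DegenerateInputError("g coincides with a; ratio undefined")
    t = _signed_params([g, f, a])
    return (t[0] - t[1]) / (t[0] - t[2])
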