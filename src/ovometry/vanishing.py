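"""Robust vanishing-point estimation from crossed-parallel reference cards.

World-parallel lines image to a pencil of lines through a common vanishing
point; the vanishing line of a world plane joins the vanishing points of two
independent in-plane directions.  The estimator here is a single-pencil
MLESAC: hypotheses are generated by intersecting the support lines of two
sampled segments, and scored with a truncated-quadratic (robust) residual —
the perpendicular distance from a segment's endpoints to the line joining the
candidate point and the segment midpoint.  The best hypothesis is refined by
direct minimization of the robust score.

The 90-degree frame rotation used to measure the vertical axis is the
*clockwise* rotation of the raster: pixel (x, y) of an H-row image maps to
(H - 1 - y, x) in the rotated frame (pixel centers, 0-based), and directions
rotate by (dx, dy) -> (-dy, dx).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError
from .projective import PlaneLine, PlanePoint, join

__all__ = [
    "LineSegment",
    "VanishingGeometry",
    "estimate_vanishing_point",
    "build_vanishing_line",
    "card_segments_from_mask",
    "rotate_frame_90",
]


@dataclass(frozen=True)
class LineSegment:
    """A finite straight stroke in the image, given by its two endpoints."""

    p_start: PlanePoint
    p_end: PlanePoint

    def __post_init__(self) -> None:
        if self.p_start.is_ideal or self.p_end.is_ideal:
            raise DegenerateInputError("segment endpoints must be finite")
        if self.p_start.is_same(self.p_end):
            raise DegenerateInputError("segment endpoints coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p_end.xy - self.p_start.xy))

    @property
    def midpoint(self) -> PlanePoint:
        m = 0.5 * (self.p_start.xy + self.p_end.xy)
        return PlanePoint.from_xy(m[0], m[1])

    @property
    def direction(self) -> np.ndarray:
        d = self.p_end.xy - self.p_start.xy
        return d / np.linalg.norm(d)

    def support_line(self) -> PlaneLine:
        return join(self.p_start, self.p_end)


@dataclass
class VanishingGeometry:
    """Vanishing points of the two card directions and their joining line."""

    vp_left: PlanePoint
    vp_right: PlanePoint
    vline: PlaneLine
    inlier_fraction_left: float = 1.0
    inlier_fraction_right: float = 1.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "vp_left": list(self.vp_left.to_array()),
                "vp_right": list(self.vp_right.to_array()),
                "vline": list(self.vline.to_array()),
                "inliers": {
                    "left": self.inlier_fraction_left,
                    "right": self.inlier_fraction_right,
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "VanishingGeometry":
        d = json.loads(text)
        return cls(
            vp_left=PlanePoint.from_array(d["vp_left"]),
            vp_right=PlanePoint.from_array(d["vp_right"]),
            vline=PlaneLine.from_array(d["vline"]),
            inlier_fraction_left=d["inliers"]["left"],
            inlier_fraction_right=d["inliers"]["right"],
        )


def _point_line_distance(p: PlanePoint, line: PlaneLine) -> float:
    """Perpendicular pixel distance from a finite point to a line."""
    l = line.to_array()
    nrm = float(np.hypot(l[0], l[1]))
    if nrm == 0.0:
        return np.inf
    return abs(l[0] * p.x + l[1] * p.y + l[2]) / nrm


def _segment_residual(seg: LineSegment, candidate: PlanePoint) -> float:
    """Distance from the segment endpoints to the line (candidate, midpoint).

    The two endpoints are symmetric about the midpoint, so both are at the
    same distance from any line through the midpoint.
    """
    mid = seg.midpoint
    if candidate.is_same(mid):
        return 0.0
    return _point_line_distance(seg.p_start, join(candidate, mid))


def _all_parallel(segments, angle_tol: float = 1e-9):
    """Common direction if all segments are mutually parallel, else None."""
    d0 = segments[0].direction
    dirs = []
    for s in segments:
        d = s.direction
        if abs(d0[0] * d[1] - d0[1] * d[0]) > angle_tol:
            return None
        dirs.append(d if d @ d0 >= 0 else -d)
    d = np.mean(dirs, axis=0)
    return d / np.linalg.norm(d)


def estimate_vanishing_point(
    segments: list[LineSegment],
    max_iters: int = 500,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> tuple[PlanePoint, np.ndarray]:
    """MLESAC estimate of the common vanishing point of image segments.

    Parameters
    ----------
    segments : list of LineSegment
        Images of world-parallel strokes (at least two).
    max_iters : int
        Number of two-segment hypotheses to sample.
    noise_scale : float
        Expected endpoint noise in pixels; residuals are truncated at
        1.96 * noise_scale (the ~95% band of a Gaussian of that scale).
    seed : int
        RNG seed; the estimate is deterministic given the seed.

    Returns
    -------
    (PlanePoint, ndarray of bool)
        The vanishing point (ideal if the segments are mutually parallel)
        and a per-segment inlier flag.
    """
    if len(segments) < 2:
        raise InsufficientDataError("need at least 2 segments")
    common = _all_parallel(segments)
    if common is not None:
        vp = PlanePoint.from_direction(common[0], common[1])
        return vp, np.ones(len(segments), dtype=bool)

    rng = np.random.default_rng(seed)
    trunc = 1.96 * max(noise_scale, 1e-6)
    trunc2 = trunc * trunc

    n = len(segments)
    # homogeneous arrays for vectorized scoring
    starts = np.array([[s.p_start.x, s.p_start.y, 1.0] for s in segments])
    mids = np.array([[*s.midpoint.xy, 1.0] for s in segments])
    support = np.array([s.support_line().to_array() for s in segments])

    def residuals(cand: np.ndarray) -> np.ndarray:
        lines = np.cross(np.broadcast_to(cand, mids.shape), mids)
        num = np.abs(np.einsum("ij,ij->i", lines, starts))
        den = np.hypot(lines[:, 0], lines[:, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return r

    def score(cand: np.ndarray) -> tuple[float, np.ndarray]:
        r = residuals(cand)
        return float(np.minimum(r * r, trunc2).sum()), r <= trunc

    best_cand, best_score, best_inl = None, np.inf, None
    pairs_i = rng.integers(0, n, size=max_iters)
    pairs_j = rng.integers(0, n - 1, size=max_iters)
    pairs_j = np.where(pairs_j >= pairs_i, pairs_j + 1, pairs_j)
    for i, j in zip(pairs_i, pairs_j):
        cand = np.cross(support[i], support[j])
        m = np.abs(cand).max()
        if m < 1e-12:
            continue  # numerically identical support lines
        cand = cand / m
        sc, inl = score(cand)
        if sc < best_score:
            best_cand, best_score, best_inl = cand, sc, inl

    if best_cand is None:  # pragma: no cover - defensive
        raise InsufficientDataError("no valid two-segment hypothesis found")
    best_vp = PlanePoint.from_array(best_cand)

    # refinement: the exact residual is r_i = (l_i/2) * dist(v, line_i) /
    # |v - mid_i|, so the robust score is minimized by iteratively
    # reweighted least squares on the support-line distances, with
    # truncated segments dropped at each iteration
    if not best_vp.is_ideal and best_score > 0.0:
        norm_lines = support / np.hypot(support[:, 0], support[:, 1])[:, None]
        lens = np.array([s.length for s in segments])
        A = norm_lines[:, :2]
        b = -norm_lines[:, 2]
        v = best_vp.xy
        for _ in range(20):
            d_mid = np.maximum(np.linalg.norm(mids[:, :2] - v, axis=1), 1e-9)
            gain = lens / (2.0 * d_mid)
            resid = np.abs(A @ v - b) * gain
            w = gain**2
            w[resid > trunc] = 0.0
            if (w > 0).sum() < 2:
                break
            sw = np.sqrt(w)
            sol, *_ = np.linalg.lstsq(A * sw[:, None], b * sw, rcond=None)
            if not np.all(np.isfinite(sol)):
                break
            step = np.linalg.norm(sol - v)
            v = sol
            if step < 1e-10:
                break
        sc, inl = score(np.array([v[0], v[1], 1.0]))
        if sc < best_score:
            best_vp = PlanePoint.from_xy(v[0], v[1])
            best_score, best_inl = sc, inl

    return best_vp.normalized(), best_inl


def build_vanishing_line(vp_left: PlanePoint, vp_right: PlanePoint) -> PlaneLine:
    """Vanishing line through the two vanishing points.

    Two ideal inputs give the ideal line (0, 0, 1) — the fronto-parallel
    (affine camera) limit in which no world plane direction converges.
    """
    if vp_left.is_same(vp_right):
        raise DegenerateInputError("vanishing points coincide")
    return join(vp_left, vp_right)


def rotate_frame_90(
    p: PlanePoint, image_height: int, inverse: bool = False
) -> PlanePoint:
    """Map a point between the original and the clockwise-90°-rotated frame.

    Forward (original H-row frame -> rotated frame): (x, y) -> (H-1-y, x).
    With ``inverse=True`` the map (x', y') -> (y', H-1-x') is applied, where
    ``image_height`` is still the height of the *original* image; forward
    followed by inverse is the identity.  Ideal points transform through the
    linear part only: (dx, dy) -> (-dy, dx) forward, (dx, dy) -> (dy, -dx)
    inverse.
    """
    H = float(image_height)
    if p.is_ideal:
        dx, dy = p.h1, p.h2
        return (
            PlanePoint.from_direction(dy, -dx)
            if inverse
            else PlanePoint.from_direction(-dy, dx)
        )
    if inverse:
        return PlanePoint.from_xy(p.y, H - 1.0 - p.x)
    return PlanePoint.from_xy(H - 1.0 - p.y, p.x)


# ---------------------------------------------------------------------------
# stroke extraction from binary card masks
# ---------------------------------------------------------------------------

def _principal_segment(cols: np.ndarray, rows: np.ndarray) -> LineSegment:
    """Least-squares segment through a pixel cloud: PCA direction + extent."""
    pts = np.column_stack([cols, rows]).astype(float)
    c = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    d = vt[0]
    t = (pts - c) @ d
    p0 = c + t.min() * d
    p1 = c + t.max() * d
    return LineSegment(PlanePoint.from_xy(*p0), PlanePoint.from_xy(*p1))


def card_segments_from_mask(
    line_pattern_mask: np.ndarray, min_length: float = 15.0
) -> list[LineSegment]:
    """Extract straight strokes from a binary card mask.

    Strokes are peeled off one at a time: the strongest straight line in a
    Hough accumulator is located, pixels within a narrow band of it are
    collected (with one direction-refinement pass), fitted by total least
    squares, and removed; crossing strokes survive because each retains the
    bulk of its own pixels.  Strokes shorter than ``min_length`` pixels are
    discarded.
    """
    from skimage.transform import hough_line, hough_line_peaks

    mask = np.asarray(line_pattern_mask, dtype=bool)
    if mask.ndim != 2:
        raise DegenerateInputError("mask must be a 2-D raster")
    if not mask.any():
        raise InsufficientDataError("empty mask: no stroke pixels")

    remaining = mask.copy()
    theta = np.linspace(-np.pi / 2, np.pi / 2, 720, endpoint=False)
    segments: list[LineSegment] = []
    guard = 0
    while remaining.sum() >= min_length and guard < 200:
        guard += 1
        h, angles, dists = hough_line(remaining, theta=theta)
        peaks = hough_line_peaks(h, angles, dists, num_peaks=1)
        if len(peaks[0]) == 0:
            break
        angle, dist = peaks[1][0], peaks[2][0]
        # hough convention: x*cos(theta) + y*sin(theta) = dist  (x=col, y=row)
        rows, cols = np.nonzero(remaining)
        band = np.abs(cols * np.cos(angle) + rows * np.sin(angle) - dist) <= 2.0
        if band.sum() < 2:
            remaining[rows, cols] = False
            continue
        # refine the line on the banded pixels, then reselect a tighter band
        seg = _principal_segment(cols[band], rows[band])
        d = seg.direction
        nvec = np.array([-d[1], d[0]])
        c0 = seg.p_start.xy
        band = np.abs((np.column_stack([cols, rows]) - c0) @ nvec) <= 1.6
        if band.sum() < 2:
            remaining[rows, cols] = False
            continue
        seg = _principal_segment(cols[band], rows[band])
        remaining[rows[band], cols[band]] = False
        if seg.length >= min_length:
            segments.append(seg)
    if not segments:
        raise InsufficientDataError(
            f"no strokes of length >= {min_length} px found"
        )
    return segments
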