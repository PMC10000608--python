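"""Single-view length measurement by cross-ratio transfer.

Given one perspective image, the length of a world segment AB can be
recovered from the image of a parallel reference segment CD of known length
R, provided the vanishing line of a world plane parallel to both segments is
known.  Writing a, b, c, d for the image endpoints and l for the vanishing
line, the construction is:

* ``e``: intersection of line bd with l — the vanishing point of the world
  direction BD, so the world line through C in that direction is parallel
  to BD;
* ``f``: intersection of line ec with line ab — the image of the world point
  F = B + (C - D), i.e. the reference length laid off along AB from B
  (B, D, C, F form a parallelogram, so BF = DC = R);
* ``g``: intersection of line ab with l — the vanishing point of the AB
  direction (ideal, i.e. "at infinity", when AB is fronto-parallel).

The cross-ratio of (b, f, a, g) then transfers the known ratio BF : BA from
the world to the image::

    Z = R * [d(b,a) * d(g,f)] / [d(b,f) * d(g,a)]

with signed distances along line ab and the g-dependent factor equal to 1 in
the limit where g is ideal.

The module also implements the classical interplanar-distance chain for a
family of parallel world planes pi_r, pi_r', pi, pi' cut by image lines
through their common vanishing point geometry: from a known separation Zr
the camera standoff Zcr is found, transferred to Zc for a second plane, and
finally the unknown separation Z is recovered.  All three steps are pure
cross-ratio identities; the exact groupings and sign conventions used here
are validated against an analytic pinhole-camera oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import (
    DegenerateInputError,
    GeometryError,
    InconsistentConfigurationError,
    ParameterError,
)
from .projective import (
    PlaneLine,
    PlanePoint,
    join,
    meet,
    ratio_with_possible_ideal,
    _signed_params,
)

__all__ = [
    "MeasurementScene",
    "AxisMeasurement",
    "EggMeasurement",
    "transfer_projection_point",
    "measure_axis",
    "measure_axis_detail",
    "measure_egg",
    "interplanar_Zcr",
    "interplanar_Zc",
    "interplanar_Z",
]


@dataclass(frozen=True)
class MeasurementScene:
    """One single-view measurement problem.

    Attributes
    ----------
    egg_a, egg_b : PlanePoint
        Image endpoints of the measured segment AB (the egg axis).
    ref_c, ref_d : PlanePoint
        Image endpoints of the reference segment CD, world-parallel to AB.
    vline : PlaneLine
        Vanishing line of a world plane parallel to both segments.
    ref_length_R : float
        True world length of CD in millimetres.
    """

    egg_a: PlanePoint
    egg_b: PlanePoint
    ref_c: PlanePoint
    ref_d: PlanePoint
    vline: PlaneLine
    ref_length_R: float

    def __post_init__(self) -> None:
        if not self.ref_length_R > 0:
            raise ParameterError("reference length R must be positive")
        for name, p in (
            ("egg_a", self.egg_a),
            ("egg_b", self.egg_b),
            ("ref_c", self.ref_c),
            ("ref_d", self.ref_d),
        ):
            if p.is_ideal:
                raise GeometryError(f"{name} must be a finite image point")
        if self.egg_a.is_same(self.egg_b):
            raise DegenerateInputError("egg endpoints coincide")
        if self.ref_c.is_same(self.ref_d):
            raise DegenerateInputError("reference endpoints coincide")


@dataclass(frozen=True)
class AxisMeasurement:
    """Recovered axis length plus the intermediate construction for audit."""

    length_mm: float
    e: PlanePoint
    f: PlanePoint
    g: PlanePoint


@dataclass(frozen=True)
class EggMeasurement:
    major_mm: float
    minor_mm: float
    major_detail: AxisMeasurement
    minor_detail: AxisMeasurement


def transfer_projection_point(
    scene: MeasurementScene,
) -> tuple[PlanePoint, PlanePoint, PlanePoint]:
    """The (e, f, g) construction that lays the reference off along AB."""
    line_bd = join(scene.egg_b, scene.ref_d)
    if line_bd.is_same(scene.vline):
        raise GeometryError("intersection e undefined: bd lies on the vanishing line")
    e = meet(line_bd, scene.vline)
    line_ab = join(scene.egg_a, scene.egg_b)
    if e.is_same(scene.ref_c):
        raise GeometryError("intersection f undefined: e coincides with c")
    line_ec = join(e, scene.ref_c)
    if line_ec.is_same(line_ab):
        raise GeometryError("intersection f undefined: ec coincides with ab")
    f = meet(line_ec, line_ab)
    if f.is_ideal:
        raise GeometryError("intersection f is ideal: ec is parallel to ab")
    if line_ab.is_same(scene.vline):
        raise GeometryError("intersection g undefined: ab lies on the vanishing line")
    g = meet(line_ab, scene.vline)
    return e, f, g


def measure_axis_detail(scene: MeasurementScene) -> AxisMeasurement:
    """Recover the world length of AB, keeping the construction points."""
    e, f, g = transfer_projection_point(scene)
    if f.is_same(scene.egg_b):
        raise GeometryError("reference projects to zero length on ab (f == b)")
    # signed ratio d(b,a)/d(b,f) along line ab
    t = _signed_params([scene.egg_b, scene.egg_a, f])
    ratio_ba_bf = (t[0] - t[1]) / (t[0] - t[2])
    # d(g,f)/d(g,a), -> 1 when g is ideal
    ratio_gf_ga = ratio_with_possible_ideal(g, f, scene.egg_a)
    z = abs(scene.ref_length_R * ratio_ba_bf * ratio_gf_ga)
    return AxisMeasurement(length_mm=z, e=e, f=f, g=g)


def measure_axis(scene: MeasurementScene) -> float:
    """World length of the egg segment AB in millimetres."""
    return measure_axis_detail(scene).length_mm


def measure_egg(
    scene_major: MeasurementScene, scene_minor: MeasurementScene
) -> EggMeasurement:
    """Measure both egg axes; errors are re-raised naming the failing axis."""
    if scene_major is None:
        raise DegenerateInputError("major-axis scene is missing")
    if scene_minor is None:
        raise DegenerateInputError("minor-axis scene is missing")
    try:
        major = measure_axis_detail(scene_major)
    except Exception as exc:
        raise type(exc)(f"major axis: {exc}") from exc
    try:
        minor = measure_axis_detail(scene_minor)
    except Exception as exc:
        raise type(exc)(f"minor axis: {exc}") from exc
    return EggMeasurement(
        major_mm=major.length_mm,
        minor_mm=minor.length_mm,
        major_detail=major,
        minor_detail=minor,
    )


# ---------------------------------------------------------------------------
# interplanar distances for a family of parallel world planes
# ---------------------------------------------------------------------------

def _ratio(p: PlanePoint, q: PlanePoint, w: PlanePoint) -> float:
    """Signed d(p,w)/d(q,w) along the common line; 1 when w is ideal."""
    if w.is_ideal:
        return 1.0
    t = _signed_params([p, q, w])
    num, den = t[0] - t[2], t[1] - t[2]
    if den == 0.0:
        raise DegenerateInputError("ratio denominator vanishes (q == w)")
    return num / den


def interplanar_Zcr(
    r1: PlanePoint,
    r2: PlanePoint,
    v_pt: PlanePoint,
    cr_pt: PlanePoint,
    Zr: float,
) -> float:
    """Camera standoff from plane pi_r, from a known separation Zr.

    r1 and r2 image world points R1 (on pi_r) and R2 (on the parallel plane
    pi_r', separation Zr) lying on one world line; v_pt is the vanishing
    point of that line and cr_pt its intersection with the vanishing line of
    the plane family.  The signed cross-ratio identity gives

        Zr / Zcr = 1 - [d(r1,v) * d(r2,cr)] / [d(r2,v) * d(r1,cr)]

    where Zcr is the (signed) distance from the camera plane to pi_r,
    measured parallel to Zr.
    """
    if not Zr > 0:
        raise ParameterError("Zr must be positive")
    bracket = _ratio(r1, r2, v_pt) * _ratio(r2, r1, cr_pt)
    denom = 1.0 - bracket
    if abs(denom) < 1e-12:
        raise InconsistentConfigurationError(
            "bracket = 1: zero plane separation implied by the image points"
        )
    zcr = Zr / denom
    if zcr <= 0:
        raise InconsistentConfigurationError(
            "non-positive camera standoff: image points are inconsistent "
            "with the stated plane ordering"
        )
    return zcr


def interplanar_Zc(
    Zcr: float,
    s1: PlanePoint,
    s2: PlanePoint,
    cs_pt: PlanePoint,
    v_pt: PlanePoint,
) -> float:
    """Transfer the camera standoff from pi_r (known Zcr) to plane pi.

    s1 images a point S1 on pi_r and s2 a point S2 on pi, on one world line
    with vanishing point v_pt and vanishing-line intersection cs_pt.  The
    cross-ratio identity CR(s1, s2; cs, v) = Zcr/Zc yields

        Zc = Zcr * [d(s1,v) * d(s2,cs)] / [d(s1,cs) * d(s2,v)].

    (The grouping is fixed by the pinhole-camera oracle; coincident planes
    give Zc = Zcr.)
    """
    if not Zcr > 0:
        raise ParameterError("Zcr must be positive")
    if s1.is_same(s2):
        return Zcr  # coincident planes sampled at the same point
    cr = _ratio(s1, s2, cs_pt) * _ratio(s2, s1, v_pt)  # = Zcr / Zc
    if abs(cr) < 1e-12:
        raise GeometryError("degenerate distances in camera-standoff transfer")
    zc = Zcr / cr
    if zc <= 0:
        raise InconsistentConfigurationError("non-positive camera standoff for pi")
    return zc


def interplanar_Z(
    x_img: PlanePoint,
    xprime_img: PlanePoint,
    c_pt: PlanePoint,
    v_pt: PlanePoint,
    Zc: float,
) -> float:
    """Separation of planes pi and pi' from the camera standoff Zc of pi.

    x_img images X on pi, xprime_img images X' on pi' (same world line, with
    vanishing point v_pt and vanishing-line intersection c_pt).  The signed
    cross-ratio rho = [d(x,c) * d(x',v)] / [d(x',c) * d(x,v)] equals
    Zc / (Zc - Z), so

        Z = Zc * (1 - 1/rho).

    Coincident image points mean coincident planes (Z = 0); rho -> 0 (x' at
    the vanishing point) would put pi' at infinity and is rejected.
    """
    if not Zc > 0:
        raise ParameterError("Zc must be positive")
    if x_img.is_same(xprime_img):
        return 0.0
    rho = _ratio(x_img, xprime_img, c_pt) * _ratio(xprime_img, x_img, v_pt)
    if abs(rho) < 1e-12:
        raise InconsistentConfigurationError(
            "unbounded separation: x' lies at the vanishing point"
        )
    return abs(Zc * (1.0 - 1.0 / rho))
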