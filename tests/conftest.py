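"""Shared fixtures: the default synthetic scene, its render, and an oracle
generator for random interplanar-distance problems."""

from __future__ import annotations

import numpy as np
import pytest

from ovometry.projective import PlaneLine, PlanePoint, join
from ovometry.simulate import (
    CameraModel,
    default_scene,
    project,
    project_direction,
    render_scene,
)


@pytest.fixture(scope="session")
def scene():
    return default_scene()


@pytest.fixture(scope="session")
def rendered(scene):
    return render_scene(scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_interplanar_case(rng: np.random.Generator) -> dict:
    """A random pinhole camera viewing four parallel world planes, with all
    the image points the interplanar equations consume and the true world
    distances they must recover.

    Planes are normal to a random direction n; world lines crossing them
    carry the sampled points.  True distances are measured along n from the
    camera plane (the plane through the camera center parallel to the
    family).
    """
    while True:
        pos = np.array(
            [rng.uniform(-150, 150), rng.uniform(-520, -350), rng.uniform(60, 260)]
        )
        target = rng.uniform(-25, 25, size=3)
        cam = CameraModel.look_at(pos, target)
        n = -pos + rng.normal(0, 100, size=3)
        n = n / np.linalg.norm(n)
        # plane offsets along n (world origin side), camera plane at n.pos
        c_cam = float(n @ pos)
        c_pir = rng.uniform(-20, 20)
        Zcr = c_pir - c_cam
        if Zcr < 150:  # keep the family well in front of the camera
            continue
        Zr = rng.uniform(15, 45)
        c_pirp = c_pir - Zr  # pi_r' lies between pi_r and the camera
        Zsep = rng.uniform(10, 40)
        c_pi = c_pir + rng.uniform(-35, 35)
        Zc = c_pi - c_cam
        c_pip = c_pi - Zsep
        if Zc < 120:
            continue
        # in-plane basis for the vanishing line
        h = np.array([0, 0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0, 0])
        u1 = np.cross(n, h)
        u1 /= np.linalg.norm(u1)
        u2 = np.cross(n, u1)

        def line_points(base, w, offsets):
            # points where the line base + t*w crosses planes n.X = offset
            out = []
            for c in offsets:
                t = (c - n @ base) / (n @ w)
                out.append(base + t * w)
            return out

        try:
            vline = join(project_direction(cam, u1), project_direction(cam, u2))
            w1 = n + rng.normal(0, 0.3, size=3)
            R1, R2 = line_points(rng.uniform(-25, 25, 3), w1, [c_pir, c_pirp])
            r1, r2 = project(cam, R1), project(cam, R2)
            cr = _meet_line(r1, r2, vline)
            v1 = project_direction(cam, w1 / np.linalg.norm(w1))

            w2 = n + rng.normal(0, 0.3, size=3)
            S1, S2 = line_points(rng.uniform(-25, 25, 3), w2, [c_pir, c_pi])
            s1, s2 = project(cam, S1), project(cam, S2)
            cs = _meet_line(s1, s2, vline)
            v2 = project_direction(cam, w2 / np.linalg.norm(w2))

            w3 = n + rng.normal(0, 0.3, size=3)
            X, Xp = line_points(rng.uniform(-25, 25, 3), w3, [c_pi, c_pip])
            x, xp = project(cam, X), project(cam, Xp)
            c = _meet_line(x, xp, vline)
            v3 = project_direction(cam, w3 / np.linalg.norm(w3))
        except Exception:
            continue
        return {
            "camera": cam,
            "vline": vline,
            "r": (r1, r2, v1, cr),
            "s": (s1, s2, v2, cs),
            "x": (x, xp, v3, c),
            "Zr": Zr,
            "Zcr": Zcr,
            "Zc": Zc,
            "Z": Zsep,
        }


def _meet_line(p: PlanePoint, q: PlanePoint, line: PlaneLine) -> PlanePoint:
    from ovometry.projective import meet

    return meet(join(p, q), line)
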