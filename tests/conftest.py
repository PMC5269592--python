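"""Shared fixtures: synthetic heads, candidate grids and closed-form
sphere-landmark oracles."""

import math

import numpy as np
import pytest

from s3r import make_ellipsoid_head, make_sphere_head
from s3r.experiments import ground_truth_1020
from s3r.virtual_1020 import measure_105_grid

RADIUS = 90.0


@pytest.fixture(scope="session")
def sphere_head():
    return make_sphere_head(RADIUS)


@pytest.fixture(scope="session")
def sphere_grid(sphere_head):
    return measure_105_grid(sphere_head.surface, sphere_head.refs)


@pytest.fixture(scope="session")
def sphere_truth(sphere_head):
    return ground_truth_1020(sphere_head)


@pytest.fixture(scope="session")
def bumpy_ellipsoid_head():
    return make_ellipsoid_head(80, 95, 85, bump_amplitude=3.0, seed=11)


def sphere_point_sagittal(f: float, r: float = RADIUS) -> np.ndarray:
    """Point at arc fraction f of the Nz -> Iz great half-circle."""
    th = f * math.pi
    return np.array([0.0, r * math.cos(th), r * math.sin(th)])


def sphere_point_coronal(f: float, r: float = RADIUS) -> np.ndarray:
    """Point at arc fraction f of the AL -> AR great half-circle."""
    th = f * math.pi
    return np.array([-r * math.cos(th), 0.0, r * math.sin(th)])


def sphere_point_circumference(f: float, side: str, r: float = RADIUS) -> np.ndarray:
    """Point at arc fraction f of the Fpz -> Oz half-circumference (the 10 %
    ring at z = r sin 18 deg), left via T3 or right via T4."""
    z = r * math.sin(math.radians(18))
    rho = r * math.cos(math.radians(18))
    th = f * math.pi
    x = -rho * math.sin(th) if side == "left" else rho * math.sin(th)
    return np.array([x, rho * math.cos(th), z])


def circle_half_arc_point(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Midpoint of the short arc p1 -> p2 of the sphere circle cut by the
    plane through p1, p2, p3 (closed-form oracle for F3/F4, P3/P4)."""
    n = np.cross(p2 - p1, p3 - p1)
    n = n / np.linalg.norm(n)
    c = np.dot(p1, n) * n
    rho = np.linalg.norm(p1 - c)
    u = (p1 - c) / rho
    w = np.cross(n, u)
    a2 = math.atan2(np.dot(p2 - c, w), np.dot(p2 - c, u))
    return c + rho * (math.cos(a2 / 2) * u + math.sin(a2 / 2) * w)


def closed_form_sphere_landmarks(r: float = RADIUS) -> dict:
    """All 21 10/20 landmarks on a sphere of radius r, analytically."""
    lm = {}
    for name, f in zip(("Fpz", "Fz", "Cz", "Pz", "Oz"), (0.1, 0.3, 0.5, 0.7, 0.9)):
        lm[name] = sphere_point_sagittal(f, r)
    for name, f in zip(("T3", "C3", "C4", "T4"), (0.1, 0.3, 0.7, 0.9)):
        lm[name] = sphere_point_coronal(f, r)
    for name, f in zip(("Fp1", "F7", "T5", "O1"), (0.1, 0.3, 0.7, 0.9)):
        lm[name] = sphere_point_circumference(f, "left", r)
    for name, f in zip(("Fp2", "F8", "T6", "O2"), (0.1, 0.3, 0.7, 0.9)):
        lm[name] = sphere_point_circumference(f, "right", r)
    lm["F3"] = circle_half_arc_point(lm["F7"], lm["Fz"], lm["F8"])
    lm["F4"] = circle_half_arc_point(lm["F8"], lm["Fz"], lm["F7"])
    lm["P3"] = circle_half_arc_point(lm["T5"], lm["Pz"], lm["T6"])
    lm["P4"] = circle_half_arc_point(lm["T6"], lm["Pz"], lm["T5"])
    return lm


def random_rigid_motion(rng):
    """Random rotation matrix and translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-50, 50, size=3)
    return rot, t
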