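import numpy as np
import pytest

from ringdyn.synthetic_data import SyntheticSpec, generate_ensemble

RING_RADIUS = 1.39


def ideal_benzene(center=(0.0, 0.0, 0.0), normal=(0.0, 0.0, 1.0), phase_deg=0.0):
    """Regular hexagon of carbons, C-C 1.39 A, in the plane normal to `normal`.

    Vertex 0 is the ipso position, vertex 3 the para position.
    """
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    # in-plane orthonormal basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    ang = np.radians(60.0 * np.arange(6) + phase_deg)
    return np.asarray(center) + RING_RADIUS * (
        np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2
    )


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def torsion_oracle(a, b, c, d):
    """Independent plane-projection torsion, degrees in (-180, 180].

    Projects the outer bonds onto the plane perpendicular to the b->c axis
    and measures the signed angle between the projections — a construction
    independent of the cross-product-of-normals route in the package.
    """
    a, b, c, d = (np.asarray(p, float) for p in (a, b, c, d))
    axis = c - b
    axis = axis / np.linalg.norm(axis)
    u = (a - b) - ((a - b) @ axis) * axis
    v = (d - c) - ((d - c) @ axis) * axis
    ang = np.degrees(np.arctan2(np.cross(u, v) @ axis, u @ v))
    return 180.0 if np.isclose(ang, -180.0) else ang


@pytest.fixture
def stacked_pair():
    """Two identical parallel benzenes, face to face, 3.5 A apart."""
    r1 = ideal_benzene()
    r2 = ideal_benzene(center=(0.0, 0.0, 3.5))
    return r1, r2


@pytest.fixture
def small_ensemble():
    spec = SyntheticSpec(n_molecules=5, n_frames=40, seed=7)
    return generate_ensemble(spec, label="ct")
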