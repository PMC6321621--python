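import math

import numpy as np
import pytest

from twn.water_model import (
    HOH_ANGLE_DEG,
    OH_BOND_LENGTH,
    TIP3PParameters,
    WaterMolecule,
)


@pytest.fixture
def params() -> TIP3PParameters:
    return TIP3PParameters()


def ideal_water(water_id, o_pos, h1_dir, h2_ref=(0.0, 0.0, 1.0)) -> WaterMolecule:
    """Ideal rigid monomer: H1 along h1_dir, H2 in the (h1_dir, h2_ref) plane."""
    o = np.asarray(o_pos, dtype=float)
    d = np.asarray(h1_dir, dtype=float)
    d = d / np.linalg.norm(d)
    ref = np.asarray(h2_ref, dtype=float)
    m = ref - np.dot(ref, d) * d
    if np.linalg.norm(m) < 1e-8:
        ref = np.array([1.0, 0.0, 0.0] if abs(d[0]) < 0.9 else [0.0, 1.0, 0.0])
        m = ref - np.dot(ref, d) * d
    m = m / np.linalg.norm(m)
    ang = math.radians(HOH_ANGLE_DEG)
    h2_dir = math.cos(ang) * d + math.sin(ang) * m
    return WaterMolecule(
        water_id,
        o,
        o + OH_BOND_LENGTH * d,
        o + OH_BOND_LENGTH * h2_dir,
        check_geometry=False,
    )


def linear_dimer(r_oo: float = 2.75):
    """Canonical linear hydrogen-bonded dimer: donor O-H along the O-O axis.

    The donor sits at the origin donating its H1 toward the acceptor at
    (r_oo, 0, 0); the acceptor's bisector points away along +x with its
    hydrogens splayed symmetrically.
    """
    donor = ideal_water(0, (0.0, 0.0, 0.0), (1.0, 0.0, 0.0))
    half = math.radians(HOH_ANGLE_DEG) / 2.0
    o = np.array([r_oo, 0.0, 0.0])
    h1 = o + OH_BOND_LENGTH * np.array([math.cos(half), math.sin(half), 0.0])
    h2 = o + OH_BOND_LENGTH * np.array([math.cos(half), -math.sin(half), 0.0])
    acceptor = WaterMolecule(1, o, h1, h2, check_geometry=False)
    return donor, acceptor


def random_water(rng, water_id, box=20.0) -> WaterMolecule:
    o = rng.uniform(-box / 2, box / 2, size=3)
    d = rng.normal(size=3)
    while np.linalg.norm(d) < 1e-8:
        d = rng.normal(size=3)
    ref = rng.normal(size=3)
    return ideal_water(water_id, o, d, h2_ref=ref)


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix via QR with sign fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
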