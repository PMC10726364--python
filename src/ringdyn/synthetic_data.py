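"""Synthetic trajectory ensembles with exactly known switching ground truth.

Generates multi-molecule, multi-frame ensembles of rigid two-ring molecules
whose inter-ring torsion lambda follows a seeded Markov jump process and
whose distance ratio rho is geometrically programmed, so that every stage
of the descriptor/switching pipeline can be validated without running MD.

The lambda process per molecule: a uniform random start, then per frame
step, with probability ``switch_probability``, a jump whose magnitude is
drawn from ``jump_size_range`` (support at or above the switch threshold),
otherwise sub-threshold jitter from ``jitter_range`` (support strictly
below the threshold).  Because jump magnitudes stay below 180 degrees, the
circular frame-to-frame distance equals the applied step magnitude, so the
ground-truth switch count equals the number of jump events *exactly* under
the circular convention; under the literal convention the two can disagree
only at 0/360 seam crossings, which the ground truth tallies per molecule.

Geometry: each molecule is two ideal benzene hexagons (C-C 1.39 A).  The
ipso1->ipso2 axis defines the torsion axis; both para carbons lean towards
the opposite ring by a fixed template angle, and lambda is realized by the
azimuth of ring 2's para carbon about the axis.  The ipso-ipso separation
is then solved per frame so that rho = r_ipso/r_para matches the program
exactly at descriptor level.  A random per-molecule rigid rotation and a
translation grid place the molecules in space (descriptors are invariant
to rigid motion, so the programs survive placement exactly up to floating
point).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ringdyn.errors import GenerationError
from ringdyn.trajectory_io import AmideStateLabel, RingPairSelection, TrajectoryEnsemble

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_ensemble",
    "generate_state_family",
    "DEFAULT_STATE_PROBS",
]

RING_CC_BOND = 1.39  # ideal benzene C-C, Angstrom
RING_DIAMETER = 2.0 * RING_CC_BOND  # ipso-para across one ring

#: per-amide-state switch probabilities mirroring an inhomogeneous
#: four-state family with max/min ratio 7:4 (eta ground truth 1.75)
DEFAULT_STATE_PROBS = {"cc": 0.028, "ct": 0.016, "tc": 0.020, "tt": 0.016}

_RING_ATOM_NAMES = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
_MOL_SIZE = 12  # two six-carbon rings


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic ensemble.

    Defaults emulate the study layout: 25 molecules observed over 2500
    frames, switch threshold 20 degrees.  ``rho_program`` may be a scalar
    (constant rho), a per-frame array (n_frames,), or per-molecule,
    per-frame (n_molecules, n_frames).  ``lean_angle_deg`` sets how far the
    para carbons lean towards the opposite ring in the geometry template
    (controls which rho values are realizable; 60 degrees covers (0, 2]).
    """

    n_molecules: int = 25
    n_frames: int = 2500
    switch_probability: float = 0.02
    jump_size_range: tuple[float, float] = (25.0, 120.0)
    jitter_range: tuple[float, float] = (0.0, 5.0)
    threshold: float = 20.0
    rho_program: object = 0.9
    lean_angle_deg: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.switch_probability <= 1.0):
            raise ValueError(f"switch_probability must be in [0,1]: {self.switch_probability}")
        if self.jump_size_range[0] < self.threshold:
            raise ValueError(
                "jump support must lie at or above the threshold so ground-truth "
                f"switch counts are exact: {self.jump_size_range} vs {self.threshold}"
            )
        if self.jump_size_range[1] >= 180.0:
            raise ValueError("jump magnitudes must stay below 180 degrees")
        if self.jitter_range[1] >= self.threshold:
            raise ValueError(
                "jitter support must lie strictly below the threshold: "
                f"{self.jitter_range} vs {self.threshold}"
            )
        if self.n_frames < 2 or self.n_molecules < 1:
            raise ValueError("need n_frames >= 2 and n_molecules >= 1")


@dataclass
class GroundTruth:
    """Everything the generator knows about the ensemble it emitted."""

    lambda_program: np.ndarray  # (n_molecules, n_frames), wrapped degrees
    rho_program: np.ndarray  # (n_molecules, n_frames)
    jump_events: list[list[int]]  # per molecule, step indices of true jumps
    n_jumps: list[int]
    seam_disagreements: list[int]  # steps where literal/circular switch calls differ
    seed: int
    switch_probability: float = field(default=0.0)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "switch_probability": self.switch_probability,
            "n_jumps": self.n_jumps,
            "jump_events": self.jump_events,
            "seam_disagreements": self.seam_disagreements,
            "lambda_program": self.lambda_program.tolist(),
            "rho_program": self.rho_program.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# lambda / rho programs


def _lambda_programs(spec: SyntheticSpec, rng: np.random.Generator):
    m, f = spec.n_molecules, spec.n_frames
    lam0 = rng.uniform(0.0, 360.0, size=m)
    jump_mask = rng.random(size=(m, f - 1)) < spec.switch_probability
    jump_mag = rng.uniform(*spec.jump_size_range, size=(m, f - 1))
    jit_mag = rng.uniform(*spec.jitter_range, size=(m, f - 1))
    signs = rng.integers(0, 2, size=(m, f - 1)) * 2 - 1
    steps = np.where(jump_mask, jump_mag, jit_mag) * signs
    lam = np.concatenate(
        [lam0[:, None], lam0[:, None] + np.cumsum(steps, axis=1)], axis=1
    )
    lam %= 360.0
    return lam, jump_mask


def _rho_programs(spec: SyntheticSpec) -> np.ndarray:
    rho = np.asarray(spec.rho_program, dtype=float)
    m, f = spec.n_molecules, spec.n_frames
    if rho.ndim == 0:
        rho = np.full((m, f), float(rho))
    elif rho.shape == (f,):
        rho = np.broadcast_to(rho, (m, f)).copy()
    elif rho.shape != (m, f):
        raise ValueError(
            f"rho_program must be scalar, (n_frames,), or (n_molecules, n_frames); "
            f"got shape {rho.shape}"
        )
    if np.any(rho <= 0):
        raise GenerationError("rho program must be strictly positive")
    return rho


# ---------------------------------------------------------------------------
# geometry realization


def _solve_separation(rho: np.ndarray, lam_deg: np.ndarray, m_lean: float, q_perp: float):
    """Ipso-ipso distance d realizing rho at torsion lambda.

    With both para carbons leaning a distance ``m_lean`` along the axis
    towards the opposite ring and sitting ``q_perp`` off-axis,
    r_para^2 = (d - 2 m_lean)^2 + 2 q_perp^2 (1 - cos lambda), and rho =
    d / r_para gives a quadratic in d.  The smallest positive root is taken
    (the compact arrangement); no positive root means the requested rho is
    geometrically infeasible for this template.
    """
    k = 2.0 * q_perp**2 * (1.0 - np.cos(np.radians(lam_deg)))
    a = 1.0 - rho**2
    b = 4.0 * m_lean * rho**2
    c = -(rho**2) * (4.0 * m_lean**2 + k)

    d = np.empty_like(rho)
    near_linear = np.abs(a) < 1e-12
    if np.any(near_linear):
        d[near_linear] = (4.0 * m_lean**2 + k[near_linear]) / (4.0 * m_lean)
    quad = ~near_linear
    if np.any(quad):
        aq, bq, cq = a[quad], b[quad], c[quad]
        disc = bq**2 - 4.0 * aq * cq
        if np.any(disc < 0):
            raise GenerationError(
                "rho program infeasible for the geometry template (no real "
                "ipso separation); reduce rho or increase the lean angle"
            )
        sq = np.sqrt(disc)
        r1 = (-bq + sq) / (2.0 * aq)
        r2 = (-bq - sq) / (2.0 * aq)
        roots = np.stack([r1, r2])
        roots[roots <= 1e-9] = np.inf
        dq = roots.min(axis=0)
        if np.any(~np.isfinite(dq)):
            raise GenerationError(
                "rho program infeasible: no positive ipso separation exists"
            )
        d[quad] = dq
    return d


def _hexagon(center, e1, e2):
    """Six ring vertices from center and two in-plane unit vectors.

    Vertex 0 (ipso) lies at center + R*e1; vertex 3 (para) opposite.
    Broadcasts over leading dimensions of the inputs.
    """
    angles = np.radians(60.0 * np.arange(6))
    return (
        center[..., None, :]
        + RING_CC_BOND
        * (
            np.cos(angles)[:, None] * e1[..., None, :]
            + np.sin(angles)[:, None] * e2[..., None, :]
        )
    )


def _template_coordinates(lam: np.ndarray, rho: np.ndarray, lean_angle_deg: float):
    """Coordinates (M, F, 12, 3) realizing the lambda and rho programs."""
    m_mol, f = lam.shape
    beta = np.radians(lean_angle_deg)
    m_lean = RING_DIAMETER * np.sin(beta)  # axial lean of each para carbon
    q_perp = RING_DIAMETER * np.cos(beta)  # off-axis offset of each para
    if q_perp <= 1e-9 or m_lean <= 1e-9:
        raise GenerationError("lean angle must lie strictly between 0 and 90 degrees")

    d = _solve_separation(rho, lam, m_lean, q_perp)
    lam_r = np.radians(lam)

    zeros = np.zeros_like(d)
    ones = np.ones_like(d)

    # ring 1: fixed template; para1 = (m_lean, q_perp, 0)
    w1 = np.stack([m_lean * ones, q_perp * ones, zeros], axis=-1)
    ipso1 = np.zeros_like(w1)
    c1 = 0.5 * w1
    e1_1 = -w1 / RING_DIAMETER
    e2_1 = np.stack([zeros, zeros, -ones], axis=-1)
    ring1 = _hexagon(c1, e1_1, e2_1)

    # ring 2: ipso at (d,0,0); para azimuth about the x axis encodes lambda
    ipso2 = np.stack([d, zeros, zeros], axis=-1)
    w2 = np.stack(
        [-m_lean * ones, q_perp * np.cos(lam_r), q_perp * np.sin(lam_r)], axis=-1
    )
    c2 = ipso2 + 0.5 * w2
    e1_2 = -w2 / RING_DIAMETER
    e2_2 = np.stack([zeros, np.sin(lam_r), -np.cos(lam_r)], axis=-1)
    ring2 = _hexagon(c2, e1_2, e2_2)

    del ipso1  # implicit in ring1 vertex 0
    return np.concatenate([ring1, ring2], axis=-2)  # (M, F, 12, 3)


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrices from normalized quaternions."""
    quat = rng.normal(size=(n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    w, x, y, z = quat.T
    return np.stack(
        [
            np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x**2 + z**2), 2 * (y * z - x * w)], -1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x**2 + y**2)], -1),
        ],
        axis=-2,
    )


# ---------------------------------------------------------------------------
# public API


def generate_ensemble(
    spec: SyntheticSpec, label: AmideStateLabel | str | None = None
) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """Generate one labeled ensemble plus its exact ground truth.

    Deterministic given ``spec.seed``; the realized lambda and rho programs
    are reproduced by the descriptor pipeline to floating-point accuracy.
    """
    if isinstance(label, str):
        label = AmideStateLabel.from_short(label)
    rng = np.random.default_rng(spec.seed)
    lam, jump_mask = _lambda_programs(spec, rng)
    rho = _rho_programs(spec)
    coords = _template_coordinates(lam, rho, spec.lean_angle_deg)  # (M,F,12,3)

    # rigid placement: random rotation + grid translation per molecule
    rot = _random_rotations(spec.n_molecules, rng)
    coords = np.einsum("mij,mfaj->mfai", rot, coords)
    grid = np.stack(
        [
            20.0 * (np.arange(spec.n_molecules) % 5),
            20.0 * ((np.arange(spec.n_molecules) // 5) % 5),
            20.0 * (np.arange(spec.n_molecules) // 25),
        ],
        axis=-1,
    )
    coords += grid[:, None, None, :]

    # (M,F,12,3) -> (F, M*12, 3)
    coords = coords.transpose(1, 0, 2, 3).reshape(spec.n_frames, -1, 3)

    selections = [
        RingPairSelection(
            molecule_id=f"mol{m:03d}",
            ring1_ipso=0,
            ring1_para=3,
            ring2_ipso=6,
            ring2_para=9,
            ring1_residue_index=0,
            ring2_residue_index=1,
        )
        for m in range(spec.n_molecules)
    ]
    molecule_atom_indices = [
        np.arange(m * _MOL_SIZE, (m + 1) * _MOL_SIZE) for m in range(spec.n_molecules)
    ]
    atom_names = np.asarray(_RING_ATOM_NAMES * 2 * spec.n_molecules)
    resnames = np.asarray((["NFA"] * 6 + ["NFA"] * 6) * spec.n_molecules)
    resids = np.asarray(([1] * 6 + [2] * 6) * spec.n_molecules)

    ensemble = TrajectoryEnsemble(
        coordinates=coords,
        molecule_atom_indices=molecule_atom_indices,
        selections=selections,
        label=label,
        atom_names=atom_names,
        resnames=resnames,
        resids=resids,
    )

    # seam accounting: steps where the literal and circular switch calls differ
    dl = np.abs(np.diff(lam, axis=1))
    circ = np.minimum(dl, 360.0 - dl)
    disagree = (dl >= spec.threshold) != (circ >= spec.threshold)

    gt = GroundTruth(
        lambda_program=lam,
        rho_program=rho,
        jump_events=[np.flatnonzero(row).tolist() for row in jump_mask],
        n_jumps=jump_mask.sum(axis=1).astype(int).tolist(),
        seam_disagreements=disagree.sum(axis=1).astype(int).tolist(),
        seed=spec.seed,
        switch_probability=spec.switch_probability,
    )
    return ensemble, gt


def generate_state_family(
    base_spec: SyntheticSpec,
    state_probs: dict[str, float] | None = None,
) -> tuple[dict[str, tuple[TrajectoryEnsemble, GroundTruth]], float]:
    """Generate one ensemble per amide state with independent seeded streams.

    ``state_probs`` maps short amide labels to per-step switch
    probabilities (default mirrors an inhomogeneous 7:4:5:4 four-state
    family).  Returns (mapping label -> (ensemble, ground truth), the
    ground-truth eta = max(p)/min(p)).
    """
    probs = dict(state_probs or DEFAULT_STATE_PROBS)
    if len(probs) < 2:
        raise ValueError("a state family needs at least 2 amide states")
    ss = np.random.SeedSequence(base_spec.seed)
    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(len(probs))]

    family: dict[str, tuple[TrajectoryEnsemble, GroundTruth]] = {}
    for (short, p), child in zip(sorted(probs.items()), child_seeds):
        spec = replace(base_spec, switch_probability=p, seed=child)
        family[short] = generate_ensemble(spec, label=short)

    p_vals = np.asarray(list(probs.values()))
    if np.any(p_vals == 0) and np.any(p_vals > 0):
        warnings.warn("some states have zero switch probability: eta ground truth infinite")
        eta_truth = float("inf")
    else:
        eta_truth = float(p_vals.max() / p_vals.min()) if p_vals.min() > 0 else float("nan")
    return family, eta_truth
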