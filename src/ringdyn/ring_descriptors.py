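"""Per-frame geometric descriptors of aromatic side-chain alignment.

Two descriptors characterize the mutual arrangement of the two phenyl rings
carried by one molecule:

``rho``
    The ratio ``r_ipso / r_para`` of the ipso–ipso to para–para carbon
    distances between the rings.  For two rings stacked exactly face to
    face (ipso over ipso, para over para) the two distances are equal and
    ``rho = 1.0``.  ``rho > 1`` means the para carbons are closer than the
    ipso carbons.

``lambda``
    The dihedral angle para1–ipso1–ipso2–para2 about the ipso1–ipso2 axis,
    signed by the standard IUPAC torsion convention and then wrapped into
    [0, 360) by adding 360 degrees to any negative value.  Values near
    0/360 correspond to a syn arrangement of the para carbons; 180 degrees
    is the coplanar anti (zig-zag) arrangement.

All functions broadcast over leading array dimensions, so a whole
(frames,) or (frames, molecules) block is evaluated in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ringdyn.errors import DegenerateGeometryError

__all__ = [
    "DescriptorSeries",
    "compute_rho",
    "compute_lambda",
    "compute_series",
    "signed_lambda",
    "write_descriptor_table",
]

#: atoms below this squared-norm are treated as coincident/collinear
_DEGENERACY_TOL2 = 1e-16


@dataclass
class DescriptorSeries:
    """Per-molecule time series of the two alignment descriptors.

    Attributes
    ----------
    molecule_id : identifier carried through from the ensemble.
    rho : (n_frames,) dimensionless ratio, strictly positive.
    lam : (n_frames,) angle in degrees, wrapped into [0, 360).
    r_ipso, r_para : (n_frames,) distances in Angstrom.
    """

    molecule_id: str
    rho: np.ndarray
    lam: np.ndarray
    r_ipso: np.ndarray = field(repr=False, default=None)
    r_para: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.lam)


def _norm(v: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("...i,...i->...", v, v))


def compute_rho(p_ipso1, p_ipso2, p_para1, p_para2):
    """Ipso/para distance ratio between two rings.

    Parameters are the 3D positions (Angstrom) of the ipso and para carbons
    of ring 1 and ring 2; arrays broadcast over leading dimensions.

    Returns ``|ipso1 - ipso2| / |para1 - para2|``.

    Raises
    ------
    DegenerateGeometryError
        If the para carbons coincide (zero denominator).
    """
    p_ipso1, p_ipso2 = np.asarray(p_ipso1, float), np.asarray(p_ipso2, float)
    p_para1, p_para2 = np.asarray(p_para1, float), np.asarray(p_para2, float)
    r_ipso = _norm(p_ipso1 - p_ipso2)
    r_para = _norm(p_para1 - p_para2)
    if np.any(r_para == 0.0):
        raise DegenerateGeometryError("para carbons coincide: r_para = 0")
    return r_ipso / r_para


def compute_lambda(p_para1, p_ipso1, p_ipso2, p_para2):
    """Inter-ring dihedral para1–ipso1–ipso2–para2, wrapped to [0, 360).

    The signed torsion about the ipso1–ipso2 axis follows the IUPAC
    convention (positive clockwise looking from ipso1 towards ipso2); any
    negative value has 360 degrees added.  Broadcasts over leading
    dimensions; returns degrees.

    Raises
    ------
    DegenerateGeometryError
        If three consecutive defining atoms are collinear (the torsion is
        undefined), which indicates corrupt coordinates rather than any
        legitimate ring chemistry.
    """
    a = np.asarray(p_para1, float)
    b = np.asarray(p_ipso1, float)
    c = np.asarray(p_ipso2, float)
    d = np.asarray(p_para2, float)

    b1 = b - a
    b2 = c - b
    b3 = d - c

    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.einsum("...i,...i->...", n1, n1) < _DEGENERACY_TOL2) or np.any(
        np.einsum("...i,...i->...", n2, n2) < _DEGENERACY_TOL2
    ):
        raise DegenerateGeometryError(
            "collinear atoms among the four torsion-defining carbons"
        )

    b2n = _norm(b2)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", np.cross(n1, n2), b2 / b2n[..., None])
    lam = np.degrees(np.arctan2(y, x))
    # wrap rule: add a full turn to negative torsions
    lam = np.where(lam < 0.0, lam + 360.0, lam)
    # guard against fp landing exactly on 360
    lam = np.where(lam >= 360.0, lam - 360.0, lam)
    return lam


def signed_lambda(lam):
    """Map wrapped [0, 360) angles onto the display range (-180, 180]."""
    lam = np.asarray(lam, float)
    return np.where(lam > 180.0, lam - 360.0, lam)


def compute_series(ensemble) -> list[DescriptorSeries]:
    """Evaluate rho and lambda for every molecule at every frame.

    Parameters
    ----------
    ensemble : TrajectoryEnsemble
        Coordinates plus one resolved ring-pair selection per molecule.

    Returns one :class:`DescriptorSeries` per molecule, in molecule order.
    Deterministic given coordinates; degenerate geometries raise with
    frame/molecule context.
    """
    out: list[DescriptorSeries] = []
    coords = ensemble.coordinates
    for mol_idx in range(ensemble.n_molecules):
        ip1, pa1, ip2, pa2 = ensemble.global_ring_indices(mol_idx)
        try:
            rho = compute_rho(coords[:, ip1], coords[:, ip2], coords[:, pa1], coords[:, pa2])
            lam = compute_lambda(coords[:, pa1], coords[:, ip1], coords[:, ip2], coords[:, pa2])
        except DegenerateGeometryError as err:
            raise DegenerateGeometryError(
                f"molecule {ensemble.molecule_ids[mol_idx]!r}: {err}"
            ) from err
        r_ipso = _norm(coords[:, ip1] - coords[:, ip2])
        r_para = _norm(coords[:, pa1] - coords[:, pa2])
        out.append(
            DescriptorSeries(
                molecule_id=ensemble.molecule_ids[mol_idx],
                rho=rho,
                lam=lam,
                r_ipso=r_ipso,
                r_para=r_para,
            )
        )
    return out


def write_descriptor_table(series: list[DescriptorSeries], path) -> None:
    """Export descriptor series as TSV (molecule_id, frame, rho, lam, r_ipso, r_para)."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": s.molecule_id,
                    "frame": np.arange(len(s)),
                    "rho": s.rho,
                    "lam": s.lam,
                    "r_ipso": s.r_ipso,
                    "r_para": s.r_para,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(Path(path), sep="\t", index=False)
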