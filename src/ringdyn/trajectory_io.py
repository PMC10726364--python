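"""Trajectory ensemble I/O and ring-atom selection resolution.

Reads multi-frame coordinate files (multi-model PDB, XYZ, and any other
format MDAnalysis can open), partitions atoms into molecules, resolves the
four torsion-defining ring carbons per molecule, and assembles the labeled
:class:`TrajectoryEnsemble` the descriptor layer consumes.

Molecule partitioning:

* PDB — by chain identifier (falling back to segid), in first-appearance
  order; chain ordering is identical across frames.
* XYZ — by fixed atom-count blocks (XYZ carries no chain concept); the
  block size comes from the selection spec.

Ring-atom selection is template-driven: built-in templates cover the
benzyl-bearing peptoid residue (``NFA``/``NF``) and phenylalanine (``PHE``),
with ipso = the ring carbon bonded to the side-chain methylene (``CG`` in
PDB convention) and para = the carbon three ring bonds away (``CZ``).
Explicit atom names in a :class:`SelectionSpec` override the templates.

Coordinates are Angstrom throughout; atom indexing is 0-based internally
and 1-based only at format boundaries.  No periodic-boundary unwrapping is
performed — ingested trajectories must be pre-wrapped molecule-whole, and a
validation pass flags any ring whose ipso–para distance exceeds 3 Angstrom
(an intact six-ring has 2 x 1.39 = 2.78) as a broken molecule.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ringdyn.errors import FormatError, SelectionError, UsageError

__all__ = [
    "AmideStateLabel",
    "RingPairSelection",
    "SelectionSpec",
    "TrajectoryEnsemble",
    "read_ensemble",
    "write_ensemble",
    "BUILTIN_TEMPLATES",
]

#: residue name -> (ipso atom name, para atom name)
BUILTIN_TEMPLATES: dict[str, tuple[str, str]] = {
    "PHE": ("CG", "CZ"),
    "NFA": ("CG", "CZ"),
    "NF": ("CG", "CZ"),
}

#: intact-ring sanity bound on the ipso–para distance (Angstrom)
BROKEN_RING_DISTANCE = 3.0

_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass(frozen=True)
class AmideStateLabel:
    """Cis/trans assignment per tracked backbone amide bond.

    ``states`` is an ordered tuple over the backbone amide bonds, each
    element ``"cis"`` or ``"trans"``; the canonical short form joins the
    initials (``"ct"`` = cis first bond, trans second).
    """

    states: tuple[str, ...]

    def __post_init__(self):
        if not self.states:
            raise ValueError("amide state label needs at least one bond state")
        for s in self.states:
            if s not in ("cis", "trans"):
                raise ValueError(f"amide bond state must be 'cis' or 'trans', got {s!r}")

    @classmethod
    def from_short(cls, short: str) -> "AmideStateLabel":
        mapping = {"c": "cis", "t": "trans"}
        try:
            return cls(tuple(mapping[ch] for ch in short))
        except KeyError as err:
            raise ValueError(f"short amide label may use only 'c'/'t': {short!r}") from err

    @property
    def short(self) -> str:
        return "".join(s[0] for s in self.states)

    def __str__(self) -> str:
        return self.short


@dataclass(frozen=True)
class RingPairSelection:
    """The four torsion-defining carbons of one molecule's two phenyl rings.

    Atom indices are 0-based positions in the molecule's own atom list;
    ring 1 is the ring nearer the N-terminus (lower residue index).
    """

    molecule_id: str
    ring1_ipso: int
    ring1_para: int
    ring2_ipso: int
    ring2_para: int
    ring1_residue_index: int = 0
    ring2_residue_index: int = 1

    def __post_init__(self):
        idx = (self.ring1_ipso, self.ring1_para, self.ring2_ipso, self.ring2_para)
        if len(set(idx)) != 4:
            raise ValueError(f"{self.molecule_id}: ring atom indices must be distinct: {idx}")
        if any(i < 0 for i in idx):
            raise ValueError(f"{self.molecule_id}: negative atom index in {idx}")
        if not self.ring1_residue_index < self.ring2_residue_index:
            raise ValueError(
                f"{self.molecule_id}: ring 1 must precede ring 2 in sequence "
                f"({self.ring1_residue_index} !< {self.ring2_residue_index})"
            )


@dataclass
class SelectionSpec:
    """How to partition molecules and locate ring atoms.

    ``templates`` maps residue names to (ipso, para) atom names and extends
    the built-in templates.  ``grouping`` is ``"chain"`` (PDB) or
    ``"block"`` (XYZ, fixed ``block_size`` atoms per molecule).
    """

    templates: dict[str, tuple[str, str]] = field(default_factory=dict)
    grouping: str | None = None  # "chain" | "block"; None = infer from format
    block_size: int | None = None

    def resolved_templates(self) -> dict[str, tuple[str, str]]:
        merged = dict(BUILTIN_TEMPLATES)
        merged.update({k.upper(): tuple(v) for k, v in self.templates.items()})
        return merged

    @classmethod
    def from_yaml(cls, path) -> "SelectionSpec":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            templates={k: tuple(v) for k, v in (data.get("templates") or {}).items()},
            grouping=data.get("grouping"),
            block_size=data.get("block_size"),
        )


@dataclass
class TrajectoryEnsemble:
    """Coordinates for M molecules x F frames, tagged with an amide state.

    ``coordinates`` has shape (n_frames, n_atoms_total, 3) in Angstrom.
    ``molecule_atom_indices`` holds, per molecule, the global atom indices
    belonging to it (order-stable across frames).  ``selections`` carry
    molecule-local ring-atom indices.  ``frame_interval`` is metadata only.
    """

    coordinates: np.ndarray
    molecule_atom_indices: list[np.ndarray]
    selections: list[RingPairSelection]
    label: AmideStateLabel | None = None
    atom_names: np.ndarray | None = None
    resnames: np.ndarray | None = None
    resids: np.ndarray | None = None
    frame_interval: float = 1.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must have shape (n_frames, n_atoms, 3), "
                f"got {self.coordinates.shape}"
            )
        if len(self.selections) != len(self.molecule_atom_indices):
            raise ValueError("one RingPairSelection required per molecule")
        n_atoms = self.coordinates.shape[1]
        for sel, idx in zip(self.selections, self.molecule_atom_indices):
            idx = np.asarray(idx)
            if idx.max(initial=-1) >= n_atoms:
                raise ValueError(f"molecule {sel.molecule_id!r}: atom index out of range")
            for local in (sel.ring1_ipso, sel.ring1_para, sel.ring2_ipso, sel.ring2_para):
                if local >= len(idx):
                    raise ValueError(
                        f"molecule {sel.molecule_id!r}: ring atom {local} outside "
                        f"its {len(idx)}-atom molecule"
                    )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_atom_indices)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def molecule_ids(self) -> list[str]:
        return [sel.molecule_id for sel in self.selections]

    def global_ring_indices(self, mol_idx: int) -> tuple[int, int, int, int]:
        """Global atom indices (ipso1, para1, ipso2, para2) for one molecule."""
        sel = self.selections[mol_idx]
        atoms = self.molecule_atom_indices[mol_idx]
        return (
            int(atoms[sel.ring1_ipso]),
            int(atoms[sel.ring1_para]),
            int(atoms[sel.ring2_ipso]),
            int(atoms[sel.ring2_para]),
        )

    def validate(self) -> list[str]:
        """Flag broken molecules: intra-ring ipso–para distance > 3 Angstrom."""
        issues: list[str] = []
        for m in range(self.n_molecules):
            ip1, pa1, ip2, pa2 = self.global_ring_indices(m)
            for ring, (a, b) in (("ring1", (ip1, pa1)), ("ring2", (ip2, pa2))):
                d = np.linalg.norm(
                    self.coordinates[:, a] - self.coordinates[:, b], axis=1
                )
                if np.any(d > BROKEN_RING_DISTANCE):
                    issues.append(
                        f"molecule {self.molecule_ids[m]!r} {ring}: ipso-para "
                        f"distance up to {d.max():.2f} A exceeds "
                        f"{BROKEN_RING_DISTANCE} A (broken molecule?)"
                    )
        return issues


# ---------------------------------------------------------------------------
# reading


def _load_universe(topology_source, trajectory_source):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDA guesses masses/elements noisily
        if trajectory_source is None or str(trajectory_source) == str(topology_source):
            return mda.Universe(str(topology_source))
        return mda.Universe(str(topology_source), str(trajectory_source))


def _partition_molecules(u, spec: SelectionSpec, path: Path) -> list[np.ndarray]:
    grouping = spec.grouping
    if grouping is None:
        grouping = "block" if path.suffix.lower() == ".xyz" else "chain"
    n_atoms = len(u.atoms)
    if grouping == "block":
        size = spec.block_size or n_atoms
        if n_atoms % size:
            raise FormatError(
                f"{path}: {n_atoms} atoms not divisible by block_size={size}"
            )
        return [np.arange(i, i + size) for i in range(0, n_atoms, size)]
    if grouping == "chain":
        keys = None
        for attr in ("chainIDs", "segids"):
            if hasattr(u.atoms, attr):
                vals = getattr(u.atoms, attr)
                if len(set(vals)) > 1 or (len(set(vals)) == 1 and str(list(vals)[0]).strip()):
                    keys = np.asarray(vals)
                    break
        if keys is None:
            return [np.arange(n_atoms)]
        groups: dict[str, list[int]] = {}
        order: list[str] = []
        for i, k in enumerate(keys):
            if k not in groups:
                groups[k] = []
                order.append(k)
            groups[k].append(i)
        return [np.asarray(groups[k]) for k in order]
    raise UsageError(f"unknown grouping {grouping!r}; use 'chain' or 'block'")


def _resolve_selection_chain(
    u, atoms_global: np.ndarray, mol_id: str, templates
) -> RingPairSelection:
    """Resolve via residue structure (PDB-like topologies)."""
    group = u.atoms[atoms_global]
    ring_residues = [r for r in group.residues if r.resname.upper() in templates]
    if len(ring_residues) != 2:
        raise SelectionError(
            f"molecule {mol_id!r}: expected exactly 2 phenyl-bearing residues, "
            f"found {len(ring_residues)} "
            f"({[r.resname for r in group.residues]}); extend the selection "
            f"templates if the residue name is nonstandard"
        )
    ring_residues.sort(key=lambda r: r.resid)
    local_of = {g: i for i, g in enumerate(atoms_global)}
    idx: list[int] = []
    for res in ring_residues:
        ipso_name, para_name = templates[res.resname.upper()]
        for name in (ipso_name, para_name):
            hits = [a.index for a in res.atoms if a.name == name]
            if len(hits) != 1:
                raise SelectionError(
                    f"molecule {mol_id!r}, residue {res.resname}{res.resid}: "
                    f"atom {name!r} resolved {len(hits)} times (need exactly 1)"
                )
            idx.append(local_of[hits[0]])
    return RingPairSelection(
        molecule_id=mol_id,
        ring1_ipso=idx[0],
        ring1_para=idx[1],
        ring2_ipso=idx[2],
        ring2_para=idx[3],
        ring1_residue_index=0,
        ring2_residue_index=1,
    )


def _resolve_selection_block(
    names: np.ndarray, mol_id: str, templates
) -> RingPairSelection:
    """Resolve by atom-name occurrence order within a fixed block (XYZ).

    The k-th occurrence of the ipso name pairs with the k-th occurrence of
    the para name; occurrence order along the block encodes sequence order
    (ring 1 = nearer the N-terminus = first occurrence).
    """
    name_pairs = set(templates.values())
    for ipso_name, para_name in name_pairs:
        ipso_hits = [i for i, n in enumerate(names) if n == ipso_name]
        para_hits = [i for i, n in enumerate(names) if n == para_name]
        if len(ipso_hits) == 2 and len(para_hits) == 2:
            return RingPairSelection(
                molecule_id=mol_id,
                ring1_ipso=ipso_hits[0],
                ring1_para=para_hits[0],
                ring2_ipso=ipso_hits[1],
                ring2_para=para_hits[1],
                ring1_residue_index=0,
                ring2_residue_index=1,
            )
    raise SelectionError(
        f"molecule {mol_id!r}: no template's ipso/para atom names occur "
        f"exactly twice among atoms {sorted(set(names))}"
    )


def read_ensemble(
    topology_source,
    trajectory_source=None,
    selection_spec: SelectionSpec | None = None,
    label: AmideStateLabel | str | None = None,
    frame_interval: float = 1.0,
) -> TrajectoryEnsemble:
    """Read a labeled multi-molecule trajectory ensemble.

    Parameters
    ----------
    topology_source
        Multi-model PDB, XYZ, or any topology MDAnalysis understands.
    trajectory_source
        Optional separate coordinate file (DCD/XTC/... via MDAnalysis);
        defaults to the topology file's own frames.
    selection_spec
        Molecule grouping and ring-atom templates; defaults resolve the
        built-in benzyl templates with format-inferred grouping.
    label
        Amide state as :class:`AmideStateLabel` or short string ("ct").
    """
    if isinstance(label, str):
        label = AmideStateLabel.from_short(label)
    spec = selection_spec or SelectionSpec()
    path = Path(topology_source)
    u = _load_universe(topology_source, trajectory_source)

    try:
        coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory]).astype(np.float64)
    except Exception as err:  # pragma: no cover - reader-specific failures
        raise FormatError(f"{path}: could not assemble frames: {err}") from err

    molecules = _partition_molecules(u, spec, path)
    templates = spec.resolved_templates()
    has_residue_names = hasattr(u.atoms, "resnames") and len(set(u.atoms.resnames)) >= 1 and not (
        path.suffix.lower() == ".xyz"
    )

    selections: list[RingPairSelection] = []
    for m, atom_idx in enumerate(molecules):
        mol_id = f"mol{m:03d}"
        if has_residue_names:
            selections.append(_resolve_selection_chain(u, atom_idx, mol_id, templates))
        else:
            names = np.asarray(u.atoms.names)[atom_idx]
            selections.append(_resolve_selection_block(names, mol_id, templates))

    ens = TrajectoryEnsemble(
        coordinates=coords,
        molecule_atom_indices=molecules,
        selections=selections,
        label=label,
        atom_names=np.asarray(u.atoms.names) if hasattr(u.atoms, "names") else None,
        resnames=np.asarray(u.atoms.resnames) if hasattr(u.atoms, "resnames") else None,
        resids=np.asarray(u.atoms.resids) if hasattr(u.atoms, "resids") else None,
        frame_interval=frame_interval,
    )
    issues = ens.validate()
    for msg in issues:
        warnings.warn(msg, stacklevel=2)
    return ens


# ---------------------------------------------------------------------------
# writing


def _build_universe(ensemble: TrajectoryEnsemble, element_style: str = "element"):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n_atoms = ensemble.n_atoms
    atom_mol = np.empty(n_atoms, dtype=int)
    for m, idx in enumerate(ensemble.molecule_atom_indices):
        atom_mol[idx] = m

    if ensemble.resids is not None and ensemble.resnames is not None:
        # one residue per unique (molecule, resid) pair, in atom order
        res_key = list(zip(atom_mol.tolist(), ensemble.resids.tolist()))
        uniq: list[tuple[int, int]] = []
        atom_res = np.empty(n_atoms, dtype=int)
        seen: dict[tuple[int, int], int] = {}
        for i, k in enumerate(res_key):
            if k not in seen:
                seen[k] = len(uniq)
                uniq.append(k)
            atom_res[i] = seen[k]
        resnames = [None] * len(uniq)
        resids = [None] * len(uniq)
        for i, r in enumerate(atom_res):
            resnames[r] = ensemble.resnames[i]
            resids[r] = int(ensemble.resids[i])
        res_mol = [k[0] for k in uniq]
    else:
        atom_res = atom_mol.copy()
        resnames = ["MOL"] * ensemble.n_molecules
        resids = list(range(1, ensemble.n_molecules + 1))
        res_mol = list(range(ensemble.n_molecules))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms,
            n_residues=len(resnames),
            n_segments=ensemble.n_molecules,
            atom_resindex=atom_res,
            residue_segindex=np.asarray(res_mol),
            trajectory=False,
        )
        names = (
            ensemble.atom_names
            if ensemble.atom_names is not None
            else np.asarray(["C"] * n_atoms)
        )
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", resids)
        if element_style == "name":
            # XYZ writers emit the element column; carry full atom names there
            u.add_TopologyAttr("elements", [str(n) for n in names])
        else:
            u.add_TopologyAttr("elements", [str(n)[0] for n in names])
        if ensemble.n_molecules > len(_CHAIN_ALPHABET):
            raise UsageError(
                f"multi-model PDB supports at most {len(_CHAIN_ALPHABET)} "
                f"chains; write XYZ for larger ensembles"
            )
        chains = [_CHAIN_ALPHABET[m] for m in range(ensemble.n_molecules)]
        u.add_TopologyAttr("segids", chains)
        u.add_TopologyAttr("chainIDs", [chains[m] for m in atom_mol])
        u.load_new(ensemble.coordinates.astype(np.float32), format=MemoryReader)
    return u


def write_ensemble(ensemble: TrajectoryEnsemble, destination, format: str | None = None) -> None:
    """Write an ensemble as multi-model PDB or XYZ.

    ``format`` is ``"pdb"`` or ``"xyz"``; inferred from the destination
    suffix when omitted.  The file is re-readable by :func:`read_ensemble`,
    reproducing coordinates to format precision (1e-3 Angstrom for PDB).
    """
    if ensemble.n_frames == 0:
        raise ValueError("cannot write an ensemble with zero frames")
    dest = Path(destination)
    fmt = (format or dest.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "xyz"):
        raise UsageError(f"unsupported format {fmt!r}; choose 'pdb' or 'xyz'")

    import MDAnalysis as mda

    u = _build_universe(ensemble, element_style="name" if fmt == "xyz" else "element")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "pdb":
            with mda.Writer(str(dest), n_atoms=ensemble.n_atoms, multiframe=True) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
        else:
            with mda.Writer(str(dest), n_atoms=ensemble.n_atoms) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
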