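"""Conformational ensembles of a single protein chain and per-frame geometry.

An :class:`Ensemble` couples a light-weight :class:`Topology` (residues, atoms,
backbone/side-chain roles) with an ``(n_frames, n_atoms, 3)`` coordinate array
in Å saved at a fixed time interval.  From it the module derives the geometric
primitives everything downstream consumes: backbone phi/psi dihedrals, amide
NH bond unit vectors, and mass-weighted radii of gyration.

File input goes through MDAnalysis, so any topology/trajectory pair it reads
(PDB, multi-model PDB, DCD, XTC, TRR) is accepted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: residue names treated as terminal caps (no dihedral/NH entries of their own)
CAP_RESIDUES = frozenset({"ACE", "NME", "NMA", "NHE"})

#: atom names assigned the backbone role (heavy atoms plus amide/alpha H)
BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HN", "H1", "H2", "H3", "HA", "HA2", "HA3"}
)

ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}


class EnsembleFormatError(ValueError):
    """Topology and coordinates disagree, or a file could not be interpreted."""


class EmptyEnsembleError(ValueError):
    """An ensemble with zero frames was supplied where frames are required."""


def element_from_name(name: str) -> str:
    """Guess the element from a PDB-style atom name."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise EnsembleFormatError(f"cannot infer element from atom name {name!r}")
    if stripped[:2].upper() in ("SE",) and len(stripped) > 1:
        return "SE"
    return stripped[0].upper()


@dataclass(frozen=True)
class Residue:
    """One residue: 1-based sequence index, 3-letter name, cap flag."""

    index: int
    name: str
    is_cap: bool = False


@dataclass(frozen=True)
class Atom:
    """One atom with its residue assignment and structural role."""

    name: str
    element: str
    mass: float
    residue_index: int
    role: str  # "backbone" | "sidechain" | "cap"


@dataclass
class Topology:
    """Chain identity: ordered residues and atoms with role annotations.

    Residue indices are contiguous and 1-based for the actual sequence; a
    leading ACE cap, when present, takes index 0 and a trailing NME cap takes
    ``n + 1`` so that protein numbering matches sequence positions.
    """

    chain_id: str
    residues: list[Residue]
    atoms: list[Atom]

    def __post_init__(self) -> None:
        indices = [r.index for r in self.residues]
        if indices != list(range(indices[0], indices[0] + len(indices))):
            raise EnsembleFormatError("residue indices must be contiguous")
        known = set(indices)
        for atom in self.atoms:
            if atom.residue_index not in known:
                raise EnsembleFormatError(
                    f"atom {atom.name} references unknown residue {atom.residue_index}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_cap]

    def residue(self, index: int) -> Residue:
        first = self.residues[0].index
        return self.residues[index - first]

    def residue_name(self, index: int) -> str:
        return self.residue(index).name

    def atom_index(self, residue_index: int, name: str) -> int | None:
        """Position of a named atom of a residue in the atom list, or None."""
        for i, atom in enumerate(self.atoms):
            if atom.residue_index == residue_index and atom.name == name:
                return i
        return None

    def atom_indices(self, residue_index: int, names=None, heavy_only=False) -> list[int]:
        out = []
        for i, atom in enumerate(self.atoms):
            if atom.residue_index != residue_index:
                continue
            if names is not None and atom.name not in names:
                continue
            if heavy_only and atom.element == "H":
                continue
            out.append(i)
        return out

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)


@dataclass
class Ensemble:
    """Topology plus ordered coordinate frames (Å) at a fixed interval (ps)."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3), Å
    frame_interval: float  # ps
    replicate: int | str = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise EnsembleFormatError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] == 0:
            raise EmptyEnsembleError("ensemble has zero frames")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise EnsembleFormatError(
                f"coordinate atom count {self.coordinates.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class DihedralSeries:
    """Backbone phi/psi per interior residue per frame, degrees in (-180, 180]."""

    residue_ids: list[int]
    phi: np.ndarray  # (n_frames, n_residues), degrees
    psi: np.ndarray
    frame_interval: float = 0.0  # ps; 0 when not tied to a time axis

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


@dataclass
class VectorSeries:
    """Amide NH bond unit vectors per non-proline residue per frame."""

    residue_ids: list[int]
    vectors: np.ndarray  # (n_frames, n_residues, 3), unit norm
    frame_interval: float  # ps

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.vectors, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("NH vectors must be unit norm (within 1e-6)")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]


def _role_for(atom_name: str, res_name: str) -> str:
    if res_name in CAP_RESIDUES:
        return "cap"
    return "backbone" if atom_name in BACKBONE_ATOMS else "sidechain"


def topology_from_universe(universe, chain_id: str = "A") -> Topology:
    """Build a :class:`Topology` from an MDAnalysis Universe (first segment)."""
    residues = []
    atoms = []
    res_list = list(universe.residues)
    # leading cap gets index 0 so the protein sequence is numbered from 1
    start = 0 if (res_list and res_list[0].resname.strip() in CAP_RESIDUES) else 1
    for offset, res in enumerate(res_list):
        resname = res.resname.strip()
        idx = start + offset
        residues.append(Residue(index=idx, name=resname, is_cap=resname in CAP_RESIDUES))
        for a in res.atoms:
            name = a.name.strip()
            element = getattr(a, "element", "") or element_from_name(name)
            element = element.upper()
            mass = float(a.mass) if a.mass > 0 else ELEMENT_MASSES.get(element, 0.0)
            atoms.append(
                Atom(
                    name=name,
                    element=element,
                    mass=mass,
                    residue_index=idx,
                    role=_role_for(name, resname),
                )
            )
    return Topology(chain_id=chain_id, residues=residues, atoms=atoms)


def load_ensemble(
    topology_source: str,
    coordinate_source: str | None = None,
    frame_interval: float = 20.0,
    replicate: int | str = 0,
) -> Ensemble:
    """Load an ensemble from a structure file and optional trajectory.

    Parameters
    ----------
    topology_source:
        PDB file defining residues and atoms.  A multi-model PDB may double
        as the coordinate source.
    coordinate_source:
        Trajectory file (DCD/XTC/TRR/multi-model PDB).  When omitted, frames
        are read from ``topology_source`` itself.
    frame_interval:
        Time between saved frames in ps.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if coordinate_source is None:
                universe = mda.Universe(topology_source)
            else:
                universe = mda.Universe(topology_source, coordinate_source)
    except (OSError, ValueError) as exc:
        raise EnsembleFormatError(f"could not load ensemble: {exc}") from exc

    topology = topology_from_universe(universe)
    frames = []
    try:
        for _ in universe.trajectory:
            frames.append(universe.atoms.positions.astype(float).copy())
    except (OSError, ValueError) as exc:
        raise EnsembleFormatError(f"trajectory/topology mismatch: {exc}") from exc
    if not frames:
        raise EmptyEnsembleError("no coordinate frames found")
    coords = np.stack(frames)
    return Ensemble(
        topology=topology,
        coordinates=coords,
        frame_interval=frame_interval,
        replicate=replicate,
        metadata={"topology_source": topology_source, "coordinate_source": coordinate_source},
    )


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Torsion angle (degrees, in (-180, 180]) for stacked coordinate arrays.

    Accepts arrays of shape ``(..., 3)``; the IUPAC sign convention is used
    (positive = clockwise rotation of the far bond viewed along p1->p2).
    """
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly to +180 so outputs live in (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


def backbone_dihedrals(ensemble: Ensemble) -> DihedralSeries:
    """Backbone phi/psi for every residue flanked by real residues.

    phi is the C'(i-1)-N-CA-C' torsion and psi the N-CA-C'-N(i+1) torsion.
    Residues adjacent only to a terminal cap (or to nothing) are absent, so a
    capped n-residue chain reports n - 2 interior residues.  A residue with a
    missing backbone atom yields NaN for that angle and is logged.
    """
    top = ensemble.topology
    protein = top.protein_residues
    interior = protein[1:-1]
    coords = ensemble.coordinates

    residue_ids: list[int] = []
    phi_cols: list[np.ndarray] = []
    psi_cols: list[np.ndarray] = []
    n_frames = ensemble.n_frames
    for res in interior:
        i = res.index
        idx_c_prev = top.atom_index(i - 1, "C")
        idx_n = top.atom_index(i, "N")
        idx_ca = top.atom_index(i, "CA")
        idx_c = top.atom_index(i, "C")
        idx_n_next = top.atom_index(i + 1, "N")
        residue_ids.append(i)
        if None in (idx_c_prev, idx_n, idx_ca, idx_c, idx_n_next):
            logger.warning("residue %d %s missing backbone atoms; dihedrals set to NaN", i, res.name)
            phi_cols.append(np.full(n_frames, np.nan))
            psi_cols.append(np.full(n_frames, np.nan))
            continue
        phi_cols.append(
            dihedral_angle(
                coords[:, idx_c_prev], coords[:, idx_n], coords[:, idx_ca], coords[:, idx_c]
            )
        )
        psi_cols.append(
            dihedral_angle(
                coords[:, idx_n], coords[:, idx_ca], coords[:, idx_c], coords[:, idx_n_next]
            )
        )
    phi = np.column_stack(phi_cols) if phi_cols else np.empty((n_frames, 0))
    psi = np.column_stack(psi_cols) if psi_cols else np.empty((n_frames, 0))
    return DihedralSeries(
        residue_ids=residue_ids, phi=phi, psi=psi, frame_interval=ensemble.frame_interval
    )


AMIDE_H_NAMES = ("H", "HN")


def nh_vectors(ensemble: Ensemble) -> VectorSeries:
    """Normalized amide H-N bond vectors for every non-proline residue.

    Prolines carry no amide hydrogen and are absent from the output; residues
    lacking an H atom (e.g. a free N-terminus without a single amide H) are
    skipped with a log message.
    """
    top = ensemble.topology
    coords = ensemble.coordinates
    residue_ids: list[int] = []
    vecs: list[np.ndarray] = []
    for res in top.protein_residues:
        if res.name == "PRO":
            continue
        idx_n = top.atom_index(res.index, "N")
        idx_h = None
        for hname in AMIDE_H_NAMES:
            idx_h = top.atom_index(res.index, hname)
            if idx_h is not None:
                break
        if idx_n is None or idx_h is None:
            logger.warning("residue %d %s lacks amide N-H; skipped", res.index, res.name)
            continue
        v = coords[:, idx_h] - coords[:, idx_n]
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        residue_ids.append(res.index)
        vecs.append(v)
    if not vecs:
        raise ValueError("no amide NH vectors could be extracted")
    return VectorSeries(
        residue_ids=residue_ids,
        vectors=np.stack(vecs, axis=1),
        frame_interval=ensemble.frame_interval,
    )


@dataclass
class RgSeries:
    """Per-frame mass-weighted radius of gyration with summary statistics."""

    values: np.ndarray  # (n_frames,), Å
    replicate: int | str = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values))


def radius_of_gyration(ensemble: Ensemble) -> RgSeries:
    """Mass-weighted radius of gyration per frame (Å)."""
    masses = ensemble.topology.masses
    if not np.any(masses > 0):
        raise ValueError("topology has no positive masses")
    w = masses / masses.sum()
    coords = ensemble.coordinates
    com = np.einsum("a,fax->fx", w, coords)
    delta = coords - com[:, None, :]
    rg2 = np.einsum("a,fax,fax->f", w, delta, delta)
    return RgSeries(values=np.sqrt(rg2), replicate=ensemble.replicate)
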