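"""Per-frame secondary-structure labels with a polyproline-II extension.

Standard DSSP states (from the Kabsch-Sander backbone hydrogen-bond
electrostatic model, -0.5 kcal/mol cutoff) are computed per frame via mdtraj.
Because PPII helices are not stabilized by backbone hydrogen bonds, DSSP
cannot see them; the extension reclassifies maximal runs of three or more
consecutive coil residues whose (phi, psi) fall in the PPII region of the
Ramachandran map as state ``P``.

Labels: H (alpha), G (3-10), I (pi), E (strand), B (bridge), T (turn),
S (bend), C (coil), P (PPII).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from idrdyn.ensemble import DihedralSeries, Ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "SSLabelSeries",
    "RamachandranRegion",
    "PPII_REGION",
    "kabsch_sander_labels",
    "ppii_reclassify",
    "ss_frequency_table",
]

#: DSSP states eligible for PPII reclassification ("coil-like")
COIL_STATES = frozenset({"C", "S"})

ALL_LABELS = ("H", "G", "I", "E", "B", "T", "S", "C", "P")


@dataclass(frozen=True)
class RamachandranRegion:
    """A rectangular (phi, psi) region in degrees, intervals inclusive."""

    phi: tuple[float, float]
    psi: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.phi, self.psi):
            if not (-180.0 <= lo < hi <= 180.0):
                raise ValueError("region bounds must satisfy -180 <= lo < hi <= 180")

    def contains(self, phi, psi) -> np.ndarray:
        phi = np.asarray(phi)
        psi = np.asarray(psi)
        return (
            (phi >= self.phi[0])
            & (phi <= self.phi[1])
            & (psi >= self.psi[0])
            & (psi <= self.psi[1])
        )


#: default PPII region; brackets the canonical (-75, 145) PPII point
PPII_REGION = RamachandranRegion(phi=(-110.0, -40.0), psi=(110.0, 180.0))


@dataclass
class SSLabelSeries:
    """One single-letter state per residue per frame."""

    residue_ids: list[int]
    labels: np.ndarray  # (n_frames, n_residues), dtype <U1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.labels.ndim != 2 or self.labels.shape[1] != len(self.residue_ids):
            raise ValueError("labels must be (n_frames, n_residues)")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


def _mdtraj_trajectory(ensemble: Ensemble):
    """Convert an Ensemble to an mdtraj Trajectory (coordinates nm)."""
    import mdtraj as md
    from mdtraj.core import element as md_element

    top = md.Topology()
    chain = top.add_chain()
    res_map = {}
    for res in ensemble.topology.residues:
        res_map[res.index] = top.add_residue(res.name, chain, resSeq=res.index)
    for atom in ensemble.topology.atoms:
        elem = md_element.get_by_symbol(atom.element.capitalize())
        top.add_atom(atom.name, elem, res_map[atom.residue_index])
    return md.Trajectory(xyz=ensemble.coordinates * 0.1, topology=top)


def kabsch_sander_labels(ensemble: Ensemble) -> SSLabelSeries:
    """Per-frame DSSP states for the non-cap residues of an ensemble.

    The amide hydrogen position is reconstructed internally from the
    preceding carbonyl geometry, as in the original algorithm, so explicit
    hydrogens are not required.  Residues the assignment cannot reach (e.g.
    chain termini in the Kabsch-Sander sense) are reported as coil.
    """
    import mdtraj as md

    traj = _mdtraj_trajectory(ensemble)
    raw = md.compute_dssp(traj, simplified=False)  # (n_frames, n_residues_all)
    keep = [i for i, r in enumerate(ensemble.topology.residues) if not r.is_cap]
    residue_ids = [ensemble.topology.residues[i].index for i in keep]
    labels = raw[:, keep].astype("<U1")
    labels[(labels == " ") | (labels == "") | (labels == "N")] = "C"
    return SSLabelSeries(residue_ids=residue_ids, labels=labels)


def ppii_reclassify(
    labels: SSLabelSeries,
    dihedrals: DihedralSeries,
    region: RamachandranRegion = PPII_REGION,
    min_run: int = 3,
    coil_states: frozenset = COIL_STATES,
) -> SSLabelSeries:
    """Reclassify runs of >= min_run in-region coil residues as PPII (``P``).

    Within each frame, a residue is *eligible* when its DSSP state is
    coil-like and its (phi, psi) lie in ``region``; every maximal run of at
    least ``min_run`` consecutive eligible residues becomes ``P``.  All other
    labels are untouched, so the operation is idempotent (``P`` itself is not
    an eligible state).
    """
    if labels.n_frames != dihedrals.n_frames:
        raise ValueError("labels and dihedrals must cover the same frames")
    out = labels.labels.copy()
    n_res = len(labels.residue_ids)
    col_of = {rid: j for j, rid in enumerate(dihedrals.residue_ids)}

    eligible = np.zeros((labels.n_frames, n_res), dtype=bool)
    for j, rid in enumerate(labels.residue_ids):
        k = col_of.get(rid)
        if k is None:
            continue  # no dihedrals (terminal residue): breaks any run
        in_region = region.contains(dihedrals.phi[:, k], dihedrals.psi[:, k])
        in_region &= ~np.isnan(dihedrals.phi[:, k])
        coil = np.isin(out[:, j], list(coil_states))
        eligible[:, j] = in_region & coil

    # run-length scan per frame: pad, diff, then select runs >= min_run
    padded = np.zeros((labels.n_frames, n_res + 2), dtype=np.int8)
    padded[:, 1:-1] = eligible
    d = np.diff(padded, axis=1)
    for f in range(labels.n_frames):
        starts = np.flatnonzero(d[f] == 1)
        ends = np.flatnonzero(d[f] == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_run:
                out[f, s:e] = "P"
    return SSLabelSeries(residue_ids=list(labels.residue_ids), labels=out)


def ss_frequency_table(labels: SSLabelSeries, aggregate: bool = True) -> pd.DataFrame:
    """Per-residue normalized frequency of each state (rows sum to 1).

    With ``aggregate`` (default), minor states are folded the way propensity
    plots usually report them: pi helix into H, isolated bridge B into E, and
    bend S into C.
    """
    if labels.n_frames < 1:
        raise ValueError("need at least one frame")
    data = labels.labels
    if aggregate:
        data = data.copy()
        data[data == "I"] = "H"
        data[data == "B"] = "E"
        data[data == "S"] = "C"
        columns = ("H", "G", "E", "T", "C", "P")
    else:
        columns = ALL_LABELS
    rows = {}
    for j, rid in enumerate(labels.residue_ids):
        counts = {c: float(np.mean(data[:, j] == c)) for c in columns}
        rows[rid] = counts
    table = pd.DataFrame.from_dict(rows, orient="index")[list(columns)]
    table.index.name = "residue"
    return table
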