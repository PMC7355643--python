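"""Residue-residue contact statistics and correlated-segment calling.

Two heavy atoms are in contact when they are within 3.5 Å; for each ordered
residue pair the *representative* frequency is the maximum over its atom-pair
frequencies (each atom pair's frequency is its fraction of frames in contact).
Side-chain/side-chain (SC-SC) and side-chain/backbone (SC-BB) maps feed:

- per-residue *nonlocal contact numbers* (mean representative frequency over
  all partners excluding the three nearest neighbours on each side),
- typed interaction events: salt bridges, cation-pi contacts (ring-centroid
  distance < 5 Å and axial angle < 60 degrees) and side-chain-to-backbone
  hydrogen bonds,
- *correlated segments*: maximal sequence intervals covering connected
  components of the graph of pairs with frequency above a threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from idrdyn.ensemble import Ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMap",
    "InteractionEvent",
    "Segment",
    "contact_frequency_map",
    "nonlocal_contact_number",
    "cation_pi_events",
    "saltbridge_hbond_events",
    "correlated_segments",
]

AROMATIC_RINGS = {
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

CATIONIC_GROUPS = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "LYS": ("NZ",),
}

ANIONIC_OXYGENS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

CATIONIC_NITROGENS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
}


@dataclass
class ContactMap:
    """Representative contact frequencies per ordered residue pair.

    ``frequencies[i, j]`` is indexed by position in ``residue_ids``.  For the
    symmetric SC-SC mode the matrix is symmetric; for SC-BB, row = side-chain
    owner and column = backbone owner.  ``atom_pair_frequencies`` optionally
    holds the underlying per-atom-pair values keyed by residue pair.
    """

    mode: str  # "sc-sc" | "sc-bb"
    residue_ids: list[int]
    frequencies: np.ndarray
    n_frames: int
    atom_pair_frequencies: dict = field(default_factory=dict)

    def frequency(self, res_i: int, res_j: int) -> float:
        pos = {r: k for k, r in enumerate(self.residue_ids)}
        return float(self.frequencies[pos[res_i], pos[res_j]])


def _residue_atom_groups(ensemble: Ensemble, role: str) -> dict[int, np.ndarray]:
    """Heavy-atom indices per non-cap residue for the given role."""
    groups: dict[int, list[int]] = {}
    for i, atom in enumerate(ensemble.topology.atoms):
        if atom.role != role or atom.element == "H":
            continue
        groups.setdefault(atom.residue_index, []).append(i)
    return {r: np.array(v) for r, v in groups.items()}


def contact_frequency_map(
    ensemble: Ensemble,
    mode: str = "sc-sc",
    cutoff: float = 3.5,
    representative: str = "max_pair",
) -> ContactMap:
    """Contact frequencies over frames for SC-SC or SC-BB heavy-atom pairs.

    ``representative="max_pair"`` (default) computes each atom pair's
    frequency first and takes the maximum over atom pairs of a residue pair;
    ``"any_atom"`` instead counts the fraction of frames in which *any* atom
    pair of the two residues is in contact.  Pairs within the same residue
    are excluded by construction.
    """
    if mode not in ("sc-sc", "sc-bb"):
        raise ValueError("mode must be 'sc-sc' or 'sc-bb'")
    if representative not in ("max_pair", "any_atom"):
        raise ValueError("representative must be 'max_pair' or 'any_atom'")
    sc = _residue_atom_groups(ensemble, "sidechain")
    residue_ids = [r.index for r in ensemble.topology.protein_residues]
    n = len(residue_ids)
    freqs = np.zeros((n, n))
    if not sc:
        warnings.warn("ensemble has no side-chain heavy atoms; contact map is empty",
                      stacklevel=2)
        return ContactMap(mode=mode, residue_ids=residue_ids, frequencies=freqs,
                          n_frames=ensemble.n_frames)
    other = sc if mode == "sc-sc" else _residue_atom_groups(ensemble, "backbone")

    coords = ensemble.coordinates
    pos = {r: k for k, r in enumerate(residue_ids)}
    pair_freqs: dict[tuple[int, int], np.ndarray] = {}
    for ri, idx_i in sc.items():
        for rj, idx_j in other.items():
            if rj == ri:
                continue
            if mode == "sc-sc" and rj < ri:
                continue  # symmetric; fill once
            # (frames, |i|, |j|) distance stack
            d = np.linalg.norm(
                coords[:, idx_i, None, :] - coords[:, None, idx_j, :], axis=-1
            )
            contact = d < cutoff
            if representative == "max_pair":
                f = float(contact.mean(axis=0).max())
            else:
                f = float(contact.any(axis=(1, 2)).mean())
            pair_freqs[(ri, rj)] = contact.mean(axis=0)
            freqs[pos[ri], pos[rj]] = f
            if mode == "sc-sc":
                freqs[pos[rj], pos[ri]] = f
    return ContactMap(
        mode=mode,
        residue_ids=residue_ids,
        frequencies=freqs,
        n_frames=ensemble.n_frames,
        atom_pair_frequencies=pair_freqs,
    )


def nonlocal_contact_number(
    cmap: ContactMap, exclusion: int = 3, ranges: list[tuple[int, int]] | None = None
) -> "np.ndarray | tuple":
    """Per-residue mean contact frequency over all non-neighbouring partners.

    For residue i the eligible partners are every other residue j with
    ``|i - j| > exclusion`` (the denominator counts all eligible partners,
    including those with zero frequency).  When ``ranges`` is given, also
    returns the mean of the per-residue values over each inclusive range.
    """
    ids = np.asarray(cmap.residue_ids)
    n = len(ids)
    if n < 2 * exclusion + 2:
        raise ValueError(f"chain of {n} residues too short for exclusion {exclusion}")
    values = np.empty(n)
    for k, i in enumerate(ids):
        mask = np.abs(ids - i) > exclusion
        values[k] = cmap.frequencies[k, mask].mean()
    if ranges is None:
        return values
    import pandas as pd

    series = pd.Series(values, index=ids)
    half_means = [
        float(series[(series.index >= lo) & (series.index <= hi)].mean())
        for lo, hi in ranges
    ]
    return values, half_means


@dataclass
class InteractionEvent:
    """A typed residue-pair interaction with per-frame occupancy."""

    kind: str  # "salt_bridge" | "cation_pi" | "scbb_hbond"
    residue_i: int
    residue_j: int
    per_frame: np.ndarray  # bool per frame
    frequency: float


def _com(coords: np.ndarray, indices: np.ndarray, masses: np.ndarray) -> np.ndarray:
    w = masses[indices]
    return np.einsum("a,fax->fx", w / w.sum(), coords[:, indices])


def cation_pi_events(
    ensemble: Ensemble, dist_cutoff: float = 5.0, angle_cutoff: float = 60.0
) -> list[InteractionEvent]:
    """Cation-pi contacts between aromatic rings and Arg/Lys cationic groups.

    An event requires the distance between the ring centre of mass and the
    cationic-group centre of mass to be below ``dist_cutoff`` Å and the angle
    between that connecting line and the ring normal below ``angle_cutoff``
    degrees (so the cation sits over the ring face, not in its plane).
    """
    top = ensemble.topology
    coords = ensemble.coordinates
    masses = top.masses
    events: list[InteractionEvent] = []
    aromatics = []
    cations = []
    for res in top.protein_residues:
        if res.name in AROMATIC_RINGS:
            idx = top.atom_indices(res.index, names=set(AROMATIC_RINGS[res.name]))
            if len(idx) != len(AROMATIC_RINGS[res.name]):
                logger.warning("residue %d %s missing ring atoms; skipped", res.index, res.name)
                continue
            aromatics.append((res.index, np.array(idx)))
        if res.name in CATIONIC_GROUPS:
            idx = top.atom_indices(res.index, names=set(CATIONIC_GROUPS[res.name]))
            if not idx:
                logger.warning("residue %d %s missing cationic atoms; skipped", res.index, res.name)
                continue
            cations.append((res.index, np.array(idx)))

    for ring_res, ring_idx in aromatics:
        ring_com = _com(coords, ring_idx, masses)
        ring_atoms = coords[:, ring_idx] - ring_com[:, None, :]
        # ring normal from a per-frame plane fit (smallest singular vector)
        normals = np.empty((ensemble.n_frames, 3))
        for f in range(ensemble.n_frames):
            _, _, vt = np.linalg.svd(ring_atoms[f], full_matrices=False)
            normals[f] = vt[-1]
        for cat_res, cat_idx in cations:
            if cat_res == ring_res:
                continue
            cat_com = _com(coords, cat_idx, masses)
            sep = cat_com - ring_com
            dist = np.linalg.norm(sep, axis=-1)
            with np.errstate(invalid="ignore"):
                cosang = np.abs(np.einsum("fx,fx->f", sep, normals)) / np.where(
                    dist == 0, 1.0, dist
                )
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            on = (dist < dist_cutoff) & (angle < angle_cutoff)
            events.append(
                InteractionEvent(
                    kind="cation_pi",
                    residue_i=ring_res,
                    residue_j=cat_res,
                    per_frame=on,
                    frequency=float(on.mean()),
                )
            )
    return events


def saltbridge_hbond_events(
    ensemble: Ensemble, hb_dist: float = 3.5, hb_angle: float = 135.0
) -> list[InteractionEvent]:
    """Salt bridges and side-chain-to-backbone hydrogen bonds.

    A salt bridge is any Arg/Lys side-chain nitrogen within ``hb_dist`` Å of
    any Asp/Glu carboxylate oxygen.  An SC-BB hydrogen bond requires the
    donor-acceptor heavy-atom distance to be at most ``hb_dist`` and the
    D-H...A angle at least ``hb_angle`` degrees; donors are side-chain N/O
    atoms with an attached hydrogen, acceptors are backbone carbonyl oxygens
    of other residues.  Without polar hydrogens the angle criterion is
    skipped with a warning (distance-only mode).
    """
    top = ensemble.topology
    coords = ensemble.coordinates
    events: list[InteractionEvent] = []

    # --- salt bridges -----------------------------------------------------
    cat_atoms = []  # (residue, atom index)
    ani_atoms = []
    for res in top.protein_residues:
        if res.name in CATIONIC_NITROGENS:
            for i in top.atom_indices(res.index, names=set(CATIONIC_NITROGENS[res.name])):
                cat_atoms.append((res.index, i))
        if res.name in ANIONIC_OXYGENS:
            for i in top.atom_indices(res.index, names=set(ANIONIC_OXYGENS[res.name])):
                ani_atoms.append((res.index, i))
    pair_masks: dict[tuple[int, int], np.ndarray] = {}
    for ri, ai in cat_atoms:
        for rj, aj in ani_atoms:
            if ri == rj:
                continue
            d = np.linalg.norm(coords[:, ai] - coords[:, aj], axis=-1)
            on = d <= hb_dist
            key = (ri, rj)
            pair_masks[key] = pair_masks.get(key, np.zeros(ensemble.n_frames, bool)) | on
    for (ri, rj), on in pair_masks.items():
        events.append(
            InteractionEvent("salt_bridge", ri, rj, per_frame=on, frequency=float(on.mean()))
        )

    # --- SC-BB hydrogen bonds --------------------------------------------
    frame0 = coords[0]
    donors = []  # (residue, heavy idx, [H idx, ...])
    has_h = any(a.element == "H" for a in top.atoms)
    for i, atom in enumerate(top.atoms):
        if atom.role != "sidechain" or atom.element not in ("N", "O"):
            continue
        hydrogens = [
            j
            for j, a in enumerate(top.atoms)
            if a.residue_index == atom.residue_index
            and a.element == "H"
            and np.linalg.norm(frame0[j] - frame0[i]) < 1.25
        ]
        if hydrogens or not has_h:
            donors.append((atom.residue_index, i, hydrogens))
    acceptors = [
        (a.residue_index, i)
        for i, a in enumerate(top.atoms)
        if a.role == "backbone" and a.name == "O"
    ]
    if not has_h:
        warnings.warn("no polar hydrogens: H-bond angle criterion skipped", stacklevel=2)
    hb_masks: dict[tuple[int, int], np.ndarray] = {}
    for ri, di, hyds in donors:
        for rj, aj in acceptors:
            if ri == rj:
                continue
            d = np.linalg.norm(coords[:, di] - coords[:, aj], axis=-1)
            on = d <= hb_dist
            if has_h and hyds:
                angle_ok = np.zeros(ensemble.n_frames, dtype=bool)
                for h in hyds:
                    hd = coords[:, di] - coords[:, h]
                    ha = coords[:, aj] - coords[:, h]
                    cosang = np.einsum("fx,fx->f", hd, ha) / (
                        np.linalg.norm(hd, axis=-1) * np.linalg.norm(ha, axis=-1)
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    angle_ok |= ang >= hb_angle
                on = on & angle_ok
            key = (ri, rj)
            hb_masks[key] = hb_masks.get(key, np.zeros(ensemble.n_frames, bool)) | on
    for (ri, rj), on in hb_masks.items():
        events.append(
            InteractionEvent("scbb_hbond", ri, rj, per_frame=on, frequency=float(on.mean()))
        )
    return events


@dataclass
class Segment:
    """A contiguous block of residues coupled by frequent contacts."""

    start: int
    end: int
    pairs: list[tuple[int, int]]
    mean_frequency: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def correlated_segments(
    cmap: ContactMap, freq_threshold: float = 0.01, min_span: int = 3
) -> list[Segment]:
    """Sequence segments covering connected components of frequent contacts.

    Residue pairs with representative frequency >= ``freq_threshold`` and
    ``|i - j| >= 2`` define edges; each edge spans the interval
    ``[min(i, j), max(i, j)]``, overlapping intervals are merged, and merged
    intervals shorter than ``min_span`` residues are dropped.
    """
    ids = cmap.residue_ids
    edges = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i, j = ids[a], ids[b]
            if abs(i - j) < 2:
                continue
            f = max(cmap.frequencies[a, b], cmap.frequencies[b, a])
            if f >= freq_threshold:
                edges.append((i, j, float(f)))
    if not edges:
        return []
    intervals = sorted((min(i, j), max(i, j), i, j, f) for i, j, f in edges)
    merged: list[dict] = []
    for lo, hi, i, j, f in intervals:
        if merged and lo <= merged[-1]["end"]:
            merged[-1]["end"] = max(merged[-1]["end"], hi)
            merged[-1]["pairs"].append((i, j))
            merged[-1]["freqs"].append(f)
        else:
            merged.append({"start": lo, "end": hi, "pairs": [(i, j)], "freqs": [f]})
    return [
        Segment(
            start=m["start"],
            end=m["end"],
            pairs=m["pairs"],
            mean_frequency=float(np.mean(m["freqs"])),
        )
        for m in merged
        if m["end"] - m["start"] + 1 >= min_span
    ]
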