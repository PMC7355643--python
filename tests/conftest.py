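"""Shared fixtures: programmatic micro-ensembles with controlled geometry."""

from __future__ import annotations

import numpy as np
import pytest

from idrdyn.ensemble import Atom, Ensemble, Residue, Topology

ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

# torsion sets whose ideal-geometry realizations DSSP labels as expected
HELIX_PHI_PSI = ([-57.0] * 12, [-47.0] * 12)
EXTENDED_PHI_PSI = ([180.0] * 10, [180.0] * 10)
HAIRPIN_PHI_PSI = (
    [-120.0] * 6 + [55.0, 80.0] + [-120.0] * 6,
    [130.0] * 6 + [40.0, 5.0] + [130.0] * 6,
)


def build_ensemble(atom_spec, frames, frame_interval=20.0):
    """Ensemble from ``atom_spec`` rows (resid, resname, atom, element, role)
    and ``frames`` of shape (n_frames, n_atoms, 3)."""
    residues = {}
    atoms = []
    for resid, resname, name, element, role in atom_spec:
        residues.setdefault(resid, resname)
        atoms.append(
            Atom(
                name=name,
                element=element,
                mass=ELEMENT_MASSES.get(element, 12.0),
                residue_index=resid,
                role=role,
            )
        )
    res_list = [Residue(index=r, name=n) for r, n in sorted(residues.items())]
    topology = Topology(chain_id="A", residues=res_list, atoms=atoms)
    return Ensemble(
        topology=topology,
        coordinates=np.asarray(frames, dtype=float),
        frame_interval=frame_interval,
    )


def hexagon_ring(center, radius=1.39, normal_axis=2):
    """Six coplanar points forming a regular hexagon (a phenol-type ring)."""
    angles = np.arange(6) * np.pi / 3.0
    pts = np.zeros((6, 3))
    axes = [i for i in range(3) if i != normal_axis]
    pts[:, axes[0]] = radius * np.cos(angles)
    pts[:, axes[1]] = radius * np.sin(angles)
    return pts + np.asarray(center)


@pytest.fixture
def tyr_arg_builder():
    """Factory: ensemble with a TYR ring at the origin (normal = z) and an
    ARG guanidinium group centred at a requested point."""

    def build(guanidinium_center):
        ring = hexagon_ring((0.0, 0.0, 0.0))
        gc = np.asarray(guanidinium_center, dtype=float)
        # compact guanidinium: CZ at centre, three N around it
        guan = gc + np.array(
            [[0.0, 0.0, 0.0], [1.33, 0.0, 0.0], [-0.66, 1.15, 0.0], [-0.66, -1.15, 0.0]]
        )
        spec = [(1, "TYR", n, n[0], "sidechain") for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]
        spec += [(2, "ALA", "CA", "C", "backbone")]
        spec += [(3, "ARG", n, n[0], "sidechain") for n in ("CZ", "NE", "NH1", "NH2")]
        frames = np.concatenate([ring, [[50.0, 0.0, 0.0]], guan])[None]
        return build_ensemble(spec, frames)

    return build
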