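"""Synthetic inputs with exact ground truth for every analysis stage.

Long all-atom trajectories of a disordered chain are expensive; each generator
here emulates one statistical aspect of such data with a known answer so the
downstream machinery (correlation functions and multi-exponential fits, PPII
classification, contact maps, CLEANEX exchange fits, Debye size fits) can be
validated quantitatively:

- :func:`rotdiff_vector_series` -- unit vectors undergoing isotropic rotational
  diffusion, whose P2 autocorrelation is exactly ``exp(-6 D tau)``;
- :func:`multiexp_corr_samples` -- multi-exponential correlation curves with
  optional Gaussian noise;
- :func:`markov_dihedral_series` -- phi/psi series with prescribed Ramachandran
  basin occupancies;
- :func:`planted_contact_ensemble` -- coarse coordinate ensembles with planted
  side-chain contact frequencies;
- :func:`cleanex_buildup_curves` -- CLEANEX-PM buildup ratios with known k_ex;
- :func:`debye_profile` -- SAXS profiles of a Gaussian chain with known Rg;
- :func:`ideal_chain` -- an ideal-geometry backbone built from prescribed
  phi/psi torsions (extended chains, helices, hairpins, capped chains).

Every generator is deterministic given its parameters and seed, and returns
``(data, ground_truth)`` where the second element records the seed and the
planted parameters.
"""

from __future__ import annotations

import warnings

import numpy as np

from idrdyn.ensemble import (
    Atom,
    DihedralSeries,
    Ensemble,
    Residue,
    Topology,
    VectorSeries,
)
from idrdyn.exchange import cleanex_ratio
from idrdyn.relaxation import CorrelationFunction
from idrdyn.size_stats import SAXSProfile, debye_intensity

__all__ = [
    "rotdiff_vector_series",
    "multiexp_corr_samples",
    "markov_dihedral_series",
    "planted_contact_ensemble",
    "cleanex_buildup_curves",
    "debye_profile",
    "ideal_chain",
    "default_lag_grid",
    "BASIN_CENTERS",
]

# ---------------------------------------------------------------------------
# rotational diffusion


def _rodrigues(vectors: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Rotate each row of ``vectors`` by the rotation vector in ``omega``."""
    theta = np.linalg.norm(omega, axis=-1, keepdims=True)
    small = theta[..., 0] < 1e-12
    axis = np.where(small[..., None], 0.0, omega / np.where(theta == 0, 1.0, theta))
    cos_t = np.cos(theta)
    sin_t = np.sin(theta)
    cross = np.cross(axis, vectors)
    dot = np.sum(axis * vectors, axis=-1, keepdims=True)
    out = vectors * cos_t + cross * sin_t + axis * dot * (1.0 - cos_t)
    return np.where(small[..., None], vectors, out)


def rotdiff_vector_series(
    D: float,
    n_frames: int,
    frame_interval: float = 20.0,
    seed: int = 0,
    n_vectors: int = 1,
    max_step_var: float = 0.01,
    substep: bool = True,
) -> tuple[VectorSeries, dict]:
    """Unit vectors under isotropic rotational diffusion.

    Each saved step applies a random rotation with a Gaussian rotation vector
    of per-component variance ``2 D dt`` (total angle variance ``6 D dt``,
    of which ``4 D dt`` reorients the vector).  The exact P2 autocorrelation is
    ``C(tau) = exp(-6 D tau)``.  Steps are subdivided so the per-step angle
    variance stays below ``max_step_var`` rad^2, keeping the discretization
    bias of the finite-rotation update below the percent level.

    Parameters
    ----------
    D:
        Rotational diffusion constant in 1/ns; the P2 correlation time is
        ``1 / (6 D)``.
    frame_interval:
        Saved-frame spacing in ps.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    dt_ns = frame_interval / 1000.0
    rng = np.random.default_rng(seed)
    start = rng.standard_normal((n_vectors, 3))
    start /= np.linalg.norm(start, axis=-1, keepdims=True)
    vectors = np.empty((n_frames, n_vectors, 3))
    vectors[0] = start
    if D > 0 and n_frames > 1:
        step_var = 6.0 * D * dt_ns
        n_sub = 1
        if substep:
            n_sub = max(1, int(np.ceil(step_var / max_step_var)))
        elif D * dt_ns > 0.05:
            warnings.warn(
                f"per-step D*dt = {D * dt_ns:.3g} rad^2 exceeds 0.05; the "
                "discretized correlation decay will be biased",
                stacklevel=2,
            )
        sigma = np.sqrt(2.0 * D * dt_ns / n_sub)
        current = start.copy()
        for t in range(1, n_frames):
            for _ in range(n_sub):
                omega = rng.normal(scale=sigma, size=(n_vectors, 3))
                current = _rodrigues(current, omega)
            current /= np.linalg.norm(current, axis=-1, keepdims=True)
            vectors[t] = current
    else:
        vectors[:] = start
    series = VectorSeries(
        residue_ids=list(range(1, n_vectors + 1)),
        vectors=vectors,
        frame_interval=frame_interval,
    )
    truth = {
        "generator": "rotdiff_vector_series",
        "seed": seed,
        "D_per_ns": D,
        "tau_c_ns": np.inf if D == 0 else 1.0 / (6.0 * D),
        "frame_interval_ps": frame_interval,
    }
    return series, truth


# ---------------------------------------------------------------------------
# multi-exponential correlation curves


def default_lag_grid(
    frame_interval_ns: float = 0.02,
    dense_until_ns: float = 2.0,
    max_lag_ns: float = 25.0,
    max_points: int = 400,
) -> np.ndarray:
    """Lag grid dense on the frame spacing up to 2 ns, log-thinned to 25 ns."""
    dense = np.arange(frame_interval_ns, dense_until_ns + 1e-12, frame_interval_ns)
    if max_lag_ns <= dense_until_ns:
        return dense[dense <= max_lag_ns + 1e-12]
    n_tail = max(2, max_points - dense.size)
    tail = np.geomspace(dense_until_ns, max_lag_ns, n_tail + 1)[1:]
    # snap tail points to the frame grid so lags remain realizable
    tail = np.unique(np.round(tail / frame_interval_ns)) * frame_interval_ns
    return np.concatenate([dense, tail[tail > dense[-1] + 1e-12]])


def multiexp_corr_samples(
    amplitudes,
    taus,
    lag_grid=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    residue_id: int = 1,
) -> tuple[CorrelationFunction, dict]:
    """Correlation curve ``C(tau) = sum_i A_i exp(-tau / tau_i)`` plus noise.

    ``taus`` and the lag grid are in ns; the default grid runs from 20 ps to
    25 ns as used for NH correlation fitting.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    taus_ns = np.asarray(taus, dtype=float)
    if amplitudes.shape != taus_ns.shape:
        raise ValueError("amplitudes and taus must have the same length")
    if np.sum(amplitudes) > 1.0 + 1e-9:
        raise ValueError("amplitudes must sum to at most 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    lags = default_lag_grid() if lag_grid is None else np.asarray(lag_grid, dtype=float)
    values = np.sum(amplitudes[:, None] * np.exp(-lags[None, :] / taus_ns[:, None]), axis=0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(scale=noise_sd, size=lags.shape)
    corr = CorrelationFunction(
        residue_id=residue_id, lags_ns=lags, values=values, n_frames=0
    )
    truth = {
        "generator": "multiexp_corr_samples",
        "seed": seed,
        "amplitudes": amplitudes.tolist(),
        "taus_ns": taus_ns.tolist(),
        "noise_sd": noise_sd,
    }
    return corr, truth


# ---------------------------------------------------------------------------
# Ramachandran basin dihedral series

#: (phi, psi) centres of the named Ramachandran basins, degrees
BASIN_CENTERS = {
    "ppii": (-70.0, 150.0),
    "helix": (-63.0, -43.0),
    "extended": (-120.0, 130.0),
    "left": (60.0, 45.0),
    # remainder mass goes to a generic coil point outside the PPII region
    "other": (-150.0, 60.0),
}


def markov_dihedral_series(
    basin_spec: dict[str, float],
    switch_prob: float = 0.1,
    n_frames: int = 1000,
    n_residues: int = 10,
    seed: int = 0,
    sigma: float = 10.0,
    block_size: int = 1,
    residue_ids=None,
    frame_interval: float = 20.0,
) -> tuple[DihedralSeries, dict]:
    """Dihedral series with prescribed long-run Ramachandran basin occupancies.

    Each residue (or contiguous block of ``block_size`` residues, switching
    jointly) carries a Markov state over the named basins: at each frame, with
    probability ``switch_prob`` the state is redrawn from the occupancy
    distribution, so the stationary occupancies equal ``basin_spec`` exactly.
    Angles are Gaussian around the basin centre with ``sigma`` degrees per
    angle.  Occupancy mass not assigned to a named basin goes to a generic
    coil point outside the PPII region.
    """
    names = list(basin_spec)
    probs = np.array([basin_spec[k] for k in names], dtype=float)
    if np.any(probs < 0) or probs.sum() > 1.0 + 1e-9:
        raise ValueError("occupancies must be in [0, 1] and sum to at most 1")
    unknown = [k for k in names if k not in BASIN_CENTERS]
    if unknown:
        raise ValueError(f"unknown basins: {unknown}")
    rest = 1.0 - probs.sum()
    if rest > 1e-12 and "other" not in names:
        names.append("other")
        probs = np.append(probs, rest)
    probs = probs / probs.sum()
    centers = np.array([BASIN_CENTERS[k] for k in names])

    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n_residues / block_size))
    states = np.empty((n_frames, n_blocks), dtype=int)
    states[0] = rng.choice(len(names), size=n_blocks, p=probs)
    for t in range(1, n_frames):
        redraw = rng.random(n_blocks) < switch_prob
        fresh = rng.choice(len(names), size=n_blocks, p=probs)
        states[t] = np.where(redraw, fresh, states[t - 1])
    res_states = np.repeat(states, block_size, axis=1)[:, :n_residues]

    angles = centers[res_states] + rng.normal(scale=sigma, size=(n_frames, n_residues, 2))
    angles = ((angles + 180.0) % 360.0) - 180.0
    angles[angles == -180.0] = 180.0
    if residue_ids is None:
        residue_ids = list(range(1, n_residues + 1))
    series = DihedralSeries(
        residue_ids=list(residue_ids),
        phi=angles[..., 0],
        psi=angles[..., 1],
        frame_interval=frame_interval,
    )
    truth = {
        "generator": "markov_dihedral_series",
        "seed": seed,
        "occupancies": dict(zip(names, probs.tolist())),
        "switch_prob": switch_prob,
        "block_size": block_size,
        "states": res_states,
        "basin_names": names,
    }
    return series, truth


# ---------------------------------------------------------------------------
# planted-contact coordinate ensembles

_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, 0.0, 0.8]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.2, 0.0, 0.8]),
    "O": np.array([1.2, 0.0, 2.0]),
}
_SC_OFFSET = np.array([0.0, 3.0, 0.0])


def planted_contact_ensemble(
    chain_length: int,
    contact_list,
    n_frames: int = 1000,
    seed: int = 0,
    frame_interval: float = 20.0,
) -> tuple[Ensemble, dict]:
    """Coarse ensemble in which chosen side-chain pairs touch at known rates.

    The backbone is a straight chain (one N/CA/C/O plus one side-chain atom CB
    per residue, 3.8 Å spacing).  For each planted contact ``(i, j, f)`` with
    ``|i - j| >= 2``, in a Bernoulli(f) fraction of frames the two CB atoms are
    moved to a private meeting point < 3.5 Å apart; in all other frames every
    inter-residue side-chain distance exceeds 6 Å.  The geometry is a counting
    fixture, not a physical chain: no excluded volume is enforced.

    A residue may participate in at most one planted contact; reusing a
    residue would make the planted frequencies geometrically inconsistent and
    raises ``ValueError``.
    """
    used: set[int] = set()
    contacts = []
    for i, j, f in contact_list:
        if abs(i - j) < 2:
            raise ValueError(f"contact ({i}, {j}) must have |i - j| >= 2")
        if not 0.0 <= f <= 1.0:
            raise ValueError("contact frequencies must be in [0, 1]")
        if i in used or j in used:
            raise ValueError(
                f"residue reused across contacts ({i}, {j}); conflicting "
                "contacts cannot co-exist geometrically"
            )
        if not (1 <= i <= chain_length and 1 <= j <= chain_length):
            raise ValueError("contact residues outside the chain")
        used.update((i, j))
        contacts.append((min(i, j), max(i, j), float(f)))

    residues = [Residue(index=r, name="ALA") for r in range(1, chain_length + 1)]
    atoms = []
    base = np.zeros((chain_length * 5, 3))
    for r in range(1, chain_length + 1):
        ca = np.array([3.8 * (r - 1), 0.0, 0.0])
        for k, (name, off) in enumerate(_BACKBONE_OFFSETS.items()):
            atoms.append(Atom(name=name, element=name[0], mass=14.0, residue_index=r, role="backbone"))
            base[(r - 1) * 5 + k] = ca + off
        atoms.append(Atom(name="CB", element="C", mass=12.011, residue_index=r, role="sidechain"))
        base[(r - 1) * 5 + 4] = ca + _SC_OFFSET
    topology = Topology(chain_id="A", residues=residues, atoms=atoms)

    rng = np.random.default_rng(seed)
    coords = np.broadcast_to(base, (n_frames, base.shape[0], 3)).copy()
    on_masks = {}
    for lane, (i, j, f) in enumerate(contacts):
        on = rng.random(n_frames) < f if f < 1.0 else np.ones(n_frames, dtype=bool)
        on_masks[(i, j)] = on
        ca_i = base[(i - 1) * 5 + 1]
        ca_j = base[(j - 1) * 5 + 1]
        meet = (ca_i + ca_j) / 2.0 + np.array([0.0, 8.0 + 5.0 * lane, 0.0])
        coords[on, (i - 1) * 5 + 4] = meet - np.array([1.5, 0.0, 0.0])
        coords[on, (j - 1) * 5 + 4] = meet + np.array([1.5, 0.0, 0.0])

    ensemble = Ensemble(
        topology=topology,
        coordinates=coords,
        frame_interval=frame_interval,
        metadata={"generator": "planted_contact_ensemble", "seed": seed},
    )
    truth = {
        "generator": "planted_contact_ensemble",
        "seed": seed,
        "contacts": contacts,
        "realized_frequencies": {pair: float(mask.mean()) for pair, mask in on_masks.items()},
    }
    return ensemble, truth


# ---------------------------------------------------------------------------
# CLEANEX buildup curves

#: CLEANEX-PM spin-lock (mixing) times in ms
DEFAULT_MIXING_TIMES_MS = (10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 75.0, 100.0)


def cleanex_buildup_curves(
    k_ex: float,
    R1_water: float = 0.6,
    R1_apparent: float = 5.0,
    mixing_times_ms=DEFAULT_MIXING_TIMES_MS,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[dict, dict]:
    """CLEANEX-PM intensity-ratio buildup from the two-rate exchange model.

    Ratios follow the standard magnetization-transfer solution
    ``V/V0 = k_ex/(R1a + k_ex - R1w) * (exp(-R1w t) - exp(-(R1a + k_ex) t))``
    with the water longitudinal rate ``R1w`` and the apparent in-protein rate
    ``R1a`` (both s^-1), evaluated at the given spin-lock times, plus optional
    Gaussian noise.
    """
    if k_ex < 0 or R1_water <= 0 or R1_apparent <= 0:
        raise ValueError("rates must be positive (k_ex may be zero)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t_s = np.asarray(mixing_times_ms, dtype=float) / 1000.0
    ratios = cleanex_ratio(t_s, k_ex, R1_apparent, R1_water)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratios = ratios + rng.normal(scale=noise_sd, size=t_s.shape)
    data = {"mixing_time_ms": np.asarray(mixing_times_ms, dtype=float), "ratio": ratios}
    truth = {
        "generator": "cleanex_buildup_curves",
        "seed": seed,
        "k_ex": k_ex,
        "R1_water": R1_water,
        "R1_apparent": R1_apparent,
        "noise_sd": noise_sd,
    }
    return data, truth


# ---------------------------------------------------------------------------
# Debye SAXS profiles


def debye_profile(
    Rg: float,
    I0: float = 1.0,
    q_grid=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SAXSProfile, dict]:
    """SAXS profile of a Gaussian chain: ``I(q) = I0 * 2(e^-x + x - 1)/x^2``
    with ``x = (q Rg)^2``, plus optional Gaussian noise."""
    if Rg <= 0 or I0 <= 0:
        raise ValueError("Rg and I0 must be positive")
    q = np.linspace(0.005, 0.30, 120) if q_grid is None else np.asarray(q_grid, dtype=float)
    intensity = debye_intensity(q, Rg, I0)
    sigma = None
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(scale=noise_sd * I0, size=q.shape)
        sigma = np.full_like(q, noise_sd * I0)
    profile = SAXSProfile(q=q, intensity=intensity, sigma=sigma)
    truth = {"generator": "debye_profile", "seed": seed, "Rg": Rg, "I0": I0, "noise_sd": noise_sd}
    return profile, truth


# ---------------------------------------------------------------------------
# ideal-geometry backbone builder

# standard peptide geometry (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_chain(
    phi,
    psi,
    sequence=None,
    caps: bool = False,
    with_h: bool = True,
    n_frames: int = 1,
    frame_interval: float = 20.0,
) -> Ensemble:
    """Backbone-only chain built from prescribed phi/psi with ideal geometry.

    ``phi[i]``/``psi[i]`` are the torsions of residue ``i + 1`` (degrees);
    ``phi[0]`` is only realized when ``caps`` adds an ACE group, and the final
    psi only when an NME cap is present.  Amide hydrogens are placed in the
    peptide plane when ``with_h``.  All frames are identical copies, which
    suffices for geometry-level fixtures.
    """
    phi = list(map(float, phi))
    psi = list(map(float, psi))
    n = len(phi)
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    if sequence is None:
        sequence = ["ALA"] * n
    if len(sequence) != n:
        raise ValueError("sequence length must match phi/psi")

    pos: dict[tuple[int, str], np.ndarray] = {}
    pos[(1, "N")] = np.zeros(3)
    pos[(1, "CA")] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    pos[(1, "C")] = pos[(1, "CA")] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(2, n + 1):
        pos[(i, "N")] = _place_atom(
            pos[(i - 1, "N")], pos[(i - 1, "CA")], pos[(i - 1, "C")],
            _B_C_N, _A_CA_C_N, psi[i - 2],
        )
        pos[(i, "CA")] = _place_atom(
            pos[(i - 1, "CA")], pos[(i - 1, "C")], pos[(i, "N")],
            _B_N_CA, _A_C_N_CA, 180.0,
        )
        pos[(i, "C")] = _place_atom(
            pos[(i - 1, "C")], pos[(i, "N")], pos[(i, "CA")],
            _B_CA_C, _A_N_CA_C, phi[i - 1],
        )
    for i in range(1, n + 1):
        # carbonyl O anti to the next amide N (torsion psi + 180)
        pos[(i, "O")] = _place_atom(
            pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
            _B_C_O, _A_CA_C_O, psi[i - 1] + 180.0,
        )

    residues: list[Residue] = []
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []

    def add(residue_index, resname, name, element, xyz, role):
        atoms.append(
            Atom(
                name=name,
                element=element,
                mass={"C": 12.011, "N": 14.007, "O": 15.999, "H": 1.008}[element],
                residue_index=residue_index,
                role=role,
            )
        )
        coords.append(xyz)

    if caps:
        residues.append(Residue(index=0, name="ACE", is_cap=True))
        c_ace = _place_atom(pos[(1, "C")], pos[(1, "CA")], pos[(1, "N")], _B_C_N, _A_C_N_CA, phi[0])
        ch3 = _place_atom(pos[(1, "CA")], pos[(1, "N")], c_ace, 1.51, _A_CA_C_N, 180.0)
        o_ace = _place_atom(pos[(1, "CA")], pos[(1, "N")], c_ace, _B_C_O, 123.0, 0.0)
        add(0, "ACE", "CH3", "C", ch3, "cap")
        add(0, "ACE", "C", "C", c_ace, "cap")
        add(0, "ACE", "O", "O", o_ace, "cap")

    for i in range(1, n + 1):
        resname = sequence[i - 1]
        residues.append(Residue(index=i, name=resname))
        add(i, resname, "N", "N", pos[(i, "N")], "backbone")
        prev_c = pos[(i - 1, "C")] if i > 1 else (coords[1] if caps else None)
        if with_h and resname != "PRO" and prev_c is not None:
            u1 = prev_c - pos[(i, "N")]
            u2 = pos[(i, "CA")] - pos[(i, "N")]
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            h_dir = -(u1 + u2)
            h_dir /= np.linalg.norm(h_dir)
            add(i, resname, "H", "H", pos[(i, "N")] + _B_N_H * h_dir, "backbone")
        add(i, resname, "CA", "C", pos[(i, "CA")], "backbone")
        add(i, resname, "C", "C", pos[(i, "C")], "backbone")
        add(i, resname, "O", "O", pos[(i, "O")], "backbone")

    if caps:
        residues.append(Residue(index=n + 1, name="NME", is_cap=True))
        n_nme = _place_atom(
            pos[(n, "N")], pos[(n, "CA")], pos[(n, "C")], _B_C_N, _A_CA_C_N, psi[n - 1]
        )
        ch3 = _place_atom(pos[(n, "CA")], pos[(n, "C")], n_nme, _B_N_CA, _A_C_N_CA, 180.0)
        add(n + 1, "NME", "N", "N", n_nme, "cap")
        add(n + 1, "NME", "CH3", "C", ch3, "cap")

    topology = Topology(chain_id="A", residues=residues, atoms=atoms)
    frame = np.array(coords)
    return Ensemble(
        topology=topology,
        coordinates=np.broadcast_to(frame, (n_frames, *frame.shape)).copy(),
        frame_interval=frame_interval,
        metadata={"generator": "ideal_chain"},
    )
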