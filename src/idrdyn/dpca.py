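"""Dihedral principal component analysis, landscapes, clusters, representatives.

Backbone phi/psi angles are embedded as (sin, cos) pairs -- the circular
embedding avoids periodicity artifacts -- giving 4 features per interior
residue.  PCA of the covariance matrix of these features yields eigenmodes
whose per-torsion contribution is

    Delta_n^k = (v_{2n-1}^k)^2 + (v_{2n}^k)^2,

the squared eigenvector amplitude on the sine and cosine of torsion n; the
contributions of a mode sum to 1 by orthonormality.  Snapshot projections on
the two largest modes define a free-energy surface F = -ln(p / p_max) (in
units of k_B T) and are grouped by Ward agglomerative clustering; each
cluster's representative snapshot maximizes the mean pairwise similarity
score

    S_i = < (1/N^2) sum_{n,m} 1 / (1 + (r_nm^i - r_nm^j)^2) >_j

over its cluster partners, where r_nm are interatomic distances (Å) of a
chosen atom selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from idrdyn.ensemble import DihedralSeries, Ensemble

__all__ = [
    "DihedralFeatureMatrix",
    "EigenModeSet",
    "ClusterAssignment",
    "SimilarityParams",
    "dihedral_features",
    "eigen_decompose",
    "fes_2d",
    "ward_clusters",
    "representative_by_similarity",
    "similarity_scores",
]


@dataclass
class DihedralFeatureMatrix:
    """Snapshots x features matrix of (sin phi, cos phi, sin psi, cos psi).

    Columns are ordered by residue, then angle (phi before psi), then
    sin before cos; ``torsions`` lists the (residue, angle) pair behind each
    consecutive (sin, cos) column pair.
    """

    matrix: np.ndarray  # (n_snapshots, 4 * n_residues)
    torsions: list[tuple[int, str]]  # [(res, "phi"), (res, "psi"), ...]

    @property
    def n_snapshots(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def dihedral_features(dihedrals: DihedralSeries) -> DihedralFeatureMatrix:
    """Circular (sin, cos) embedding of a dihedral series.

    Snapshots containing any missing (NaN) dihedral are dropped.  A capped
    64-residue chain (62 interior residues) yields 248 feature columns.
    """
    phi = np.radians(dihedrals.phi)
    psi = np.radians(dihedrals.psi)
    ok = ~(np.isnan(phi).any(axis=1) | np.isnan(psi).any(axis=1))
    phi, psi = phi[ok], psi[ok]
    n_frames, n_res = phi.shape
    cols = np.empty((n_frames, 4 * n_res))
    cols[:, 0::4] = np.sin(phi)
    cols[:, 1::4] = np.cos(phi)
    cols[:, 2::4] = np.sin(psi)
    cols[:, 3::4] = np.cos(psi)
    torsions = []
    for rid in dihedrals.residue_ids:
        torsions.append((rid, "phi"))
        torsions.append((rid, "psi"))
    return DihedralFeatureMatrix(matrix=cols, torsions=torsions)


@dataclass
class EigenModeSet:
    """Covariance eigenmodes of a dihedral feature matrix."""

    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, orthonormal
    projections: np.ndarray  # (n_snapshots, n_modes), mean-centered
    torsions: list[tuple[int, str]]

    @property
    def normalized_eigenvalues(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues

    def torsion_contributions(self, mode: int) -> np.ndarray:
        """Delta_n^k per torsion: squared (sin, cos) eigenvector amplitudes.

        ``mode`` is zero-based; contributions over all torsions sum to 1.
        """
        v = self.eigenvectors[:, mode]
        return v[0::2] ** 2 + v[1::2] ** 2


def eigen_decompose(features: DihedralFeatureMatrix) -> EigenModeSet:
    """Eigen-decomposition of the covariance of mean-centered features.

    Rank-deficient input simply yields (near-)zero trailing eigenvalues.
    The unbiased (ddof = 1) covariance convention is used, so projection
    variances (ddof = 1) equal the eigenvalues.
    """
    x = features.matrix
    if x.shape[0] < 2:
        raise ValueError("need at least 2 snapshots")
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    projections = centered @ evecs
    return EigenModeSet(
        eigenvalues=evals,
        eigenvectors=evecs,
        projections=projections,
        torsions=features.torsions,
    )


def fes_2d(
    projections: np.ndarray, bins: int = 100, temperature: float = 300.0
):
    """Free-energy surface F = -ln(p / p_max) over 2-D mode projections.

    Returns ``(F, xedges, yedges)`` where F is a masked array in units of
    k_B T (the ``temperature`` is recorded for unit conversion by callers but
    does not change the k_B T-scaled surface); the occupied minimum is
    exactly 0 and empty bins are masked.
    """
    proj = np.asarray(projections)
    if proj.ndim != 2 or proj.shape[1] < 2:
        raise ValueError("projections must be (n_snapshots, >=2)")
    hist, xedges, yedges = np.histogram2d(proj[:, 0], proj[:, 1], bins=bins)
    if hist.max() <= 0:
        raise ValueError("no occupied bins")
    with np.errstate(divide="ignore"):
        fes = -np.log(hist / hist.max())
    return np.ma.masked_invalid(fes), xedges, yedges


@dataclass
class ClusterAssignment:
    """Snapshot-to-cluster labels (ids 1..k) with member lists."""

    labels: np.ndarray  # (n_snapshots,), values in 1..k
    k: int

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def ward_clusters(projections: np.ndarray, k: int = 16) -> ClusterAssignment:
    """Hierarchical Ward (minimum-variance) clustering of 2-D projections."""
    proj = np.asarray(projections)
    if proj.ndim == 1:
        proj = proj[:, None]
    n = proj.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of snapshots ({n})")
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        z = linkage(proj, method="ward")
        labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(labels=labels, k=k)


@dataclass
class SimilarityParams:
    """Configuration of the pairwise-distance similarity score.

    ``selection`` chooses the atoms whose N(N-1)/2 distances enter the score
    ("heavy" or "all"); the all-pairs evaluation is quadratic in cluster
    size, so clusters larger than ``max_members`` are subsampled uniformly
    (seeded) before scoring.
    """

    selection: str = "heavy"
    max_members: int = 200
    seed: int = 0


def _selected_atoms(ensemble: Ensemble, selection: str) -> np.ndarray:
    if selection == "all":
        idx = np.arange(ensemble.n_atoms)
    elif selection == "heavy":
        idx = np.array(
            [i for i, a in enumerate(ensemble.topology.atoms) if a.element != "H"]
        )
    else:
        raise ValueError("selection must be 'heavy' or 'all'")
    if idx.size < 2:
        raise ValueError("similarity selection needs at least 2 atoms")
    return idx


def similarity_scores(distance_rows: np.ndarray, n_atoms: int) -> np.ndarray:
    """S_i for every snapshot from its condensed distance vector rows.

    ``distance_rows`` is (n_snapshots, n_pairs) of pdist vectors.  The full
    double sum over ordered atom pairs (n, m) counts each unordered pair
    twice and the N diagonal terms (distance difference 0) once each; the
    average runs over the other snapshots (self excluded).
    """
    m = distance_rows.shape[0]
    if m == 1:
        return np.ones(1)
    scores = np.empty(m)
    for i in range(m):
        diff = distance_rows - distance_rows[i]
        pair_terms = 1.0 / (1.0 + diff**2)
        per_j = (n_atoms + 2.0 * pair_terms.sum(axis=1)) / n_atoms**2
        scores[i] = (per_j.sum() - per_j[i]) / (m - 1)
    return scores


def representative_by_similarity(
    ensemble: Ensemble,
    clusters: ClusterAssignment,
    params: SimilarityParams | None = None,
) -> dict[int, tuple[int, float]]:
    """Most representative snapshot per cluster by mean similarity score.

    Returns ``{cluster_id: (snapshot_index, score)}``; the representative is
    the member with the highest S_i, ties broken by the lowest snapshot
    index.  A singleton cluster's only member has score 1 by convention.
    """
    params = params or SimilarityParams()
    atom_idx = _selected_atoms(ensemble, params.selection)
    n_atoms = atom_idx.size
    rng = np.random.default_rng(params.seed)
    out: dict[int, tuple[int, float]] = {}
    for cid in range(1, clusters.k + 1):
        members = clusters.members(cid)
        if members.size == 0:
            continue
        if members.size == 1:
            out[cid] = (int(members[0]), 1.0)
            continue
        scored = members
        if members.size > params.max_members:
            scored = np.sort(rng.choice(members, size=params.max_members, replace=False))
        rows = np.stack(
            [pdist(ensemble.coordinates[s][atom_idx]) for s in scored]
        )
        scores = similarity_scores(rows, n_atoms)
        best = np.flatnonzero(scores == scores.max())[0]  # lowest index wins ties
        out[cid] = (int(scored[best]), float(scores[best]))
    return out
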