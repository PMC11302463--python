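"""Structure-based featurization of a protein backbone.

Produces everything the encoder consumes: a k-nearest-neighbour graph over
CA atoms with Euclidean distances and unit edge vectors, forward/backward
orientation vectors for each backbone atom type, the two intra-residue
"side-chain" unit vectors (N->CA and CA->C), the phi/psi/omega backbone
torsions, per-residue canonical local frames, and confidence masking that
removes low-pLDDT residues from the geometry while keeping their sequence
identity visible to the model.

Scalar features (distances, torsions) are rotation-invariant; vector
features transform as f(R x) = R f(x). The tests assert both properties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import ProteinStructure

__all__ = [
    "FeatureBundle",
    "knn_graph",
    "edge_vectors",
    "orientation_vectors",
    "sidechain_vectors",
    "backbone_dihedrals",
    "canonical_frames",
    "rbf_encode",
    "featurize",
    "apply_plddt_mask",
]

ATOM_TYPES = ("n", "ca", "c")
_COLLINEAR_TOL = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when coordinates do not define the requested geometric quantity."""


@dataclass
class FeatureBundle:
    """All per-protein features, 0-based residue indexing.

    Edge-level arrays are aligned: ``edges[e] = (source, target)`` with
    ``edge_distance[e]`` and ``edge_vector[e]`` (unit, source CA -> target CA).
    ``orientation_forward[i, a]`` is the unit vector from residue i's atom of
    type a (N, CA, C) to residue i+1's same atom; flags mark defined entries.
    """

    protein_id: str
    n_residues: int
    ca: np.ndarray                     # (L, 3) kept so masking can rebuild the graph
    edges: np.ndarray                  # (E, 2) int
    edge_distance: np.ndarray          # (E,)
    edge_vector: np.ndarray            # (E, 3) unit
    orientation_forward: np.ndarray    # (L, 3, 3)
    orientation_backward: np.ndarray   # (L, 3, 3)
    orientation_defined: np.ndarray    # (L, 2) bool: [forward, backward]
    sidechain_vectors: np.ndarray      # (L, 2, 3) unit: N->CA, CA->C
    sidechain_defined: np.ndarray      # (L,) bool
    dihedrals: np.ndarray              # (L, 3) phi, psi, omega in (-pi, pi]
    dihedral_defined: np.ndarray       # (L, 3) bool
    plddt: np.ndarray                  # (L,)
    mask: np.ndarray                   # (L,) bool, True = geometry masked out
    tokens: np.ndarray                 # (L,) int
    seq_embedding: np.ndarray          # (L, d_emb)
    k: int

    def validate(self) -> None:
        L = self.n_residues
        assert self.ca.shape == (L, 3)
        assert self.edges.ndim == 2 and self.edges.shape[1] == 2
        E = len(self.edges)
        assert self.edge_distance.shape == (E,) and self.edge_vector.shape == (E, 3)
        if E:
            norms = np.linalg.norm(self.edge_vector, axis=1)
            assert np.all(np.abs(norms - 1.0) < 1e-6), "edge vectors must be unit"
            assert np.all(self.edge_distance >= 0)
        assert self.seq_embedding.shape[0] == L


def _pairwise_ca(structure: ProteinStructure) -> np.ndarray:
    return structure.coords("ca")


def _knn_from_coords(ca: np.ndarray, idx: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """kNN among the residues listed in ``idx``; ties broken by residue index.

    Distances are quantized to 1e-6 A for the ordering (never for the
    returned values) so the selected edge set is stable under rigid motions,
    which perturb exact ties at floating-point level.
    """
    sub = ca[idx]
    d = cdist(sub, sub)
    np.fill_diagonal(d, np.inf)
    kk = min(k, len(idx) - 1)
    key = np.round(d, 6)
    order = np.lexsort((np.broadcast_to(np.arange(len(idx)), d.shape), key), axis=1)[:, :kk]
    src = np.repeat(idx, kk)
    dst = idx[order].ravel()
    dist = np.take_along_axis(d, order, axis=1).ravel()
    return np.stack([src, dst], axis=1), dist


def knn_graph(
    structure: ProteinStructure, k: int, include: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Directed edges from every included residue to its k nearest included residues.

    Distances are CA-CA Euclidean; self edges are excluded and k caps at the
    number of available neighbours. ``include`` restricts both endpoints
    (used by confidence masking). Returns ``(edges, distances)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    L = len(structure)
    ca = _pairwise_ca(structure)
    if include is None:
        include = np.ones(L, dtype=bool)
    idx = np.nonzero(include)[0]
    if len(idx) <= 1:
        if len(idx) == 1:
            warnings.warn("structure has a single usable residue; empty edge set", stacklevel=2)
        return np.zeros((0, 2), dtype=int), np.zeros(0)
    return _knn_from_coords(ca, idx, k)


def edge_vectors(structure: ProteinStructure, edges: np.ndarray) -> np.ndarray:
    """Unit vectors from source CA to target CA for each edge."""
    ca = _pairwise_ca(structure)
    if len(edges) == 0:
        return np.zeros((0, 3))
    diff = ca[edges[:, 1]] - ca[edges[:, 0]]
    norms = np.linalg.norm(diff, axis=1)
    if np.any(norms < 1e-9):
        bad = edges[norms < 1e-9][0]
        raise DegenerateGeometryError(f"coincident CA coordinates on edge {tuple(bad)}")
    return diff / norms[:, None]


def orientation_vectors(
    structure: ProteinStructure,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vectors to the same backbone atom of the next / previous residue.

    Returns ``(forward, backward, defined)`` with shapes (L, 3, 3), (L, 3, 3)
    and (L, 2); undefined terminal entries are zero-filled.
    """
    L = len(structure)
    if L < 2:
        raise ValueError("orientation vectors need at least 2 residues")
    atoms = structure.backbone()  # (L, 3, 3) ordered N, CA, C
    forward = np.zeros((L, 3, 3))
    backward = np.zeros((L, 3, 3))
    diff = atoms[1:] - atoms[:-1]  # (L-1, 3, 3)
    norms = np.linalg.norm(diff, axis=2, keepdims=True)
    norms = np.where(norms < 1e-9, 1.0, norms)
    unit = diff / norms
    forward[:-1] = unit
    backward[1:] = -unit
    defined = np.zeros((L, 2), dtype=bool)
    defined[:-1, 0] = True
    defined[1:, 1] = True
    return forward, backward, defined


def sidechain_vectors(structure: ProteinStructure) -> np.ndarray:
    """Per-residue unit vectors N->CA and CA->C, shape (L, 2, 3)."""
    atoms = structure.backbone()
    v1 = atoms[:, 1] - atoms[:, 0]
    v2 = atoms[:, 2] - atoms[:, 1]
    out = np.stack([v1, v2], axis=1)
    norms = np.linalg.norm(out, axis=2)
    if np.any(norms < 1e-9):
        bad = int(np.nonzero(norms.min(axis=1) < 1e-9)[0][0])
        raise DegenerateGeometryError(f"zero-length backbone bond at residue {bad}")
    return out / norms[..., None]


def _torsion(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed torsion angle(s) in (-pi, pi] for stacked points; returns (angle, defined)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1, axis=-1)
    defined = (np.linalg.norm(n1, axis=-1) > _COLLINEAR_TOL) & (np.linalg.norm(n2, axis=-1) > _COLLINEAR_TOL)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.sum(n1 * n2, axis=-1)
        y = np.sum(np.cross(n1, n2) * (b1 / np.maximum(b1n, 1e-12)[..., None]), axis=-1)
        ang = np.arctan2(y, x)
    ang = np.where(defined, ang, 0.0)
    # map -pi to +pi so the planar all-trans case is exactly pi regardless of sign noise
    ang = np.where(np.isclose(ang, -np.pi), np.pi, ang)
    return ang, defined


def backbone_dihedrals(structure: ProteinStructure) -> tuple[np.ndarray, np.ndarray]:
    """Standard phi/psi/omega torsions per residue.

    phi_i  = torsion(C_{i-1}, N_i, CA_i, C_i)
    psi_i  = torsion(N_i, CA_i, C_i, N_{i+1})
    omega_i = torsion(CA_{i-1}, C_{i-1}, N_i, CA_i)

    Terminal and geometrically degenerate entries are flagged undefined and
    zero-filled (never NaN). Returns ``(angles, defined)`` of shape (L, 3).
    """
    L = len(structure)
    if L < 2:
        raise ValueError("dihedrals need at least 2 residues")
    N, CA, C = (structure.coords(a) for a in ATOM_TYPES)
    angles = np.zeros((L, 3))
    defined = np.zeros((L, 3), dtype=bool)
    phi, phi_def = _torsion(C[:-1], N[1:], CA[1:], C[1:])
    angles[1:, 0], defined[1:, 0] = phi, phi_def
    psi, psi_def = _torsion(N[:-1], CA[:-1], C[:-1], N[1:])
    angles[:-1, 1], defined[:-1, 1] = psi, psi_def
    omega, omega_def = _torsion(CA[:-1], C[:-1], N[1:], CA[1:])
    angles[1:, 2], defined[1:, 2] = omega, omega_def
    return angles, defined


def canonical_frames(structure: ProteinStructure) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue orthonormal local frame by Gram-Schmidt on the backbone.

    e1 along CA->C; e2 the component of CA->N orthogonal to e1; e3 = e1 x e2.
    Returns ``(rotations, origins)`` with rotations (L, 3, 3) whose *columns*
    are e1, e2, e3 (proper rotations, det = +1) and origins the CA positions.
    """
    atoms = structure.backbone()
    n, ca, c = atoms[:, 0], atoms[:, 1], atoms[:, 2]
    u = c - ca
    u_norm = np.linalg.norm(u, axis=1)
    if np.any(u_norm < 1e-9):
        raise DegenerateGeometryError("zero-length CA->C bond")
    e1 = u / u_norm[:, None]
    w = n - ca
    w = w - np.sum(w * e1, axis=1, keepdims=True) * e1
    w_norm = np.linalg.norm(w, axis=1)
    if np.any(w_norm < 1e-7):
        bad = int(np.nonzero(w_norm < 1e-7)[0][0])
        raise DegenerateGeometryError(f"collinear N, CA, C at residue {bad}")
    e2 = w / w_norm[:, None]
    e3 = np.cross(e1, e2)
    rot = np.stack([e1, e2, e3], axis=2)
    return rot, ca.copy()


def rbf_encode(distances: np.ndarray, n_centers: int = 16, d_min: float = 0.0, d_max: float = 20.0) -> np.ndarray:
    """Gaussian radial basis expansion of distances over [d_min, d_max]."""
    centers = np.linspace(d_min, d_max, n_centers)
    width = (d_max - d_min) / max(n_centers - 1, 1)
    d = np.asarray(distances, dtype=float)[..., None]
    return np.exp(-(((d - centers) / width) ** 2))


def featurize(
    structure: ProteinStructure,
    seq_embedding: np.ndarray,
    k: int = 30,
) -> FeatureBundle:
    """Compute the full unmasked feature bundle for one protein."""
    L = len(structure)
    seq_embedding = np.asarray(seq_embedding, dtype=float)
    if seq_embedding.ndim != 2 or seq_embedding.shape[0] != L:
        raise ValueError(f"seq_embedding must be (L={L}, d); got {seq_embedding.shape}")
    edges, dist = knn_graph(structure, k)
    evec = edge_vectors(structure, edges)
    if L >= 2:
        fwd, bwd, orient_def = orientation_vectors(structure)
        dihedrals, dih_def = backbone_dihedrals(structure)
    else:
        fwd = np.zeros((L, 3, 3))
        bwd = np.zeros((L, 3, 3))
        orient_def = np.zeros((L, 2), dtype=bool)
        dihedrals = np.zeros((L, 3))
        dih_def = np.zeros((L, 3), dtype=bool)
    sc = sidechain_vectors(structure)
    bundle = FeatureBundle(
        protein_id=structure.protein_id,
        n_residues=L,
        ca=structure.coords("ca"),
        edges=edges,
        edge_distance=dist,
        edge_vector=evec,
        orientation_forward=fwd,
        orientation_backward=bwd,
        orientation_defined=orient_def,
        sidechain_vectors=sc,
        sidechain_defined=np.ones(L, dtype=bool),
        dihedrals=dihedrals,
        dihedral_defined=dih_def,
        plddt=structure.plddt,
        mask=np.zeros(L, dtype=bool),
        tokens=structure.tokens(),
        seq_embedding=seq_embedding,
        k=k,
    )
    bundle.validate()
    return bundle


def apply_plddt_mask(bundle: FeatureBundle, threshold: float) -> FeatureBundle:
    """Mask geometry of residues whose pLDDT falls below ``threshold``.

    Masked residues keep their token, pLDDT value and sequence embedding but
    lose all vector/torsion features, and the kNN graph is rebuilt over the
    confident residues only, so a masked residue is never anyone's neighbour.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = bundle.plddt < threshold
    if mask.all():
        raise ValueError("no confident residues: every pLDDT is below the threshold")
    if not mask.any():
        return replace(bundle, mask=mask)
    keep = ~mask
    idx = np.nonzero(keep)[0]
    # rebuild the graph on the confident subset
    if len(idx) == 1:
        edges = np.zeros((0, 2), dtype=int)
        dist = np.zeros(0)
        evec = np.zeros((0, 3))
    else:
        edges, dist = _knn_from_coords(bundle.ca, idx, bundle.k)
        diff = bundle.ca[edges[:, 1]] - bundle.ca[edges[:, 0]]
        evec = diff / np.linalg.norm(diff, axis=1, keepdims=True)
    zero3 = mask[:, None, None]
    out = replace(
        bundle,
        edges=edges,
        edge_distance=dist,
        edge_vector=evec,
        orientation_forward=np.where(zero3, 0.0, bundle.orientation_forward),
        orientation_backward=np.where(zero3, 0.0, bundle.orientation_backward),
        orientation_defined=bundle.orientation_defined & keep[:, None],
        sidechain_vectors=np.where(zero3, 0.0, bundle.sidechain_vectors),
        sidechain_defined=bundle.sidechain_defined & keep,
        dihedrals=np.where(mask[:, None], 0.0, bundle.dihedrals),
        dihedral_defined=bundle.dihedral_defined & keep[:, None],
        mask=mask,
    )
    # neighbours of a masked residue must themselves be defined, so also drop
    # orientation vectors that point at masked residues
    L = bundle.n_residues
    for i in range(L):
        if keep[i]:
            if i + 1 < L and mask[i + 1]:
                out.orientation_forward[i] = 0.0
                out.orientation_defined[i, 0] = False
            if i - 1 >= 0 and mask[i - 1]:
                out.orientation_backward[i] = 0.0
                out.orientation_defined[i, 1] = False
    out.validate()
    return out
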