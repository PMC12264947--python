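"""Per-frame and per-residue structural descriptors.

Implements the scalar descriptors used for ensemble decomposition
(radius of gyration, end-to-end distance, solvent-accessible surface
area, polymer shape), rigid-body superposition and RMSF, and the two
contact-map statistics (minimum residue-residue distance and hydrogen
bonds per frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .ensemble import Ensemble, ScalarSeries
from .errors import (
    DegenerateInputError,
    MissingHydrogenError,
    ParameterError,
    SelectionError,
)

__all__ = [
    "ContactMap",
    "ResidueProfile",
    "radius_of_gyration",
    "end_to_end_distance",
    "polymer_shape",
    "sasa_shrake_rupley",
    "kabsch_superpose",
    "rmsf",
    "min_distance_map",
    "mean_min_pair_distance",
    "hbond_contact_map",
]


@dataclass
class ContactMap:
    """Residue × residue contact statistic."""

    matrix: np.ndarray
    statistic: str  # "min_distance" | "hbonds_per_frame"
    units: str
    normalization: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ParameterError("contact map must be square")
        if self.statistic == "min_distance":
            if not np.allclose(self.matrix, self.matrix.T):
                raise ParameterError("min-distance map must be symmetric")
            if np.any(np.diag(self.matrix) != 0) or np.any(self.matrix < 0):
                raise ParameterError("min-distance map must be >= 0 with zero diagonal")


@dataclass
class ResidueProfile:
    """One named real value per residue (RMSF, per-residue SASA, ...)."""

    name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("profile must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError(f"profile {self.name!r} contains non-finite values")


# ---------------------------------------------------------------------------
# Scalar descriptors
# ---------------------------------------------------------------------------

def radius_of_gyration(ensemble: Ensemble, mass_weighted: bool = True) -> ScalarSeries:
    """Per-frame radius of gyration, Å.

    Rg = sqrt( Σ_i w_i |r_i − r̄|² / Σ_i w_i ) with w_i the atomic mass
    (default, the ``gmx gyrate`` convention) or 1.
    """
    w = ensemble.masses if mass_weighted else np.ones(ensemble.n_atoms)
    wsum = w.sum()
    if wsum <= 0:
        raise DegenerateInputError("all weights are zero; cannot mass-weight Rg")
    centroid = np.einsum("fab,a->fb", ensemble.coords, w) / wsum
    dev = ensemble.coords - centroid[:, None, :]
    rg2 = np.einsum("fab,fab,a->f", dev, dev, w) / wsum
    return ScalarSeries("Rg", np.sqrt(rg2), "Å")


def end_to_end_distance(
    ensemble: Ensemble,
    start_atom: tuple[int, str] | None = None,
    end_atom: tuple[int, str] | None = None,
) -> ScalarSeries:
    """Per-frame Euclidean distance between two atoms, Å.

    Defaults: backbone N of the first residue to backbone C of the last
    residue. Selectors are ``(residue_number, atom_name)`` pairs and
    must resolve to exactly one atom.
    """
    if start_atom is None:
        start_atom = (1, "N")
    if end_atom is None:
        end_atom = (ensemble.n_residues, "C")
    i = ensemble.select_one(*start_atom)
    j = ensemble.select_one(*end_atom)
    d = np.linalg.norm(ensemble.coords[:, i, :] - ensemble.coords[:, j, :], axis=1)
    return ScalarSeries("Ree", d, "Å")


def polymer_shape(rg: ScalarSeries, ree: ScalarSeries) -> ScalarSeries:
    """Polymer shape P_S = Ree² / Rg² per frame (12 for a thin rod,
    ≈6.3 for an ideal chain, smaller for compact globules)."""
    if len(rg) != len(ree):
        raise ParameterError("Rg and Ree series have different lengths")
    zero = np.flatnonzero(rg.values == 0)
    if zero.size:
        raise DegenerateInputError(
            f"Rg is zero in frame(s) {zero[:5].tolist()}; P_S undefined"
        )
    return ScalarSeries("P_S", ree.values**2 / rg.values**2, "")


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_shrake_rupley(
    ensemble: Ensemble,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> tuple[ScalarSeries, np.ndarray]:
    """Solvent-accessible surface area by the Shrake–Rupley method.

    For every atom, test points on a sphere of radius r_vdw + probe are
    checked for burial inside any neighbor's expanded sphere; the
    accessible fraction times the expanded-sphere area is the atomic
    SASA. Returns the per-frame total (Å²) and a
    ``(n_frames, n_residues)`` per-residue SASA array.
    """
    if probe_radius < 0:
        raise ParameterError("probe radius must be non-negative")
    radii = ensemble.radii + probe_radius
    pts = _sphere_points(n_sphere_points)
    areas = 4.0 * np.pi * radii**2
    n_res = ensemble.n_residues
    res_of_atom = ensemble.residue_index - 1
    per_res = np.zeros((ensemble.n_frames, n_res))
    total = np.zeros(ensemble.n_frames)
    rmax = radii.max()
    for f in range(ensemble.n_frames):
        xyz = ensemble.coords[f]
        tree = cKDTree(xyz)
        for a in range(ensemble.n_atoms):
            neighbors = [
                j for j in tree.query_ball_point(xyz[a], radii[a] + rmax)
                if j != a and np.linalg.norm(xyz[j] - xyz[a]) < radii[a] + radii[j]
            ]
            if neighbors:
                test = xyz[a] + radii[a] * pts  # (n, 3)
                d = cdist(test, xyz[neighbors])  # (n, k)
                # points exactly on a neighbor's expanded sphere count as
                # buried (coincident identical atoms have zero SASA)
                accessible = np.all(d > radii[neighbors][None, :] + 1e-8, axis=1)
                frac = accessible.mean()
            else:
                frac = 1.0
            contrib = frac * areas[a]
            per_res[f, res_of_atom[a]] += contrib
            total[f] += contrib
    return ScalarSeries("SASA", total, "Å²"), per_res


# ---------------------------------------------------------------------------
# Superposition / RMSF
# ---------------------------------------------------------------------------

def kabsch_superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    atom_subset: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to the
    reference over the fitted subset. The rotation is proper (det +1).
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    sub = np.arange(len(reference)) if atom_subset is None else np.asarray(atom_subset)
    if len(sub) < 3:
        raise DegenerateInputError("need at least 3 atoms to superpose")
    P = mobile[sub] - mobile[sub].mean(axis=0)
    Q = reference[sub] - reference[sub].mean(axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # collinearity: rank of the cross-covariance < 2
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise DegenerateInputError("superposition subset is (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = reference[sub].mean(axis=0) - mobile[sub].mean(axis=0) @ R.T
    moved = mobile[sub] @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference[sub]) ** 2, axis=1))))
    return R, t, rmsd


def _backbone_subset(ensemble: Ensemble) -> np.ndarray:
    mask = np.isin(ensemble.atom_names, ("N", "CA", "C"))
    return np.flatnonzero(mask) if mask.any() else np.arange(ensemble.n_atoms)


def rmsf(ensemble: Ensemble, superpose_subset: np.ndarray | None = None) -> ResidueProfile:
    """Root-mean-square fluctuation per residue, Å.

    Two-pass procedure: all frames are superposed onto the running mean
    structure (two iterations, backbone-atom fit by default), then the
    per-atom fluctuation sqrt(⟨|r − ⟨r⟩|²⟩) is averaged within each
    residue.
    """
    if ensemble.n_frames < 2:
        raise ParameterError("RMSF requires at least 2 frames")
    sub = _backbone_subset(ensemble) if superpose_subset is None else superpose_subset
    coords = ensemble.coords.copy()
    # pre-align to frame 0 so the initial mean does not depend on each
    # frame's arbitrary global placement
    for f in range(1, len(coords)):
        R, t, _ = kabsch_superpose(coords[0], coords[f], sub)
        coords[f] = coords[f] @ R.T + t
    for _ in range(2):
        mean = coords.mean(axis=0)
        for f in range(len(coords)):
            R, t, _ = kabsch_superpose(mean, coords[f], sub)
            coords[f] = coords[f] @ R.T + t
    mean = coords.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    values = np.array(
        [atom_rmsf[ensemble.residue_index == r].mean() for r in range(1, ensemble.n_residues + 1)]
    )
    return ResidueProfile("RMSF", values, "Å")


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

def _residue_starts(ensemble: Ensemble) -> np.ndarray:
    """Atom index at which each residue starts (atoms are residue-sorted)."""
    return np.searchsorted(ensemble.residue_index, np.arange(1, ensemble.n_residues + 1))


def _frame_min_res_distances(ensemble: Ensemble, xyz: np.ndarray) -> np.ndarray:
    """(R, R) matrix of per-residue-pair minimum atom distances for one frame."""
    d = cdist(xyz, xyz)
    starts = _residue_starts(ensemble)
    d = np.minimum.reduceat(d, starts, axis=0)
    d = np.minimum.reduceat(d, starts, axis=1)
    return d


def min_distance_map(
    ensemble: Ensemble,
    frames: np.ndarray | None = None,
    normalize: bool = False,
) -> ContactMap:
    """Minimum residue-residue distance over the selected frames, Å.

    Entry (i, j) is the smallest interatomic distance between residues
    i and j observed in any selected frame. With ``normalize`` the map
    is rescaled to [0, 1] by its largest entry.
    """
    if frames is None:
        frames = np.arange(ensemble.n_frames)
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0:
        raise ParameterError("empty frame selection")
    n = ensemble.n_residues
    m = np.full((n, n), np.inf)
    for f in frames:
        np.minimum(m, _frame_min_res_distances(ensemble, ensemble.coords[f]), out=m)
    np.fill_diagonal(m, 0.0)
    note = None
    if normalize:
        peak = m.max()
        if peak > 0:
            m = m / peak
            note = f"divided by max distance {peak:.3f} Å"
    return ContactMap(m, "min_distance", "" if normalize else "Å", note)


def mean_min_pair_distance(
    ensemble: Ensemble,
    pair: tuple[int, int],
    frames: np.ndarray | None = None,
) -> float:
    """Average over frames of the per-frame minimum interatomic distance
    between two (1-based) residues, Å.

    Contrast with :func:`min_distance_map`, which takes the global
    minimum over all frames.
    """
    i, j = pair
    if i == j:
        raise SelectionError("pair must name two distinct residues")
    for r in (i, j):
        if not 1 <= r <= ensemble.n_residues:
            raise SelectionError(f"residue {r} out of range 1..{ensemble.n_residues}")
    if frames is None:
        frames = np.arange(ensemble.n_frames)
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0:
        raise ParameterError("empty frame selection")
    ai = np.flatnonzero(ensemble.residue_index == i)
    aj = np.flatnonzero(ensemble.residue_index == j)
    vals = [cdist(ensemble.coords[f][ai], ensemble.coords[f][aj]).min() for f in frames]
    return float(np.mean(vals))


def _donor_pairs(ensemble: Ensemble, bond_cut: float = 1.25) -> tuple[np.ndarray, np.ndarray]:
    """(hydrogen_index, donor_heavy_index) pairs, inferred from frame-0
    geometry: each H is bonded to its nearest N/O within ``bond_cut`` Å."""
    names = np.char.lstrip(ensemble.atom_names, "0123456789")
    h_idx = np.flatnonzero(np.char.startswith(names, "H"))
    heavy = np.flatnonzero(
        np.char.startswith(names, "N") | np.char.startswith(names, "O")
    )
    if h_idx.size == 0:
        raise MissingHydrogenError(
            "topology contains no hydrogens; hydrogen-bond analysis requires them"
        )
    xyz = ensemble.coords[0]
    d = cdist(xyz[h_idx], xyz[heavy])
    nearest = d.argmin(axis=1)
    keep = d[np.arange(len(h_idx)), nearest] < bond_cut
    return h_idx[keep], heavy[nearest[keep]]


def hbond_contact_map(
    ensemble: Ensemble,
    frames: np.ndarray | None = None,
    d_cut: float = 3.5,
    angle_cut: float = 30.0,
    symmetrize: bool = False,
) -> ContactMap:
    """Hydrogen bonds per frame for every residue pair.

    Geometric criterion (the common trajectory-tool default): donor–acceptor distance
    ≤ ``d_cut`` (3.5 Å) and hydrogen–donor–acceptor angle ≤
    ``angle_cut`` (30°). Donors are N/O atoms with a covalent hydrogen;
    acceptors are all N/O atoms. Rows are donor residues unless
    ``symmetrize`` is set.
    """
    if frames is None:
        frames = np.arange(ensemble.n_frames)
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0:
        raise ParameterError("empty frame selection")
    h_idx, don_idx = _donor_pairs(ensemble)
    names = np.char.lstrip(ensemble.atom_names, "0123456789")
    acc_idx = np.flatnonzero(
        np.char.startswith(names, "N") | np.char.startswith(names, "O")
    )
    n = ensemble.n_residues
    counts = np.zeros((n, n))
    cos_cut = np.cos(np.deg2rad(angle_cut))
    res = ensemble.residue_index - 1
    for f in frames:
        xyz = ensemble.coords[f]
        d_da = cdist(xyz[don_idx], xyz[acc_idx])  # (nd, na)
        within = d_da <= d_cut
        within[:, :] &= don_idx[:, None] != acc_idx[None, :]
        dh = xyz[h_idx] - xyz[don_idx]  # D->H
        dh /= np.linalg.norm(dh, axis=1, keepdims=True)
        for k in np.flatnonzero(within.any(axis=1)):
            acc_ok = np.flatnonzero(within[k])
            da = xyz[acc_idx[acc_ok]] - xyz[don_idx[k]]
            da /= np.linalg.norm(da, axis=1, keepdims=True)
            cosang = da @ dh[k]
            good = acc_ok[cosang >= cos_cut]
            np.add.at(counts, (np.full(len(good), res[don_idx[k]]), res[acc_idx[good]]), 1.0)
    counts /= len(frames)
    if symmetrize:
        counts = counts + counts.T
    return ContactMap(counts, "hbonds_per_frame", "bonds·frame⁻¹")
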