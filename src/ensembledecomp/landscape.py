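"""Dihedral featurization, dimensionality reduction, and free-energy landscapes.

Backbone φ/ψ angles are the features: φ_i = C(i−1)–N(i)–CA(i)–C(i),
ψ_i = N(i)–CA(i)–C(i)–N(i+1), encoded as sin/cos pairs to remove the
±180° periodicity. Two projections are offered: PCA (variance-ordered)
and tICA, which solves the generalized eigenproblem C(τ) v = λ C(0) v
on mean-free features so the leading components capture the slowest
decorrelating motions rather than the largest-amplitude ones.

A 2D free-energy landscape over a projection is the Boltzmann inversion
of the bin occupancy: ΔF_i = −k_B T ln(n_i / n_max). The most populated
bin sits at ΔF = 0; optionally the field is shifted so the least
populated occupied bin sits at 0 instead ("highest energy state set to
zero"). Unoccupied bins are masked, never ±∞.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import numpy.ma as ma
import scipy.linalg

from .ensemble import Ensemble
from .errors import DegenerateInputError, ParameterError, TopologyError

logger = logging.getLogger(__name__)

#: Boltzmann constant, kJ·mol⁻¹·K⁻¹.
KB_KJ_PER_MOL_K = 0.008314462618

__all__ = [
    "FeatureMatrix",
    "FreeEnergyLandscape",
    "dihedral_features",
    "pca_project",
    "tica_project",
    "free_energy_landscape",
]


@dataclass
class FeatureMatrix:
    """Frames × features matrix with column names."""

    data: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("feature matrix contains non-finite values")
        if len(self.feature_names) != self.data.shape[1]:
            raise ParameterError("feature_names length mismatch")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


@dataclass
class FreeEnergyLandscape:
    """2D grid of ΔF values with bin edges and an occupancy mask."""

    grid: ma.MaskedArray  # ΔF; masked where the bin is unoccupied
    x_edges: np.ndarray
    y_edges: np.ndarray
    temperature: float
    units: str  # "kT" or "kJ/mol"
    reference: str


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed torsion angle (radians) for stacked point arrays (..., 3)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return np.arctan2(-y, x)  # IUPAC sign convention (right-handed helix: φ < 0)


def dihedral_features(ensemble: Ensemble) -> FeatureMatrix:
    """sin/cos-encoded backbone φ/ψ features for every residue that has
    both angles defined (residues 2 .. n−1 of a linear chain)."""
    n_res = ensemble.n_residues
    if n_res < 3:
        raise TopologyError("need at least 3 residues for a residue with both φ and ψ")
    idx: dict[tuple[int, str], int] = {}
    for r in range(1, n_res + 1):
        for name in ("N", "CA", "C"):
            try:
                idx[(r, name)] = ensemble.select_one(r, name)
            except Exception as exc:
                raise TopologyError(
                    f"backbone atom {name} missing or ambiguous in residue {r}"
                ) from exc
    cols = []
    names = []
    X = ensemble.coords
    for r in range(2, n_res):
        phi = _dihedral(
            X[:, idx[(r - 1, "C")]], X[:, idx[(r, "N")]],
            X[:, idx[(r, "CA")]], X[:, idx[(r, "C")]],
        )
        psi = _dihedral(
            X[:, idx[(r, "N")]], X[:, idx[(r, "CA")]],
            X[:, idx[(r, "C")]], X[:, idx[(r + 1, "N")]],
        )
        cols += [np.sin(phi), np.cos(phi), np.sin(psi), np.cos(psi)]
        names += [f"sin_phi_{r}", f"cos_phi_{r}", f"sin_psi_{r}", f"cos_psi_{r}"]
    return FeatureMatrix(np.column_stack(cols), names)


def dihedral_angles(ensemble: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """Raw (φ, ψ) in degrees, shape (n_frames, n_residues); NaN where
    an angle is undefined (φ of residue 1, ψ of the last residue)."""
    n_res = ensemble.n_residues
    X = ensemble.coords
    get = ensemble.select_one
    phi = np.full((ensemble.n_frames, n_res), np.nan)
    psi = np.full((ensemble.n_frames, n_res), np.nan)
    for r in range(1, n_res + 1):
        if r > 1:
            phi[:, r - 1] = np.rad2deg(_dihedral(
                X[:, get(r - 1, "C")], X[:, get(r, "N")],
                X[:, get(r, "CA")], X[:, get(r, "C")],
            ))
        if r < n_res:
            psi[:, r - 1] = np.rad2deg(_dihedral(
                X[:, get(r, "N")], X[:, get(r, "CA")],
                X[:, get(r, "C")], X[:, get(r + 1, "N")],
            ))
    return phi, psi


def pca_project(
    features: FeatureMatrix, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal-component projection of the feature matrix.

    Returns ``(projections, explained_variance_ratio, components)``.
    Components carry a deterministic sign convention: the
    largest-magnitude loading of each component is positive. Requesting
    more components than the matrix rank logs a warning and reduces the
    request.
    """
    if features.n_frames < 2:
        raise ParameterError("PCA needs at least 2 frames")
    if n_components > features.n_features:
        raise ParameterError("n_components exceeds the number of features")
    X = features.data - features.data.mean(axis=0)
    cov = X.T @ X / (len(X) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > 1e-12 * max(evals[0], 1.0)))
    if n_components > rank:
        logger.warning("requested %d components but rank is %d", n_components, rank)
    comps = evecs[:, :n_components].T  # (k, d)
    # sign convention
    for c in comps:
        if c[np.argmax(np.abs(c))] < 0:
            c *= -1.0
    proj = X @ comps.T
    ratio = np.clip(evals[:n_components], 0, None) / max(evals.clip(min=0).sum(), 1e-300)
    return proj, ratio, comps


def tica_project(
    features: FeatureMatrix,
    lag: int = 50,
    n_components: int = 2,
    epsilon: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-lagged independent component analysis.

    Solves C(τ) v = λ C(0) v with the symmetrized lagged covariance
    C(τ) and a ridge-regularized instantaneous covariance C(0) + εI on
    mean-free features. Returns ``(projections, eigenvalues,
    components)`` ordered by decreasing eigenvalue; after
    symmetrization the eigenvalues are real autocorrelations with
    |λ| ≤ 1 (up to regularization error).
    """
    if lag < 1:
        raise ParameterError("lag must be >= 1 frame")
    if lag >= features.n_frames:
        raise ParameterError(
            f"lag ({lag}) must be smaller than the number of frames ({features.n_frames})"
        )
    X = features.data - features.data.mean(axis=0)
    X0, Xt = X[:-lag], X[lag:]
    n = len(X0)
    C0 = (X0.T @ X0 + Xt.T @ Xt) / (2.0 * n)
    Ct = (X0.T @ Xt + Xt.T @ X0) / (2.0 * n)
    C0reg = C0 + epsilon * np.eye(C0.shape[0])
    try:
        evals, evecs = scipy.linalg.eigh(Ct, C0reg)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(
            "instantaneous covariance is singular; increase the ridge epsilon"
        ) from exc
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if n_components > len(evals):
        raise ParameterError("n_components exceeds the number of features")
    comps = evecs[:, :n_components].T
    for c in comps:
        if c[np.argmax(np.abs(c))] < 0:
            c *= -1.0
    proj = X @ comps.T
    return proj, evals[:n_components], comps


def free_energy_landscape(
    projection: np.ndarray,
    n_bins: int = 64,
    temperature: float = 298.0,
    shift_to_zero_max: bool = False,
    units: str = "kT",
) -> FreeEnergyLandscape:
    """Boltzmann-inverted 2D histogram of a projection.

    ΔF_i = −k_B T ln(n_i / n_max) over occupied bins; the most
    populated bin is the zero of energy. With ``shift_to_zero_max`` the
    maximum occupied ΔF is subtracted instead, putting the least
    populated occupied bin at 0 and all others below. ``units`` is
    ``"kT"`` (ΔF in multiples of k_B T) or ``"kJ/mol"``.
    """
    points = np.asarray(projection, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ParameterError("projection must be an (n, 2) array")
    if len(points) < 1:
        raise ParameterError("need at least one point")
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    if np.ptp(points[:, 0]) == 0 and np.ptp(points[:, 1]) == 0:
        logger.warning("all points identical; landscape degenerates to one bin")
    counts, x_edges, y_edges = np.histogram2d(points[:, 0], points[:, 1], bins=n_bins)
    occupied = counts > 0
    kt = 1.0 if units == "kT" else KB_KJ_PER_MOL_K * temperature
    if units not in ("kT", "kJ/mol"):
        raise ParameterError(f"unknown units {units!r}; use 'kT' or 'kJ/mol'")
    grid = ma.masked_array(np.zeros_like(counts), mask=~occupied)
    grid[occupied] = -kt * np.log(counts[occupied] / counts.max())
    reference = "n_max bin at 0"
    if shift_to_zero_max:
        grid = grid - grid.max()
        reference = "least-populated occupied bin at 0"
    return FreeEnergyLandscape(
        grid=grid,
        x_edges=x_edges,
        y_edges=y_edges,
        temperature=temperature,
        units=units,
        reference=reference,
    )
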