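"""Synthetic conformer and fixture generators.

Everything the analysis modules consume can be generated here at desk
scale with known ground truth: dihedral-built peptide backbones with
tunable compactness (helix-like vs extended/PPII basins), ensembles
spanning compact-to-extended conformers whose Rg/Ree/SASA are broad and
mutually correlated, secondary-structure label series with planted
trends, two-state time series for tICA validation, and closed-form
Gaussian-chain (Debye) scattering curves.

Backbones use ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
trans ω = 180°) with backbone N, H, CA, C, O atoms only; self-clashes
are not resolved. Every generator is a pure, seed-deterministic
function of its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Ensemble, ScalarSeries, ScatterCurve, SecondaryStructureSeries
from .errors import ParameterError
from .landscape import FeatureMatrix

__all__ = [
    "GeneratorSpec",
    "gen_backbone_ensemble",
    "gen_heterogeneous_ensemble",
    "gen_ss_labels",
    "gen_two_state_series",
    "gen_gaussian_chain_curve",
]

# ideal backbone geometry (Å, degrees)
B_N_CA, B_CA_C, B_C_N = 1.458, 1.525, 1.329
B_C_O, B_N_H = 1.229, 1.010
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.0, 116.6, 121.9
A_CA_C_O, A_C_N_H = 120.5, 119.0

# dihedral basins: helix-like (compact) and extended/PPII
HELIX_BASIN = (-57.8, -47.0)
EXTENDED_BASIN = (-70.0, 145.0)


@dataclass
class GeneratorSpec:
    """Conditions for one synthetic ensemble.

    ``compactness`` ∈ [0, 1] is the per-residue probability of sampling
    the helix basin instead of the extended/PPII basin. ``helix_span``
    optionally plants an always-helical 1-based inclusive residue range
    with tight dihedral jitter so the i→i+4 hydrogen-bond geometry is
    near-ideal.
    """

    n_residues: int = 38
    n_frames: int = 200
    compactness: float = 0.3
    seed: int = 0
    jitter_deg: float = 15.0
    helix_span: tuple[int, int] | None = None
    helix_jitter_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ParameterError("need at least 2 residues")
        if self.n_frames < 1:
            raise ParameterError("need at least 1 frame")
        if not 0.0 <= self.compactness <= 1.0:
            raise ParameterError("compactness must be in [0, 1]")
        if self.helix_span is not None:
            lo, hi = self.helix_span
            if not (1 <= lo <= hi <= self.n_residues):
                raise ParameterError("helix_span out of residue range")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: np.ndarray | float) -> np.ndarray:
    """NeRF placement: position d with |c−d| = bond, angle(b,c,d) =
    angle, dihedral(a,b,c,d) = torsion. All point args are (..., 3)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(np.asarray(torsion_deg))
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * np.cos(angle) * np.ones_like(torsion),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ],
        axis=-1,
    )
    return c + d_local[..., 0:1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n


def _build_frames(phi: np.ndarray, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build backbone coordinates from dihedrals.

    phi, psi: (n_frames, n_residues), degrees; phi[:, 0] is ignored.
    Returns (coords, atom_names, residue_index); atoms per residue are
    N, [H], CA, C, O with H absent in residue 1.
    """
    F, R = phi.shape
    pos: dict[tuple[int, str], np.ndarray] = {}
    pos[(1, "N")] = np.zeros((F, 3))
    pos[(1, "CA")] = np.tile([B_N_CA, 0.0, 0.0], (F, 1))
    ang = np.deg2rad(A_N_CA_C)
    pos[(1, "C")] = pos[(1, "CA")] + B_CA_C * np.array(
        [np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0]
    )
    for r in range(2, R + 1):
        pos[(r, "N")] = _place(
            pos[(r - 1, "N")], pos[(r - 1, "CA")], pos[(r - 1, "C")],
            B_C_N, A_CA_C_N, psi[:, r - 2],
        )
        pos[(r - 1, "O")] = _place(
            pos[(r - 1, "N")], pos[(r - 1, "CA")], pos[(r - 1, "C")],
            B_C_O, A_CA_C_O, psi[:, r - 2] + 180.0,
        )
        pos[(r, "CA")] = _place(
            pos[(r - 1, "CA")], pos[(r - 1, "C")], pos[(r, "N")],
            B_N_CA, A_C_N_CA, 180.0 * np.ones(F),
        )
        pos[(r, "H")] = _place(
            pos[(r - 1, "O")], pos[(r - 1, "C")], pos[(r, "N")],
            B_N_H, A_C_N_H, 180.0 * np.ones(F),
        )
        pos[(r, "C")] = _place(
            pos[(r - 1, "C")], pos[(r, "N")], pos[(r, "CA")],
            B_CA_C, A_N_CA_C, phi[:, r - 1],
        )
    # last-residue carbonyl oxygen from the drawn (otherwise unused) psi
    pos[(R, "O")] = _place(
        pos[(R, "N")], pos[(R, "CA")], pos[(R, "C")],
        B_C_O, A_CA_C_O, psi[:, R - 1] + 180.0,
    )
    atom_names: list[str] = []
    residue_index: list[int] = []
    stacks: list[np.ndarray] = []
    for r in range(1, R + 1):
        names = ["N", "CA", "C", "O"] if r == 1 else ["N", "H", "CA", "C", "O"]
        for nm in names:
            atom_names.append(nm)
            residue_index.append(r)
            stacks.append(pos[(r, nm)])
    coords = np.stack(stacks, axis=1)
    return coords, np.array(atom_names), np.array(residue_index)


def _sample_dihedrals(spec: GeneratorSpec, rng: np.random.Generator,
                      compactness_per_frame: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    F, R = spec.n_frames, spec.n_residues
    helix = rng.random((F, R)) < compactness_per_frame[:, None]
    jitter = np.full((F, R), spec.jitter_deg)
    if spec.helix_span is not None:
        lo, hi = spec.helix_span
        helix[:, lo - 1:hi] = True
        jitter[:, lo - 1:hi] = spec.helix_jitter_deg
    phi = np.where(helix, HELIX_BASIN[0], EXTENDED_BASIN[0]) + rng.normal(0, 1, (F, R)) * jitter
    psi = np.where(helix, HELIX_BASIN[1], EXTENDED_BASIN[1]) + rng.normal(0, 1, (F, R)) * jitter
    phi[:, 0] = np.nan  # undefined for the first residue; not used in building
    return phi, psi, helix


def gen_backbone_ensemble(spec: GeneratorSpec) -> tuple[Ensemble, dict]:
    """Dihedral-built backbone ensemble with ground truth.

    Returns ``(ensemble, truth)`` where ``truth`` holds the sampled
    ``phi``/``psi`` (degrees; phi of residue 1 is NaN, psi of the last
    residue is used only to place its carbonyl oxygen) and the boolean
    helix-basin assignment per residue and frame.
    """
    rng = np.random.default_rng(spec.seed)
    comp = np.full(spec.n_frames, spec.compactness)
    phi, psi, helix = _sample_dihedrals(spec, rng, comp)
    coords, atom_names, residue_index = _build_frames(np.nan_to_num(phi), psi)
    ens = Ensemble(
        coords=coords,
        atom_names=atom_names,
        residue_index=residue_index,
        residue_names=np.array(["ALA"] * spec.n_residues),
    )
    return ens, {"phi": phi, "psi": psi, "helix_basin": helix, "compactness": comp}


def gen_heterogeneous_ensemble(
    spec: GeneratorSpec, beta_a: float = 1.2, beta_b: float = 1.2
) -> tuple[Ensemble, dict]:
    """Ensemble spanning compact to extended conformers.

    Per-frame compactness is drawn from Beta(a, b) (default Beta(1.2,
    1.2): broad with populated tails), so Rg, Ree and SASA are broad
    and mutually positively correlated and an X_conf decomposition at
    α = 5 populates several integer groups around 15.
    """
    if spec.n_frames < 100:
        raise ParameterError("heterogeneous ensembles need >= 100 frames")
    rng = np.random.default_rng(spec.seed)
    comp = rng.beta(beta_a, beta_b, size=spec.n_frames)
    phi, psi, helix = _sample_dihedrals(spec, rng, comp)
    coords, atom_names, residue_index = _build_frames(np.nan_to_num(phi), psi)
    ens = Ensemble(
        coords=coords,
        atom_names=atom_names,
        residue_index=residue_index,
        residue_names=np.array(["ALA"] * spec.n_residues),
    )
    return ens, {"phi": phi, "psi": psi, "helix_basin": helix, "compactness": comp}


def gen_ss_labels(
    ree: ScalarSeries,
    n_residues: int,
    seed: int = 0,
    p_trend: float = 0.3,
    helix_span: tuple[int, int] | None = None,
) -> SecondaryStructureSeries:
    """Secondary-structure labels with an extension-correlated PPII trend.

    Class probabilities depend on each frame's Ree percentile u: the
    PPII ('P') probability rises linearly with u by ``p_trend`` (may be
    negative or zero), compensated in the unassigned class '~'.
    Residues in ``helix_span`` (1-based, inclusive) are always 'H'.
    """
    rng = np.random.default_rng(seed)
    n_frames = len(ree)
    ranks = np.argsort(np.argsort(ree.values))
    u = (ranks + 0.5) / n_frames
    base = {"H": 0.08, "G": 0.04, "E": 0.05, "B": 0.03, "T": 0.12, "S": 0.12, "P": 0.25}
    if helix_span is not None:
        # planted helices are the dominant helical signal; keep stray
        # background H rare so the span carries the profile mass
        base["H"] = 0.01
    classes = list(base) + ["~"]
    labels = np.empty((n_frames, n_residues), dtype="U1")
    for f in range(n_frames):
        p = dict(base)
        p["P"] = base["P"] + p_trend * (u[f] - 0.5)
        p["P"] = min(max(p["P"], 0.0), 0.9)
        rest = 1.0 - sum(p.values())
        if rest < 0:
            raise ParameterError("class probabilities exceed 1; reduce p_trend")
        probs = np.array(list(p.values()) + [rest])
        labels[f] = rng.choice(classes, size=n_residues, p=probs)
    if helix_span is not None:
        lo, hi = helix_span
        if not (1 <= lo <= hi <= n_residues):
            raise ParameterError("helix_span out of residue range")
        labels[:, lo - 1:hi] = "H"
    return SecondaryStructureSeries(labels=labels)


def gen_two_state_series(
    n_frames: int,
    switch_prob: float = 0.01,
    n_channels: int = 6,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Symmetric two-state Markov chain embedded in noisy channels.

    Each channel reads the hidden state (±1) through its own loading
    plus i.i.d. Gaussian noise. Returns the feature matrix and the true
    state sequence — the ground truth for tICA recovery tests.
    """
    if not 0.0 < switch_prob < 1.0:
        raise ParameterError("switch_prob must be in (0, 1)")
    if n_frames < 2 or n_channels < 1:
        raise ParameterError("need n_frames >= 2 and n_channels >= 1")
    rng = np.random.default_rng(seed)
    flips = rng.random(n_frames) < switch_prob
    states = np.where(np.cumsum(flips) % 2 == 0, 1, -1)
    loadings = rng.normal(1.0, 0.3, n_channels) * rng.choice([-1.0, 1.0], n_channels)
    data = states[:, None] * loadings[None, :] + rng.normal(0, noise_sd, (n_frames, n_channels))
    names = [f"channel_{i}" for i in range(n_channels)]
    return FeatureMatrix(data, names), states


def gen_gaussian_chain_curve(
    rg: float,
    q_grid: np.ndarray,
    noise_fraction: float = 0.0,
    seed: int = 0,
    i0: float = 1.0,
) -> ScatterCurve:
    """Debye Gaussian-chain scattering curve of known Rg.

    I(q)/I(0) = 2(e^(−x) + x − 1)/x² with x = (qRg)². With
    ``noise_fraction`` > 0, multiplicative Gaussian noise of that
    relative size is applied and reported in the sigma column.
    """
    if rg <= 0:
        raise ParameterError("rg must be positive")
    if noise_fraction < 0:
        raise ParameterError("noise_fraction must be >= 0")
    q = np.asarray(q_grid, dtype=float)
    x = (q * rg) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        form = 2.0 * (np.expm1(-x) + x) / x**2
    # series branch: cancellation makes the closed form lose precision
    small = x < 1e-4
    xs = x[small]
    form[small] = 1.0 - xs / 3.0 + xs**2 / 12.0
    I = i0 * form
    sigma = None
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_fraction * I
        I = I * (1.0 + noise_fraction * rng.normal(size=len(q)))
    return ScatterCurve(q=q, I=I, sigma=sigma)
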