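"""Small-angle X-ray scattering curve processing and model comparison.

Covers the standard reduction chain for comparing a measured curve with
an ensemble-derived model curve: block rebinning, I(0) or fixed-q
normalization, an iterative Guinier fit (I(q) ≈ I(0)·exp(−q²Rg²/3),
restricted to q·Rg ≤ 1.1 by default), the dimensionless Kratky
transform (qRg)²·I(q)/I(0), and the goodness-of-fit statistic

    χ² = Σ_i (E_i − S_i)² / S_i

over experimental points E and model points S on a common grid (both
curves are expected to be I(0)-normalized; no division by N). A Debye
unit-form-factor calculator, I(q) = Σ_ij sinc(q·r_ij), produces model
curves directly from coordinates for testing and desk-scale use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import ScatterCurve
from .errors import FitError, ParameterError

__all__ = [
    "GuinierFit",
    "rebin_join",
    "normalize_curve",
    "chi_squared",
    "chi_squared_on_common_grid",
    "guinier_rg",
    "kratky_normalized",
    "debye_scatter",
]


@dataclass
class GuinierFit:
    """Result of an iterative Guinier fit."""

    rg: float  # Å
    i0: float
    fit_range: tuple[float, float]  # (q_min, q_max) used
    qrg_max: float
    n_points_used: int
    residual_rms: float

    def __post_init__(self) -> None:
        if self.rg <= 0:
            raise FitError("Guinier fit produced non-positive Rg")


def rebin_join(curve: ScatterCurve, block: int = 10) -> ScatterCurve:
    """Join every ``block`` consecutive points into one.

    q and I become block means; sigma propagates as sqrt(Σσ²)/n for the
    n points actually joined; a trailing partial block is averaged as-is.
    """
    if block < 1:
        raise ParameterError("block must be >= 1")
    if block == 1:
        return ScatterCurve(curve.q.copy(), curve.I.copy(),
                            None if curve.sigma is None else curve.sigma.copy(),
                            curve.i0)
    n = len(curve)
    edges = np.arange(0, n, block)
    counts = np.diff(np.append(edges, n))
    q = np.add.reduceat(curve.q, edges) / counts
    I = np.add.reduceat(curve.I, edges) / counts
    sigma = None
    if curve.sigma is not None:
        sigma = np.sqrt(np.add.reduceat(curve.sigma**2, edges)) / counts
    return ScatterCurve(q=q, I=I, sigma=sigma, i0=curve.i0)


def normalize_curve(
    curve: ScatterCurve,
    mode: str = "at_i0",
    q_ref: float | None = None,
    i0: float | None = None,
) -> ScatterCurve:
    """Normalize intensities by I(0) (``at_i0``) or by the interpolated
    intensity at ``q_ref`` (``at_q``); sigma scales identically."""
    if mode == "at_i0":
        ref = i0 if i0 is not None else curve.i0
        if ref is None:
            raise ParameterError(
                "I(0) not available; run a Guinier fit first or pass i0="
            )
    elif mode == "at_q":
        if q_ref is None:
            raise ParameterError("mode 'at_q' requires q_ref")
        if not (curve.q[0] <= q_ref <= curve.q[-1]):
            raise ParameterError(
                f"q_ref {q_ref} outside curve range [{curve.q[0]}, {curve.q[-1]}]"
            )
        ref = float(np.interp(q_ref, curve.q, curve.I))
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    if ref == 0:
        raise ParameterError("normalization reference intensity is zero")
    return ScatterCurve(
        q=curve.q.copy(),
        I=curve.I / ref,
        sigma=None if curve.sigma is None else curve.sigma / abs(ref),
        i0=None if curve.i0 is None else curve.i0 / ref,
    )


def chi_squared(experimental: ScatterCurve, simulated: ScatterCurve) -> float:
    """χ² = Σ (E_i − S_i)² / S_i over all points (no division by N).

    Both curves must have identical point counts and are expected to be
    pre-normalized by their own I(0).
    """
    if len(experimental) != len(simulated):
        raise ParameterError(
            f"point counts differ ({len(experimental)} vs {len(simulated)}); "
            "the statistic assumes identical grids — rebin/interpolate first"
        )
    S = simulated.I
    if np.any(S <= 0):
        raise ParameterError("simulated intensities must be positive")
    return float(np.sum((experimental.I - S) ** 2 / S))


def chi_squared_sigma_weighted(experimental: ScatterCurve, simulated: ScatterCurve) -> float:
    """Conventional reduced χ² = Σ((E−S)/σ)²/N. Requires experimental
    sigma. Offered for comparison only; not the default statistic."""
    if len(experimental) != len(simulated):
        raise ParameterError("point counts differ")
    if experimental.sigma is None:
        raise ParameterError("sigma-weighted χ² requires experimental uncertainties")
    r = (experimental.I - simulated.I) / experimental.sigma
    return float(np.mean(r**2))


def chi_squared_on_common_grid(
    experimental: ScatterCurve, simulated: ScatterCurve, block: int = 10
) -> float:
    """Full comparison protocol: normalize both curves by their own
    Guinier I(0), rebin the experimental curve, linearly interpolate the
    simulated curve onto the rebinned grid, then apply :func:`chi_squared`."""
    e_fit = guinier_rg(experimental)
    s_fit = guinier_rg(simulated)
    e = normalize_curve(experimental, i0=e_fit.i0)
    s = normalize_curve(simulated, i0=s_fit.i0)
    e = rebin_join(e, block)
    s_interp = ScatterCurve(q=e.q, I=np.interp(e.q, s.q, s.I))
    return chi_squared(e, s_interp)


def guinier_rg(
    curve: ScatterCurve,
    qrg_limit: float = 1.1,
    min_points: int = 5,
    max_iter: int = 20,
) -> GuinierFit:
    """Iterative Guinier fit of the low-q region.

    Linear regression of ln I on q² starts from the ``min_points``
    lowest-q points; the window is then grown/shrunk to q·Rg ≤
    ``qrg_limit`` and the fit repeated until the window stabilizes.
    Rg = sqrt(−3·slope), I(0) = exp(intercept).
    """
    if len(curve) < min_points:
        raise FitError(f"need at least {min_points} points for a Guinier fit")
    q2 = curve.q**2
    n_win = min_points
    for _ in range(max_iter):
        window = slice(0, n_win)
        I_win = curve.I[window]
        if np.any(I_win <= 0):
            raise FitError("non-positive intensity inside the Guinier window")
        slope, intercept = np.polyfit(q2[window], np.log(I_win), 1)
        if slope >= 0:
            raise FitError("positive Guinier slope: no Guinier regime at low q")
        rg = float(np.sqrt(-3.0 * slope))
        n_new = int(np.searchsorted(curve.q, qrg_limit / rg, side="right"))
        n_new = min(max(n_new, min_points), len(curve))
        if n_new == n_win:
            break
        n_win = n_new
    if n_win < min_points:
        raise FitError("Guinier window collapsed below the minimum point count")
    window = slice(0, n_win)
    if np.any(curve.I[window] <= 0):
        raise FitError("non-positive intensity inside the Guinier window")
    slope, intercept = np.polyfit(q2[window], np.log(curve.I[window]), 1)
    if slope >= 0:
        raise FitError("positive Guinier slope: no Guinier regime at low q")
    rg = float(np.sqrt(-3.0 * slope))
    resid = np.log(curve.I[window]) - (slope * q2[window] + intercept)
    return GuinierFit(
        rg=rg,
        i0=float(np.exp(intercept)),
        fit_range=(float(curve.q[0]), float(curve.q[n_win - 1])),
        qrg_max=qrg_limit,
        n_points_used=n_win,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def kratky_normalized(
    curve: ScatterCurve, rg: float, i0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless Kratky transform: y = (qRg)²·I(q)/I(0) vs x = qRg.

    For a globule y peaks near x = √3 at y = 3/e and decays; for an
    ideal chain y plateaus at 2; a continuing rise at high x is the
    disordered-chain signature.
    """
    if rg <= 0 or i0 <= 0:
        raise ParameterError("rg and i0 must be positive")
    x = curve.q * rg
    y = x**2 * curve.I / i0
    return x, y


def debye_scatter(
    coords: np.ndarray, q_grid: np.ndarray, average_frames: bool = False
) -> ScatterCurve:
    """Debye-formula scattering with unit form factors.

    I(q) = Σ_i Σ_j sinc(q·r_ij), sinc(0) = 1, so I(0⁺) → N². Accepts a
    single frame ``(n_atoms, 3)`` or, with ``average_frames``, a stack
    ``(n_frames, n_atoms, 3)`` whose per-frame intensities are averaged.
    """
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ParameterError("q grid must be strictly positive")
    if coords.ndim == 2:
        frames = coords[None]
    elif coords.ndim == 3 and average_frames:
        frames = coords
    else:
        raise ParameterError(
            "coords must be (n_atoms, 3), or (n_frames, n_atoms, 3) with average_frames=True"
        )
    n_atoms = frames.shape[1]
    if n_atoms < 1:
        raise ParameterError("need at least one atom")
    iu, ju = np.triu_indices(n_atoms, k=1)
    I = np.zeros(len(q))
    for xyz in frames:
        r = np.linalg.norm(xyz[iu] - xyz[ju], axis=1)
        # np.sinc(x) = sin(pi x)/(pi x); we need sin(qr)/(qr)
        I += n_atoms + 2.0 * np.sinc(np.outer(q, r) / np.pi).sum(axis=1)
    return ScatterCurve(q=q, I=I / len(frames))
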