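"""Conformational-ensemble decomposition.

An ensemble of frames is partitioned into groups by a per-frame scalar.
The multivariable conformation parameter combines the three descriptors
that grow together as a disordered chain extends:

    X_conf,i = α · ( Rg,i/⟨Rg⟩ + Ree,i/⟨Ree⟩ + SASA_i/⟨SASA⟩ )

where the averages are arithmetic means over all analyzed frames and α
sets the resolution: frames are grouped by the nearest integer to
X_conf, so larger α spreads the same ensemble over more integer groups.
Because each normalized ratio averages to 1, ⟨X_conf⟩ = 3α identically;
with the default α = 5 the central group sits at 15, compact frames
fall toward 10 and extended, solvent-exposed frames toward 20.

Per-group summaries (secondary-structure fractions, hydrogen-bond maps,
pair-distance tables) then characterize how structure changes from
compact to extended sub-ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .descriptors import ContactMap, ResidueProfile, hbond_contact_map, mean_min_pair_distance
from .ensemble import (
    DSSP_ALPHABET,
    Ensemble,
    ScalarSeries,
    SecondaryStructureSeries,
)
from .errors import DegenerateInputError, ParameterError

__all__ = [
    "DecompositionConfig",
    "DecompositionGroups",
    "conformation_parameter",
    "decompose",
    "decompose_single",
    "group_ss_fractions",
    "group_hbond_maps",
    "group_pair_distance_table",
    "ss_vs_ree_kde",
    "ss_residue_occurrence",
]


@dataclass
class DecompositionConfig:
    """Settings of a multivariable decomposition."""

    alpha: float = 5.0
    parameters: tuple[str, ...] = ("Rg", "Ree", "SASA")
    averages: dict = field(default_factory=dict)
    grouping_rule: str = "nearest-integer"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ParameterError("alpha must be positive")
        if not self.parameters:
            raise ParameterError("at least one decomposition parameter required")
        for name, val in self.averages.items():
            if val <= 0:
                raise ParameterError(f"average for {name} must be positive, got {val}")


@dataclass
class DecompositionGroups:
    """A disjoint partition of frame indices keyed by integer group label."""

    membership: dict[int, np.ndarray]
    xconf: ScalarSeries
    config: DecompositionConfig

    def __post_init__(self) -> None:
        n = len(self.xconf)
        seen = np.concatenate([np.asarray(v) for v in self.membership.values()])
        if len(seen) != n or len(np.unique(seen)) != n:
            raise ParameterError("groups must form a partition of all frames")

    @property
    def group_labels(self) -> list[int]:
        return sorted(self.membership)

    @property
    def n_frames(self) -> int:
        return len(self.xconf)

    def sizes(self) -> dict[int, int]:
        return {g: len(idx) for g, idx in sorted(self.membership.items())}

    def frame_labels(self) -> np.ndarray:
        """Group label per frame, in frame order."""
        out = np.empty(self.n_frames, dtype=int)
        for g, idx in self.membership.items():
            out[idx] = g
        return out


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Nearest-integer with ties at .5 rounded up (not banker's)."""
    return np.floor(np.asarray(x) + 0.5).astype(int)


def conformation_parameter(
    rg: ScalarSeries,
    ree: ScalarSeries,
    sasa: ScalarSeries,
    alpha: float = 5.0,
) -> ScalarSeries:
    """Per-frame conformation parameter X_conf (dimensionless).

    Each descriptor is normalized by its arithmetic mean over the input
    frames; the sum of the three ratios is scaled by the resolution
    multiplier α. High values indicate extended, solvent-exposed
    conformations.
    """
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    if not (len(rg) == len(ree) == len(sasa)):
        raise ParameterError("descriptor series must have equal lengths")
    total = np.zeros(len(rg))
    for series in (rg, ree, sasa):
        ave = series.values.mean()
        if ave <= 0:
            raise DegenerateInputError(
                f"ensemble mean of {series.name!r} is not positive; "
                "X_conf undefined for a degenerate ensemble"
            )
        total += series.values / ave
    return ScalarSeries("X_conf", alpha * total, "")


def decompose(
    xconf: ScalarSeries, config: DecompositionConfig | None = None
) -> DecompositionGroups:
    """Partition frames into nearest-integer X_conf groups.

    Empty integer groups are simply absent from the result; the
    remaining groups are a partition of all frames and the mapping is
    monotone (a higher X_conf never yields a lower group label).
    """
    if config is None:
        config = DecompositionConfig()
    labels = _round_half_up(xconf.values)
    membership = {
        int(g): np.flatnonzero(labels == g) for g in np.unique(labels)
    }
    return DecompositionGroups(membership=membership, xconf=xconf, config=config)


def decompose_single(series: ScalarSeries, bin_width: float) -> DecompositionGroups:
    """Decompose by a single descriptor with fixed-width bins.

    Group label = nearest integer multiple of ``bin_width`` (label k
    collects values in [(k−½)·w, (k+½)·w)); same partition contract as
    :func:`decompose`.
    """
    if bin_width <= 0:
        raise ParameterError("bin width must be positive")
    config = DecompositionConfig(
        alpha=1.0, parameters=(series.name,), grouping_rule=f"width-{bin_width}"
    )
    labels = _round_half_up(series.values / bin_width)
    membership = {int(g): np.flatnonzero(labels == g) for g in np.unique(labels)}
    return DecompositionGroups(membership=membership, xconf=series, config=config)


def group_ss_fractions(
    labels: SecondaryStructureSeries,
    groups: DecompositionGroups,
    hide_unassigned: bool = False,
) -> pd.DataFrame:
    """Secondary-structure class fractions per decomposition group.

    Rows are group labels, columns DSSP classes; each row sums to 1
    over the full alphabet. With ``hide_unassigned`` the ``~`` column
    is dropped from the output (the remaining fractions are reported
    as-is, not renormalized).
    """
    if labels.n_frames != groups.n_frames:
        raise ParameterError(
            f"label frames ({labels.n_frames}) != partition frames ({groups.n_frames})"
        )
    classes = sorted(DSSP_ALPHABET)
    rows = {}
    for g, idx in sorted(groups.membership.items()):
        block = labels.labels[idx]
        total = block.size
        rows[g] = {c: np.count_nonzero(block == c) / total for c in classes}
    df = pd.DataFrame.from_dict(rows, orient="index")[classes]
    df.index.name = "group"
    if hide_unassigned:
        df = df.drop(columns=["~"])
    return df


def group_hbond_maps(
    ensemble: Ensemble,
    groups: DecompositionGroups,
    d_cut: float = 3.5,
    angle_cut: float = 30.0,
    symmetrize: bool = False,
) -> dict[int, ContactMap]:
    """Hydrogen-bond contact map restricted to each group's frames."""
    return {
        g: hbond_contact_map(
            ensemble, frames=idx, d_cut=d_cut, angle_cut=angle_cut, symmetrize=symmetrize
        )
        for g, idx in sorted(groups.membership.items())
    }


def group_pair_distance_table(
    ensemble: Ensemble,
    groups: DecompositionGroups,
    pairs: list[tuple[int, int]],
) -> pd.DataFrame:
    """Mean minimum pair distance (Å) for each residue pair within each
    group; rows are pairs, columns group labels."""
    data = {}
    for g, idx in sorted(groups.membership.items()):
        data[g] = [mean_min_pair_distance(ensemble, pair, frames=idx) for pair in pairs]
    df = pd.DataFrame(data, index=[f"{i}-{j}" for i, j in pairs])
    df.index.name = "pair"
    return df


def ss_vs_ree_kde(
    labels: SecondaryStructureSeries,
    ree: ScalarSeries,
    ss_class: str,
    gridsize: int = 100,
    pad_bandwidths: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian KDE of (per-frame class propensity, per-frame Ree).

    Propensity is the fraction of residues carrying ``ss_class`` in a
    frame. Bandwidth follows Scott's rule; the evaluation grid extends
    ``pad_bandwidths`` bandwidths past the data range so the density
    integrates to 1 over the grid to within ~1%. Returns
    ``(x_grid, y_grid, density)`` with density shaped (gridsize, gridsize).
    """
    if ss_class not in DSSP_ALPHABET:
        raise ParameterError(f"class {ss_class!r} not in the DSSP alphabet")
    if labels.n_frames != len(ree):
        raise ParameterError("label frames and Ree length differ")
    propensity = np.mean(labels.labels == ss_class, axis=1)
    data = np.vstack([propensity, ree.values])
    if np.ptp(propensity) == 0 or np.ptp(ree.values) == 0:
        raise DegenerateInputError(
            "zero-variance axis: KDE undefined; decompose by a different "
            "class or check the input series"
        )
    kde = gaussian_kde(data)  # Scott's rule by default
    bw = np.sqrt(np.diag(kde.covariance))
    x = np.linspace(
        propensity.min() - pad_bandwidths * bw[0],
        propensity.max() + pad_bandwidths * bw[0],
        gridsize,
    )
    y = np.linspace(
        ree.values.min() - pad_bandwidths * bw[1],
        ree.values.max() + pad_bandwidths * bw[1],
        gridsize,
    )
    X, Y = np.meshgrid(x, y, indexing="ij")
    density = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(gridsize, gridsize)
    return x, y, density


def ss_residue_occurrence(
    labels: SecondaryStructureSeries, ss_class: str
) -> ResidueProfile:
    """Where along the chain a structural element occurs.

    Per-residue count of ``ss_class`` occurrences divided by the total
    count over all residues and frames; sums to 1.
    """
    if ss_class not in DSSP_ALPHABET:
        raise ParameterError(f"class {ss_class!r} not in the DSSP alphabet")
    counts = np.count_nonzero(labels.labels == ss_class, axis=0).astype(float)
    total = counts.sum()
    if total == 0:
        raise DegenerateInputError(
            f"class {ss_class!r} never occurs; occurrence profile undefined"
        )
    return ResidueProfile(f"occurrence_{ss_class}", counts / total, "")
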