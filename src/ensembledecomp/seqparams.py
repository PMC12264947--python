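"""Sequence-level parameters for disordered peptides (CIDER-style).

Computes the standard composition and charge-patterning descriptors:
fraction of charged residues (FCR), net charge per residue (NCPR), the
Das–Pappu charge-patterning parameter κ, mean rescaled Kyte–Doolittle
hydropathy (0–9), the fraction of disorder-promoting residues, and
sliding-window scale profiles (hydrophobicity, trans-membrane tendency).

κ measures charge mixing: blobs of width g = 5 and 6 slide along the
sequence; the local charge asymmetry σ = (f⁺−f⁻)²/(f⁺+f⁻) of each blob
is compared with the whole-sequence asymmetry, δ = ⟨(σ_blob − σ_seq)²⟩,
and δ is normalized by the δ_max of the maximally segregated
rearrangement of the same composition. κ = mean of the g=5 and g=6
values: ~0 for well-mixed charges, 1 for fully segregated blocks.

Histidine is treated as uncharged by default (neutral-pH convention,
matching the simulation protocol the descriptors accompany).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .errors import AlphabetError, DegenerateInputError, ParameterError

__all__ = [
    "SequenceParams",
    "WindowProfile",
    "charge_assign",
    "fcr_ncpr",
    "kappa",
    "mean_hydropathy",
    "disorder_promoting_fraction",
    "window_profile",
    "sequence_params",
    "KYTE_DOOLITTLE",
    "TM_TENDENCY",
    "HST1",
    "HST3",
    "HST5",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
POSITIVE = set("KR")
NEGATIVE = set("DE")

#: Residues statistically enriched in disordered regions.
DISORDER_PROMOTING = set("TAGRDHQKSEP")

#: Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Zhao & London (2006) trans-membrane tendency scale.
TM_TENDENCY: dict[str, float] = {
    "A": 0.38, "R": -2.57, "N": -1.62, "D": -3.27, "C": -0.30,
    "Q": -1.84, "E": -2.90, "G": -0.19, "H": -1.44, "I": 1.97,
    "L": 1.82, "K": -3.46, "M": 1.40, "F": 1.98, "P": -1.44,
    "S": -0.53, "T": -0.32, "W": 1.53, "Y": 0.49, "V": 1.46,
}

# Wild-type human histatin sequences (one-letter).
HST1 = "DSHEKRHHGYRRKFHEKHHSHREFPFYGDYGSNYLYDN"
HST3 = "DSHAKRHHGYKRKFHEKHHSHRGYRSNYLYDN"
HST5 = "DSHAKRHHGYKRKFHEKHHSHRGY"


@dataclass
class SequenceParams:
    """The one-row summary of a sequence's disorder-relevant parameters."""

    length: int
    kappa: float | None  # None when undefined (no opposing charges)
    fcr: float
    ncpr: float
    hydropathy: float
    disorder_promoting: float

    def __post_init__(self) -> None:
        if abs(self.ncpr) > self.fcr + 1e-12:
            raise ParameterError("|NCPR| cannot exceed FCR")
        for name, lo, hi in (
            ("fcr", 0, 1), ("hydropathy", 0, 9), ("disorder_promoting", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ParameterError(f"{name}={v} outside [{lo}, {hi}]")


@dataclass
class WindowProfile:
    """Sliding-window average of a per-residue scale."""

    positions: np.ndarray  # 1-based residue centers
    values: np.ndarray
    window: int
    scale_name: str


def _validate(sequence: str) -> str:
    sequence = sequence.strip().upper()
    if not sequence:
        raise ParameterError("empty sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise AlphabetError(
            f"non-standard residue letter(s): {sorted(bad)!r}"
        )
    return sequence


def charge_assign(sequence: str, histidine_charged: bool = False) -> np.ndarray:
    """Integer charge per residue: K, R → +1; D, E → −1; H → 0 unless
    ``histidine_charged``; everything else 0. Termini are not counted."""
    sequence = _validate(sequence)
    pos = POSITIVE | ({"H"} if histidine_charged else set())
    return np.array(
        [1 if c in pos else (-1 if c in NEGATIVE else 0) for c in sequence], dtype=int
    )


def fcr_ncpr(sequence: str, histidine_charged: bool = False) -> tuple[float, float]:
    """Fraction of charged residues and net charge per residue."""
    ch = charge_assign(sequence, histidine_charged)
    n_pos = int(np.sum(ch == 1))
    n_neg = int(np.sum(ch == -1))
    L = len(ch)
    return (n_pos + n_neg) / L, (n_pos - n_neg) / L


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

def _sigma(charges: np.ndarray) -> float:
    f_pos = np.mean(charges == 1)
    f_neg = np.mean(charges == -1)
    if f_pos + f_neg == 0:
        return 0.0
    return (f_pos - f_neg) ** 2 / (f_pos + f_neg)


def _delta(charges: np.ndarray, g: int) -> float:
    """Mean squared deviation of blob asymmetry from the global asymmetry."""
    sig_global = _sigma(charges)
    n_blobs = len(charges) - g + 1
    return float(
        np.mean([(_sigma(charges[i:i + g]) - sig_global) ** 2 for i in range(n_blobs)])
    )


def _segregated_templates(n_pos: int, n_neg: int, n_neu: int):
    """Candidate maximally segregated charge patterns of one composition.

    Three-block arrangements (neutrals split around a positive and a
    negative block) plus variants that split one charge type across
    both ends — the latter can carry the true permutation maximum when
    one charge type is scarce.
    """
    for a in range(n_neu + 1):
        for b in range(n_neu - a + 1):
            c = n_neu - a - b
            yield [0] * a + [1] * n_pos + [0] * b + [-1] * n_neg + [0] * c
    for maj_count, min_count, maj, mino in (
        (n_pos, n_neg, 1, -1),
        (n_neg, n_pos, -1, 1),
    ):
        for split in range(1, min_count):
            for a in range(n_neu + 1):
                b = n_neu - a
                yield (
                    [mino] * split + [0] * a + [maj] * maj_count
                    + [0] * b + [mino] * (min_count - split)
                )


def delta_max(charges: np.ndarray, g: int) -> float:
    """δ of the maximally segregated rearrangement of the composition,
    searched over the segregated-template family."""
    n_pos = int(np.sum(charges == 1))
    n_neg = int(np.sum(charges == -1))
    n_neu = len(charges) - n_pos - n_neg
    return max(
        _delta(np.asarray(t), g)
        for t in _segregated_templates(n_pos, n_neg, n_neu)
    )


def delta_max_bruteforce(charges: np.ndarray, g: int) -> float:
    """Exhaustive δ_max over all distinct permutations of the charge
    pattern. Exponential cost — only for short sequences (oracle use)."""
    vals = (
        _delta(np.asarray(p), g)
        for p in set(permutations(charges.tolist()))
    )
    return max(vals)


def kappa(
    sequence: str,
    histidine_charged: bool = False,
    blob_sizes: tuple[int, ...] = (5, 6),
) -> float:
    """Das–Pappu charge-patterning parameter κ ∈ [0, 1]."""
    ch = charge_assign(sequence, histidine_charged)
    n_pos = int(np.sum(ch == 1))
    n_neg = int(np.sum(ch == -1))
    if n_pos + n_neg == 0 or n_pos == 0 or n_neg == 0:
        raise DegenerateInputError(
            "kappa is undefined without charges of both signs; report as "
            "not-applicable rather than 0"
        )
    if len(ch) < max(blob_sizes):
        raise ParameterError("sequence shorter than the largest blob size")
    vals = []
    for g in blob_sizes:
        dmax = delta_max(ch, g)
        if dmax == 0:
            raise DegenerateInputError(f"delta_max is zero for blob size {g}")
        vals.append(_delta(ch, g) / dmax)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# hydropathy / disorder / windows
# ---------------------------------------------------------------------------

def mean_hydropathy(sequence: str) -> float:
    """Mean Kyte–Doolittle hydropathy rescaled from [−4.5, 4.5] to [0, 9]."""
    sequence = _validate(sequence)
    return float(np.mean([KYTE_DOOLITTLE[c] + 4.5 for c in sequence]))


def disorder_promoting_fraction(sequence: str) -> float:
    """Fraction of residues in the disorder-promoting set
    {T, A, G, R, D, H, Q, K, S, E, P}."""
    sequence = _validate(sequence)
    return sum(c in DISORDER_PROMOTING for c in sequence) / len(sequence)


def window_profile(
    sequence: str, scale: str | dict[str, float], window: int = 9
) -> WindowProfile:
    """Unweighted sliding-window mean of a per-residue scale.

    ``scale`` is ``"kyte_doolittle"``, ``"tm_tendency"``, or a custom
    {letter: value} table. Profile length is L − window + 1; positions
    are the 1-based window centers.
    """
    sequence = _validate(sequence)
    if isinstance(scale, str):
        try:
            table = {"kyte_doolittle": KYTE_DOOLITTLE, "tm_tendency": TM_TENDENCY}[scale]
            name = scale
        except KeyError:
            raise ParameterError(f"unknown scale {scale!r}") from None
    else:
        table, name = scale, "custom"
    if window % 2 == 0:
        raise ParameterError("window must be odd")
    if window > len(sequence):
        raise ParameterError("window exceeds sequence length")
    raw = np.array([table[c] for c in sequence])
    kernel = np.ones(window) / window
    values = np.convolve(raw, kernel, mode="valid")
    half = window // 2
    positions = np.arange(1 + half, len(sequence) - half + 1)
    return WindowProfile(positions=positions, values=values, window=window, scale_name=name)


def sequence_params(sequence: str, histidine_charged: bool = False) -> SequenceParams:
    """All Table-style parameters of one sequence in a single record.

    κ is ``None`` when the sequence lacks charges of both signs."""
    sequence = _validate(sequence)
    fcr, ncpr = fcr_ncpr(sequence, histidine_charged)
    try:
        k = kappa(sequence, histidine_charged)
    except DegenerateInputError:
        k = None
    return SequenceParams(
        length=len(sequence),
        kappa=k,
        fcr=fcr,
        ncpr=ncpr,
        hydropathy=mean_hydropathy(sequence),
        disorder_promoting=disorder_promoting_fraction(sequence),
    )


def read_sequence(source: str) -> str:
    """Accept a raw one-letter string or a FASTA file path / FASTA text;
    returns the first record's sequence."""
    from pathlib import Path

    text = source
    p = Path(source)
    try:
        if p.exists():
            text = p.read_text()
    except OSError:
        pass
    if text.lstrip().startswith(">"):
        lines = [ln.strip() for ln in text.splitlines()]
        seq_lines: list[str] = []
        in_first = False
        for ln in lines:
            if ln.startswith(">"):
                if in_first:
                    break
                in_first = True
                continue
            if in_first and ln:
                seq_lines.append(ln)
        text = "".join(seq_lines)
    return _validate(text)
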