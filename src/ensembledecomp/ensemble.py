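"""Core data model and file I/O.

The central container is :class:`Ensemble`: a stack of conformations
(frames) of one molecule, with per-atom topology annotations (names,
residue assignment, masses, van der Waals radii). All coordinates are
stored in Ångström; readers of nm-based formats must convert at the
boundary. Residues are numbered 1-based throughout; frames are indexed
0-based internally.

Multi-model PDB reading/writing is delegated to biotite; this module
adds the topology bookkeeping (contiguous residue renumbering, element
inference, mass/radius lookup) and strict validation on construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import elements
from .errors import AlphabetError, FormatError, ParameterError, TopologyError

logger = logging.getLogger(__name__)

#: DSSP secondary-structure alphabet (``P`` = polyproline-II helix,
#: ``~`` = unassigned/loop).
DSSP_ALPHABET = frozenset("HGIEBTSP~")


@dataclass
class Ensemble:
    """A frame-stacked conformational ensemble of a single molecule.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)``, Å.
    atom_names
        PDB-style atom names, shape ``(n_atoms,)``.
    residue_index
        1-based residue number per atom, non-decreasing.
    residue_names
        Three-letter residue codes, shape ``(n_residues,)``.
    masses
        Atomic masses in Da; inferred from atom names if omitted.
    radii
        van der Waals radii in Å; inferred from atom names if omitted.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    residue_index: np.ndarray
    residue_names: np.ndarray
    masses: np.ndarray | None = None
    radii: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise TopologyError("coordinates contain non-finite values")
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype="U3")
        n_atoms = self.coords.shape[1]
        if self.atom_names.shape != (n_atoms,) or self.residue_index.shape != (n_atoms,):
            raise TopologyError("atom annotation lengths do not match coords")
        if n_atoms == 0:
            raise TopologyError("ensemble must contain at least one atom")
        if self.residue_index[0] != 1 or np.any(np.diff(self.residue_index) < 0):
            raise TopologyError("residue_index must be non-decreasing and start at 1")
        if self.residue_names.shape != (self.residue_index.max(),):
            raise TopologyError(
                "residue_names length must equal the number of residues"
            )
        if self.masses is None:
            self.masses = np.array(
                [elements.mass_of(elements.element_from_atom_name(a)) for a in self.atom_names]
            )
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if self.radii is None:
            self.radii = np.array(
                [elements.vdw_radius_of(elements.element_from_atom_name(a)) for a in self.atom_names]
            )
        else:
            self.radii = np.asarray(self.radii, dtype=float)
        if self.masses.shape != (n_atoms,) or self.radii.shape != (n_atoms,):
            raise TopologyError("masses/radii lengths do not match atom count")

    # -- counts ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max())

    # -- selections -----------------------------------------------------
    def atom_mask(self, residue: int | None = None, atom_name: str | None = None) -> np.ndarray:
        """Boolean mask over atoms, optionally restricted to a 1-based
        residue number and/or an atom name."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue is not None:
            mask &= self.residue_index == residue
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        return mask

    def select_one(self, residue: int, atom_name: str) -> int:
        """Index of the unique atom matching (residue, atom_name)."""
        idx = np.flatnonzero(self.atom_mask(residue, atom_name))
        if len(idx) != 1:
            from .errors import SelectionError

            raise SelectionError(
                f"selector (residue={residue}, atom={atom_name!r}) matched "
                f"{len(idx)} atoms, expected exactly 1"
            )
        return int(idx[0])

    def has_hydrogens(self) -> bool:
        return bool(np.any(np.char.startswith(np.char.lstrip(self.atom_names, "0123456789"), "H")))

    def subset_frames(self, frames: np.ndarray) -> "Ensemble":
        frames = np.asarray(frames, dtype=int)
        if frames.size == 0:
            raise ParameterError("empty frame selection")
        if frames.min() < 0 or frames.max() >= self.n_frames:
            raise IndexError(f"frame index out of range [0, {self.n_frames})")
        return Ensemble(
            coords=self.coords[frames],
            atom_names=self.atom_names,
            residue_index=self.residue_index,
            residue_names=self.residue_names,
            masses=self.masses,
            radii=self.radii,
        )


@dataclass
class ScalarSeries:
    """One named real number per frame (Rg, Ree, SASA, P_S, X_conf, ...)."""

    name: str
    values: np.ndarray
    units: str = ""

    _NONNEGATIVE = ("Rg", "Ree", "SASA")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("ScalarSeries values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError(f"series {self.name!r} contains non-finite values")
        if self.name in self._NONNEGATIVE and np.any(self.values < 0):
            raise ParameterError(f"series {self.name!r} must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SecondaryStructureSeries:
    """Per-frame × per-residue DSSP labels."""

    labels: np.ndarray  # (n_frames, n_residues) of single characters

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.labels.ndim != 2:
            raise FormatError("labels must be a 2-D (frames × residues) array")
        bad = set(np.unique(self.labels)) - DSSP_ALPHABET
        if bad:
            raise AlphabetError(
                f"illegal secondary-structure symbol(s): {sorted(bad)!r}; "
                f"alphabet is {''.join(sorted(DSSP_ALPHABET))}"
            )

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]


@dataclass
class ScatterCurve:
    """A small-angle scattering curve: I(q) with optional uncertainties.

    ``q`` is in Å⁻¹ and must be strictly increasing and positive;
    ``i0`` optionally stores an extrapolated zero-angle intensity
    (e.g. from a Guinier fit).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    i0: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise FormatError("q and I must be 1-D arrays of equal length")
        if len(self.q) == 0:
            raise FormatError("empty scattering curve")
        if np.any(self.q <= 0):
            raise FormatError("q values must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise FormatError("q must be strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise FormatError("intensities contain non-finite values")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise FormatError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise FormatError("sigma values must be positive")

    def __len__(self) -> int:
        return len(self.q)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_multi_model_pdb(path: str | Path) -> Ensemble:
    """Read a (multi-)MODEL PDB file into an :class:`Ensemble`.

    One frame per MODEL; masses and radii are filled from an element
    lookup keyed on the atom name; residue numbers are remapped to
    contiguous 1-based indices.
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError / ValueError
        raise TopologyError(f"cannot parse {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise FormatError(f"{path} contains no ATOM records")
    coords = np.asarray(stack.coord, dtype=float)
    atom_names = np.asarray(stack.atom_name)
    res_ids = np.asarray(stack.res_id)
    chain_ids = np.asarray(stack.chain_id)
    # contiguous 1-based renumbering, in order of first appearance
    keys = list(zip(chain_ids.tolist(), res_ids.tolist()))
    mapping: dict[tuple, int] = {}
    residue_index = np.empty(len(keys), dtype=int)
    residue_names: list[str] = []
    for i, k in enumerate(keys):
        if k not in mapping:
            mapping[k] = len(mapping) + 1
            residue_names.append(str(stack.res_name[i]))
        residue_index[i] = mapping[k]
    return Ensemble(
        coords=coords,
        atom_names=atom_names,
        residue_index=residue_index,
        residue_names=np.array(residue_names),
    )


def write_multi_model_pdb(
    ensemble: Ensemble, path: str | Path, frames: np.ndarray | None = None
) -> None:
    """Write selected frames (default: all) as a multi-MODEL PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    if frames is None:
        frames = np.arange(ensemble.n_frames)
    frames = np.asarray(frames, dtype=int)
    if frames.size and (frames.min() < 0 or frames.max() >= ensemble.n_frames):
        raise IndexError(f"frame index out of range [0, {ensemble.n_frames})")
    stack = struc.AtomArrayStack(len(frames), ensemble.n_atoms)
    stack.coord = ensemble.coords[frames]
    stack.atom_name = ensemble.atom_names
    stack.res_id = ensemble.residue_index
    stack.res_name = ensemble.residue_names[ensemble.residue_index - 1]
    stack.chain_id = np.full(ensemble.n_atoms, "A")
    stack.element = np.array(
        [elements.element_from_atom_name(a) for a in ensemble.atom_names]
    )
    stack.hetero = np.zeros(ensemble.n_atoms, dtype=bool)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_scatter_curve(path: str | Path) -> ScatterCurve:
    """Read a 2- or 3-column ASCII scattering curve (q, I[, sigma]).

    Lines starting with ``#`` are comments. A non-monotone q grid is
    sorted with a logged warning.
    """
    path = Path(path)
    try:
        data = np.loadtxt(str(path), comments="#", ndmin=2)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as numeric columns: {exc}") from exc
    if data.size == 0:
        raise FormatError(f"{path} contains no data rows")
    if data.shape[1] < 2:
        raise FormatError(
            f"{path}: expected 2 or 3 columns, found {data.shape[1]}"
        )
    q, I = data[:, 0], data[:, 1]
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    if np.any(np.diff(q) <= 0):
        logger.warning("%s: q not strictly increasing; sorting", path)
        order = np.argsort(q)
        q, I = q[order], I[order]
        if sigma is not None:
            sigma = sigma[order]
    return ScatterCurve(q=q, I=I, sigma=sigma)


def write_scatter_curve(curve: ScatterCurve, path: str | Path) -> None:
    """Write a curve as 2/3-column ASCII (full double precision)."""
    cols = [curve.q, curve.I] + ([curve.sigma] if curve.sigma is not None else [])
    np.savetxt(str(path), np.column_stack(cols), header="q I" + (" sigma" if curve.sigma is not None else ""))


def read_ss_labels(path: str | Path) -> SecondaryStructureSeries:
    """Read plain-text secondary-structure labels: one line per frame,
    one DSSP character per residue."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path} is empty")
    lengths = {len(ln) for ln in lines}
    if len(lengths) != 1:
        raise FormatError(
            f"{path}: ragged line lengths {sorted(lengths)}; all frames must "
            "have the same residue count"
        )
    labels = np.array([list(ln) for ln in lines], dtype="U1")
    return SecondaryStructureSeries(labels=labels)


def write_ss_labels(series: SecondaryStructureSeries, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join("".join(row) for row in series.labels) + "\n"
    )
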