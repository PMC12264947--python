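"""Element lookup tables: atomic masses (Da) and Bondi van der Waals radii (Å)."""

from __future__ import annotations

from .errors import TopologyError

# Standard atomic weights, elements that occur in peptide topologies.
MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

# Bondi (1964) van der Waals radii.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}


def element_from_atom_name(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Tries the two-letter symbol first (for SE etc.), then the first
    alphabetic character. Leading digits (as in ``1HB``) are skipped.
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise TopologyError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in MASSES and not (two[0] in MASSES and two[0] in "HCNOP"):
        return two
    one = stripped[0].upper()
    if one in MASSES:
        return one
    if two in MASSES:
        return two
    raise TopologyError(
        f"unknown element for atom name {atom_name!r}; refusing a silent default"
    )


def mass_of(element: str) -> float:
    try:
        return MASSES[element.upper()]
    except KeyError:
        raise TopologyError(f"no mass tabulated for element {element!r}") from None


def vdw_radius_of(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise TopologyError(f"no vdW radius tabulated for element {element!r}") from None
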