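"""Exception hierarchy for ensembledecomp.

All errors raised by the library derive from :class:`EnsembleDecompError`
so callers can catch everything from one base class.
"""


class EnsembleDecompError(Exception):
    """Base class for all ensembledecomp errors."""


class FormatError(EnsembleDecompError):
    """An input file does not conform to its declared format."""


class TopologyError(EnsembleDecompError):
    """Atom/residue bookkeeping is inconsistent (e.g. atom count varies
    across models, or a required backbone atom is absent)."""


class SelectionError(EnsembleDecompError):
    """An atom/residue selector resolved to zero or more than one target."""


class ParameterError(EnsembleDecompError):
    """A numeric parameter is outside its valid range."""


class DegenerateInputError(EnsembleDecompError):
    """Input is formally valid but degenerate for the requested operation
    (all-zero weights, zero-variance axis, collinear subset, ...)."""


class MissingHydrogenError(TopologyError):
    """Operation requires explicit hydrogens but the topology has none."""


class AlphabetError(FormatError):
    """A sequence or label contains a symbol outside the declared alphabet."""


class FitError(EnsembleDecompError):
    """A model fit failed (no Guinier regime, window collapse, ...)."""
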