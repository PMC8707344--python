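"""Exception hierarchy for chiracal."""


class ChiracalError(Exception):
    """Base class for all chiracal errors."""


class InvalidInputError(ChiracalError, ValueError):
    """Input violates a precondition (too few points, bad parameters, ...)."""


class DegenerateGeometryError(ChiracalError, ValueError):
    """A zero-length difference vector: consecutive reference points coincide.

    Duplicated Calpha records are a data problem, not a value of zero
    chirality, so they raise instead of being silently skipped.
    """


class StructureParseError(ChiracalError, ValueError):
    """Input file could not be parsed in the expected format."""


class ChainNotFoundError(ChiracalError, KeyError):
    """Requested chain id does not exist in the selected model."""


class MissingResidueError(ChiracalError, ValueError):
    """A residue inside the requested range is absent from the coordinates."""


class MissingAtomError(ChiracalError, ValueError):
    """A residue in the range has no Calpha atom."""
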