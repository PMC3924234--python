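"""Exception hierarchy shared across the package."""


class OligoSuperError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(OligoSuperError):
    """The input could not be parsed as PDB."""


class EmptyStructureError(OligoSuperError):
    """A structure contained no standard protein chains (or an atom
    selection came back empty)."""


class MissingAssemblyError(OligoSuperError):
    """Biological-unit construction requested but the file carries no
    REMARK 350 information for the requested assembly."""


class ChainCountMismatchError(OligoSuperError):
    """Reference and target expose different numbers of chains, so no
    cyclic chain mapping exists."""


class NoCorrespondenceError(OligoSuperError):
    """No residue correspondence could be established between a pair of
    chains (sequence- or structure-based)."""
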