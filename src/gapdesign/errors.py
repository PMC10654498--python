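"""Exception hierarchy shared across the package."""


class GapDesignError(Exception):
    """Base class for all package-specific errors."""


class MoleculeError(GapDesignError):
    """Base class for molecule parsing/validation failures."""


class ParseError(MoleculeError):
    """SMILES string is syntactically invalid."""


class ElementError(MoleculeError):
    """Molecule contains an element outside the supported set {C,H,N,O,F,S}."""


class ValenceError(MoleculeError):
    """Molecule has a chemically impossible valence."""


class ChargeError(MoleculeError):
    """Molecule carries a nonzero net formal charge (rejected by default)."""


class FeaturizeError(GapDesignError):
    """Molecule cannot be mapped onto the fixed feature layout."""


class TokenizeError(GapDesignError):
    """SMILES string contains characters outside the tokenizer alphabet."""


class ExhaustionError(GapDesignError):
    """A sampling budget was consumed before the requested yield was reached."""


class TooFewRecords(GapDesignError):
    """Dataset too small for the requested split."""


class EmptySetError(GapDesignError):
    """An evaluation was requested on an empty record set."""


class DegenerateInput(GapDesignError):
    """Input carries no variance to project (e.g. identical fingerprints)."""


class NoCarbonError(GapDesignError):
    """H/C ratio is undefined for carbon-free molecules."""
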