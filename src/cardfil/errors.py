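"""Exception hierarchy for cardfil."""


class CardfilError(Exception):
    """Base class for all cardfil errors."""


class ParseError(CardfilError):
    """A structure file could not be parsed; names the offending line when known."""


class EmptyInputError(CardfilError):
    """An input carried no usable coordinates."""


class ConfigError(CardfilError):
    """A configuration table (helix intervals, patch plan, run config) is invalid."""


class SpecError(CardfilError):
    """A synthetic-data spec is infeasible (e.g. two patches on one residue)."""


class ChainExhaustionError(CardfilError):
    """More chains than single-character PDB chain identifiers (62)."""


class NotAFilamentError(CardfilError):
    """Subunits are not congruent copies of a common monomer."""


class NoPeakError(CardfilError):
    """No periodic signal above threshold in a profile or autocorrelation."""


class EstimationError(CardfilError):
    """A spectral estimate could not be formed (no detected peaks)."""
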