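"""Exception types raised across the package."""


class PDBParseError(ValueError):
    """A structure file could not be parsed; the message names the offending line."""


class TopologyIntegrityError(ValueError):
    """Duplicate atoms or inconsistent residue bookkeeping in a topology."""


class ShapeMismatchError(ValueError):
    """Frame/atom counts disagree between inputs that must share a topology."""


class EmptySelectionError(ValueError):
    """An atom selection resolved to no atoms."""


class DegenerateFitError(ValueError):
    """Too few or collinear atoms for a rigid-body superposition."""


class InsufficientFramesError(ValueError):
    """An operation needs more trajectory frames than were provided."""


class UndefinedScoreError(ValueError):
    """Essential-dynamics score requested from a model with no retained components."""


class DegenerateSeriesError(ValueError):
    """A descriptor series has zero variance and cannot be standardized."""


class AtomLookupError(KeyError):
    """A named atom could not be found in the topology."""


class RadiusError(KeyError):
    """No van der Waals radius available for an element."""


class CurveFitError(RuntimeError):
    """A nonlinear least-squares fit failed to converge."""
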