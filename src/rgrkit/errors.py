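"""Exception hierarchy.

Every error raised by the library derives from :class:`RgrKitError`, so
callers (and the CLI) can distinguish validation problems (exit code 2)
from design infeasibility (exit code 3).
"""


class RgrKitError(Exception):
    """Base class for all rgrkit errors."""


class AlphabetError(RgrKitError, ValueError):
    """A sequence contains a character outside its declared alphabet."""


class KindError(RgrKitError, ValueError):
    """A DNA operation received RNA, or vice versa."""


class PatternError(RgrKitError, ValueError):
    """A motif pattern contains an invalid IUPAC code."""


class RegistryError(RgrKitError, ValueError):
    """A part registry failed to load or violates an invariant."""


class PartLookupError(RgrKitError, KeyError):
    """A requested part or enzyme is missing or ambiguous."""


class DesignError(RgrKitError, ValueError):
    """A cassette/array design request is invalid."""


class CloningError(RgrKitError, ValueError):
    """Digestion or ligation cannot proceed as requested."""


class AssemblyInfeasibleError(RgrKitError):
    """No site-free closed construct exists for the given fragments."""


class ExplosionGuardError(RgrKitError):
    """The junction-graph exploration exceeded its state cap."""
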