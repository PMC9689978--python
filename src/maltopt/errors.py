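"""Exception hierarchy shared across the package."""


class MaltoptError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MaltoptError):
    """Input data violate a structural or range invariant."""


class InsufficientDataError(MaltoptError):
    """Too few complete observations for the requested fit."""


class RankDeficiencyError(MaltoptError):
    """Model matrix is rank deficient for the requested term set."""
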