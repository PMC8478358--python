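"""Exception types shared across the package."""


class WhalebrainError(Exception):
    """Base class for package-specific errors."""


class NewickParseError(WhalebrainError, ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips,
    negative or missing branch lengths)."""


class MissingTaxaError(WhalebrainError, KeyError):
    """Requested taxa absent from a tree or covariance matrix."""


class RegistryError(WhalebrainError, KeyError):
    """A named coefficient entry is missing from the registry."""


class DataError(WhalebrainError, ValueError):
    """Malformed or inconsistent tabular input."""


class FitError(WhalebrainError, ValueError):
    """A regression cannot be computed (rank deficiency, too few points,
    non-finite likelihood)."""
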