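"""Exception hierarchy shared across the package."""


class GsicrossError(Exception):
    """Base class for all package errors."""


class DomainError(GsicrossError, ValueError):
    """A numeric argument lies outside its valid domain (e.g. r not in [0, 0.5])."""


class UnsupportedPloidyError(GsicrossError, ValueError):
    """Transmission requested for a ploidy the model does not cover (triploids)."""


class MissingLocusError(GsicrossError, KeyError):
    """A trait locus was requested that is absent from the genotypes at hand."""


class MissingTissueError(GsicrossError, KeyError):
    """An expression summary for a required tissue (pistil) is absent."""


class InsufficientDataError(GsicrossError, ValueError):
    """Too few informative observations to run the estimator."""


class InsufficientAllelesError(GsicrossError, ValueError):
    """Fewer than two allele sequences: divergence is undefined."""


class EmptySelectionError(GsicrossError, ValueError):
    """A feature/record selection matched nothing."""


class ParseError(GsicrossError, ValueError):
    """A file failed validation; the message carries the offending line/row."""


class SchemaError(ParseError):
    """A table is missing columns or holds values of the wrong type."""
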