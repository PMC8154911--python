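"""Exception hierarchy used across the package."""


class GeothermFloraError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(GeothermFloraError, ValueError):
    """A configuration value violates its documented constraints."""


class NewickParseError(GeothermFloraError, ValueError):
    """Malformed newick input (syntax, duplicate labels, missing lengths)."""


class UnplaceableSpeciesError(GeothermFloraError, ValueError):
    """Species whose family and order are both absent from the tree.

    Carries the offending species names in ``species``.
    """

    def __init__(self, species):
        self.species = sorted(species)
        super().__init__(
            "cannot place species (family and order absent from tree): "
            + ", ".join(self.species)
        )


class UndefinedStatisticError(GeothermFloraError, ValueError):
    """A statistic is undefined for the given input (e.g. constant column)."""


class PipelineError(GeothermFloraError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
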