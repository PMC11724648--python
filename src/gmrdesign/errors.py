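"""Exception hierarchy shared across the package."""


class GmrDesignError(Exception):
    """Base class for all package errors."""


class FitError(GmrDesignError):
    """Raised when a mixture model cannot be fitted (e.g. fewer samples than components)."""


class StandardizationError(GmrDesignError):
    """Raised when a column cannot be standardized (zero variance); names the column."""


class DimensionError(GmrDesignError):
    """Raised on a shape/dimension mismatch between a query and a model block."""


class DegenerateQueryError(GmrDesignError):
    """Raised when a conditioning query lies in a region of vanishing density
    for every mixture component (all log-densities -inf)."""


class InvalidMoleculeError(GmrDesignError):
    """Raised when a string cannot be parsed as a molecule; carries the input."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"invalid molecule: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class UndefinedMetricError(GmrDesignError):
    """Raised when a metric is undefined for the given input
    (e.g. diversity of fewer than two hits, r2 of a constant column)."""
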