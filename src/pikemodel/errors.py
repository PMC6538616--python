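"""Exception types shared across the package."""


class SchemaError(ValueError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(ValueError):
    """Input data violate an invariant (counts, keys, coverage, ranges)."""


class ConvergenceWarning(UserWarning):
    """An MCMC fit completed but failed the convergence thresholds."""
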