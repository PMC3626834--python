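"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid user input: missing columns, bad outcome coding, bad config."""


class SingularFitError(RuntimeError):
    """The design matrix of a node model is rank deficient."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given data (e.g. constant outcome)."""
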