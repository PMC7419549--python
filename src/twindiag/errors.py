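"""Exception types shared across the package."""


class ModelSchemaError(ValueError):
    """A model or vignette file violates its JSON schema.

    Parameters
    ----------
    json_path : str
        JSONPath-style location of the offending element, e.g.
        ``$.cpts[2].leak_failure``.
    message : str
        Human-readable description of the violation.
    """

    def __init__(self, json_path: str, message: str):
        self.json_path = json_path
        super().__init__(f"{json_path}: {message}")


class IncompleteNoiseError(ValueError):
    """An exogenous state is missing noise entries required for evaluation."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(
            "incomplete exogenous state; missing entries: "
            + ", ".join(map(str, self.missing))
        )


class ZeroEvidenceError(ValueError):
    """Raised when conditioning on evidence that has probability zero."""

    def __init__(self, message: str = "conditioning on null event"):
        super().__init__(message)
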