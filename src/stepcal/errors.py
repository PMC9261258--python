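"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A constraint, parameter or plan definition is invalid."""


class SimulationError(RuntimeError):
    """The model integration failed or produced non-finite state.

    Carries the offending parameter set so that sensitivity screening can
    classify the corresponding design row as a numerical error.
    """

    def __init__(self, message: str, params: dict | None = None):
        super().__init__(message)
        self.params = dict(params) if params else {}
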