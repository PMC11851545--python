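"""Exception taxonomy shared across the package."""


class ContractError(ValueError):
    """A caller violated a documented precondition."""


class GeometryError(ContractError):
    """Geometry is degenerate or incompatible with the requested mesh mode."""


class DataError(ValueError):
    """Input data (CSV, ILT map, waveform samples) failed a sanity check."""


class ConfigError(ValueError):
    """Run configuration is schema-invalid or physically meaningless."""


class SolverError(RuntimeError):
    """A solver failed to converge or hit a stability guard."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history
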