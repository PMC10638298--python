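"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration value is missing, out of range, or inconsistent."""


class SimulationError(RuntimeError):
    """Requested simulation is infeasible (e.g. rates exceed eligible bases)."""


class IntegrityError(RuntimeError):
    """Inputs disagree with each other (e.g. truth table vs reference)."""


class VcfParseError(ValueError):
    """A VCF record could not be parsed into the data model."""
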