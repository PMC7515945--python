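"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class ContractError(RuntimeError):
    """Two inputs that must agree (settings, geometry, frame identity) do not."""


class ConfigurationError(ValueError):
    """A configuration file or registry entry is missing or malformed."""
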