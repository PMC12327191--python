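"""Exception taxonomy shared across the package.

``ParameterError`` signals invalid user input, ``CapabilityError`` signals a
request that is valid but outside what an operation supports (e.g. exact
enumeration above its hard cap, or a theorem whose hypothesis fails), and
``NumericalError`` signals a numerical procedure that failed to converge.
"""


class ParameterError(ValueError):
    """Invalid model, graph or distribution parameters."""


class CapabilityError(RuntimeError):
    """The request is outside the supported range of this operation."""


class NumericalError(RuntimeError):
    """A numerical routine failed to reach its tolerance."""


class ConfigError(ParameterError):
    """An experiment configuration could not be parsed or validated."""
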