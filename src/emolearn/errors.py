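"""Exception hierarchy shared by all emolearn modules."""


class EmolearnError(Exception):
    """Base class for all package-specific errors."""


class StabilityError(EmolearnError, ValueError):
    """The reactive gain violates the |alpha| < 1 stability condition."""


class ConfigError(EmolearnError, ValueError):
    """A configuration value is missing, malformed or inconsistent."""


class StateError(EmolearnError, ValueError):
    """A dynamical state variable left its admissible range."""


class TraceError(EmolearnError, ValueError):
    """A simulation trace is empty or lacks required fields."""


class FitError(EmolearnError, RuntimeError):
    """Parameter estimation is ill-posed for the supplied trace."""
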