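"""Exception hierarchy shared across the package."""


class VRMotorError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(VRMotorError):
    """An invalid configuration value; the message names the offending field."""


class MalformedLogError(VRMotorError):
    """A slicing-session event log violates its contract."""


class TraceError(VRMotorError):
    """A kinematic trace violates its contract (too short, non-monotone, ...)."""


class AnalysisError(VRMotorError):
    """A statistical routine was called on inputs it cannot handle."""
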