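"""Exception types shared across the pipeline."""


class InputError(ValueError):
    """Invalid or inconsistent user-supplied inputs."""


class ConfigurationError(ValueError):
    """A configuration value that cannot describe a runnable experiment."""


class ConditionAbsent(LookupError):
    """Requested event type was not estimable (no trials of that type).

    Raised instead of silently returning zeros so that an omitted cell
    (e.g. a subject with no incorrect object-relative trials) is an explicit
    outcome the caller must handle.
    """


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; the message names collinear columns."""
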