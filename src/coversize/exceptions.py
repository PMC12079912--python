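"""Exception hierarchy.

Two failure families matter to callers (and map to CLI exit codes):
malformed input files, and inputs that are well-formed but make the
estimate mathematically impossible (no regions, zero coverage).
"""


class InputError(ValueError):
    """A problem with an input file or argument (CLI exit code 2)."""


class DialectError(InputError):
    """A line of an input file violates its dialect; message names the line."""


class EstimationError(RuntimeError):
    """The estimate cannot be computed from the given inputs (CLI exit code 3)."""
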