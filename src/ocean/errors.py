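"""Exception hierarchy for the ocean package.

Every error raised on bad user input derives from :class:`OceanError`, so
callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class OceanError(Exception):
    """Base class for all ocean-specific errors."""


class FormatError(OceanError):
    """A file did not match the expected table dialect (e.g. missing column)."""


class IntegrityError(OceanError):
    """A network violated referential integrity (dangling species, duplicate id)."""


class FormulaError(OceanError):
    """A molecular formula string did not parse."""


class GPRParseError(OceanError):
    """A gene-reaction rule expression did not parse."""


class DesignError(OceanError):
    """A sample design is unusable (confounded batches, too few QC samples...)."""


class ContrastError(OceanError):
    """A requested group contrast refers to groups absent from the design."""
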