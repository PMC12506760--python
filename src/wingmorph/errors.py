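"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit statuses, so library code should
raise the most specific class that applies.
"""


class WingmorphError(Exception):
    """Base class for all package errors."""


class InputValidationError(WingmorphError):
    """Malformed or inconsistent input data (bad file, degenerate contour,
    group too small, unpaired replicates, ...)."""


class NumericalError(WingmorphError):
    """A computation could not be carried out (singular covariance,
    degenerate first-harmonic ellipse, no variance, ...)."""
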