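"""Exception hierarchy.

InputError covers malformed data (bad characters, empty files, unreadable
records); ConfigError covers out-of-range parameters. The CLI maps them to
exit codes 1 and 2 respectively.
"""


class TandemsatError(Exception):
    """Base class for all package errors."""


class InputError(TandemsatError, ValueError):
    """Malformed or insufficient input data."""


class ConfigError(TandemsatError, ValueError):
    """Parameter outside its documented range."""
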