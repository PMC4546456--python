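"""Exception hierarchy shared by all modules."""


class SimsError(Exception):
    """Base class for all errors raised by this package."""


class DataError(SimsError):
    """Malformed or inconsistent input data (exit code 1 in the CLI)."""


class RegistryError(DataError):
    """Invalid node-registry, miRNA-map or whitelist content."""
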