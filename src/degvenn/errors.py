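"""Exception hierarchy."""


class DegvennError(Exception):
    """Base class for all degvenn errors."""


class ConfigError(DegvennError, ValueError):
    """Invalid configuration values."""


class ValidationError(DegvennError, ValueError):
    """Malformed or inconsistent input data."""


class GeneSetError(DegvennError, ValueError):
    """Infeasible or inconsistent gene-set construction."""
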