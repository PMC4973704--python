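"""Exception types raised by netmoments."""


class NetworkError(ValueError):
    """Structural problem with the evidence network (e.g. disconnected)."""


class IdentifiabilityError(ValueError):
    """A variance component cannot be estimated from the data layout."""
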