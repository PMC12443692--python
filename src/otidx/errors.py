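"""Exception types shared across the package."""


class TextFormatError(ValueError):
    """Input text violates the sentinel-terminated text contract."""


class ContractViolation(ValueError):
    """An operation was called outside its documented precondition."""


class IntegrityError(RuntimeError):
    """Internal structures disagree (mismatched trees, missing links, duplicates)."""
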