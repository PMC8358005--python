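class RecipaseError(Exception):
    """Base class for all recipase errors."""


class UserInputError(RecipaseError):
    """Invalid user-supplied data or configuration (CLI exit code 1)."""
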