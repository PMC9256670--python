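"""Exception hierarchy shared across modules."""


class ConnmotifError(Exception):
    """Base class for all package errors."""


class ParseError(ConnmotifError):
    """A malformed input row or matrix; message names the offending line."""


class PaletteError(ConnmotifError):
    """A color name or code outside the configured palette."""


class CollapseError(ConnmotifError):
    """Multi-edge rows with conflicting colors and no combined color configured."""


class SizeError(ConnmotifError):
    """Motif order k exceeds the configured canonical-labeling maximum."""


class BudgetError(ConnmotifError):
    """An exhaustive generation or brute-force pass would exceed its budget."""


class MergeError(ConnmotifError):
    """Censuses with mismatched k, colored flag, palette, or graph hash."""


class PartitionBackendError(ConnmotifError):
    """Requested graph partitioner backend is unavailable."""


class ComparisonError(ConnmotifError):
    """Censuses cannot be compared (mismatched k or empty supports)."""
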