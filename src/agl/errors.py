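"""Exception hierarchy for the agl package."""


class AGLError(Exception):
    """Base class for all agl errors."""


class UnknownSyllableError(AGLError, KeyError):
    """A syllable string is not in the lexicon."""


class CategoryError(AGLError, ValueError):
    """A syllable has the wrong category (A/B) for its position."""


class DuplicatePairError(AGLError, ValueError):
    """A sequence uses the same syllable pair more than once."""


class SequenceError(AGLError, ValueError):
    """A sequence is structurally invalid (odd length, empty, misplaced dummy)."""


class ConfigError(AGLError, ValueError):
    """A design or simulant configuration is infeasible or inconsistent."""


class GenerationError(AGLError, RuntimeError):
    """Stimulus generation exhausted its search budget (uniqueness/counterbalance)."""


class AlignmentError(AGLError, ValueError):
    """A response log does not align with the design it claims to score."""


class SchemaError(AGLError, ValueError):
    """A file does not conform to the documented CSV/JSON schema."""
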