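"""Exception hierarchy."""


class LigmotifError(Exception):
    """Base class for all package errors."""


class VocabularyError(LigmotifError):
    """Unknown label, gene type or cluster request."""


class RelationAmbiguityError(LigmotifError):
    """No inter-label relation is defined for identical intervals."""


class RefDBError(LigmotifError):
    """Reference motif database build/load failure."""


class SearchError(LigmotifError):
    """Local-similarity search failure (backend or contract)."""


class AssemblyError(LigmotifError):
    """Gene delimitation / cluster assembly failure."""


class ParseError(LigmotifError):
    """Unparseable input sequence or annotation."""
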