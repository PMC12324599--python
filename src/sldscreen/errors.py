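"""Exception hierarchy for sldscreen.

Every error raised by the package derives from :class:`SldScreenError`, so
callers can catch pipeline failures without catching programming errors.
"""


class SldScreenError(Exception):
    """Base class for all sldscreen errors."""


class InvalidScoreError(SldScreenError, ValueError):
    """A4 score outside the 0-3 rubric range."""


class KnowledgeError(SldScreenError, ValueError):
    """Packaged domain knowledge is missing or inconsistent."""


class CorpusParseError(SldScreenError, ValueError):
    """Malformed transcript record; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateUtteranceError(CorpusParseError):
    """Duplicate (subject, scenario, index) triple in a transcript."""


class ConfigError(SldScreenError, ValueError):
    """Invalid generator or pipeline configuration."""


class EmptyDialogueError(SldScreenError, ValueError):
    """A prompt was requested for a dialogue with no utterances."""


class BackendError(SldScreenError, RuntimeError):
    """A live detector backend failed; carries retry metadata."""

    def __init__(self, message: str, *, retryable: bool = False, attempts: int = 1):
        self.retryable = retryable
        self.attempts = attempts
        super().__init__(message)


class AmbiguousResponseError(SldScreenError, ValueError):
    """The detector answer contains no parseable verdict (or both verdicts)."""


class UnknownFeatureError(SldScreenError, ValueError):
    """A feature identifier outside F1..F10."""


class AggregationError(SldScreenError, ValueError):
    """Scenario verdicts from different subjects were aggregated together."""


class InsufficientDataError(SldScreenError, ValueError):
    """Not enough samples for the requested statistic."""


class AlignmentError(SldScreenError, ValueError):
    """Two runs or label vectors do not cover the same samples."""


class CoverageError(SldScreenError, ValueError):
    """Pooled predictions miss or duplicate samples of the fold plan."""


class FoldError(SldScreenError, ValueError):
    """Fewer samples (or groups) than requested folds."""
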