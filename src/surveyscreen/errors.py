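"""Exception hierarchy shared across the pipeline.

Each error class maps to a documented CLI exit code (see ``surveyscreen.cli``).
"""


class SurveyScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(SurveyScreenError):
    """Input table does not match the documented column schema."""


class ConfigError(SurveyScreenError):
    """A protocol or generator configuration is invalid."""


class IntegrityError(SurveyScreenError):
    """Cross-record consistency violated (duplicate ids, unknown ids, unbalanced flow)."""


class StateError(SurveyScreenError):
    """Illegal screening-case state transition or operation on the wrong state."""
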