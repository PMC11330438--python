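"""Error hierarchy.

Every operational failure carries a stable machine-readable ``code`` so the
CLI (and any caller) can map failures to exit status and structured logs
without string matching.
"""

from __future__ import annotations


class EdcError(Exception):
    """Base class for all study-engine errors."""

    code = "EDC_ERROR"

    def __init__(self, message: str = "", **context):
        self.context = context
        super().__init__(message or self.code)


class StudyNotInEditorMode(EdcError):
    code = "STUDY_NOT_IN_EDITOR_MODE"


class UnknownVisit(EdcError):
    code = "UNKNOWN_VISIT"


class InvalidMetadata(EdcError):
    code = "INVALID_METADATA"

    def __init__(self, message: str = "", report=None, **context):
        self.report = report
        super().__init__(message, **context)


class UnsupportedFormatVersion(EdcError):
    code = "UNSUPPORTED_FORMAT_VERSION"


class MalformedBundle(EdcError):
    code = "MALFORMED_BUNDLE"


class InvalidConfig(EdcError):
    code = "INVALID_CONFIG"


class StoreReadOnly(EdcError):
    code = "STORE_READ_ONLY"


class UnknownRecord(EdcError):
    code = "UNKNOWN_RECORD"


class AlreadyDeleted(EdcError):
    code = "ALREADY_DELETED"


class AlreadyDeployed(EdcError):
    code = "ALREADY_DEPLOYED"


class NotAdmin(EdcError):
    code = "NOT_ADMIN"


class NotDeployed(EdcError):
    code = "NOT_DEPLOYED"


class VisitFrozen(EdcError):
    code = "VISIT_FROZEN"


class NarrowingChange(EdcError):
    """Post-deployment metadata edit that removes or restricts existing fields."""

    code = "NARROWING_CHANGE"


class UnknownParticipant(EdcError):
    code = "UNKNOWN_PARTICIPANT"


class UnknownPid(EdcError):
    code = "UNKNOWN_PID"


class MetadataMismatch(EdcError):
    code = "METADATA_MISMATCH"


class MergeConflict(EdcError):
    code = "MERGE_CONFLICT"

    def __init__(self, message: str = "", report=None, **context):
        self.report = report
        super().__init__(message, **context)


class NotAQuestionnaire(EdcError):
    code = "NOT_A_QUESTIONNAIRE"


class MalformedResource(EdcError):
    code = "MALFORMED_RESOURCE"


class CoercionFailure(ValueError):
    """A raw input string cannot be coerced to a widget's value type.

    Deliberately not an :class:`EdcError`: submission validation converts it
    into a COERCION_ERROR report entry rather than letting it propagate.
    """

    code = "COERCION_ERROR"

    def __init__(self, variable_id: str, expected_type: str, raw: str):
        self.variable_id = variable_id
        self.expected_type = expected_type
        self.raw = raw
        super().__init__(
            f"cannot coerce {raw!r} to {expected_type} for variable {variable_id!r}"
        )
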