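"""Exception hierarchy shared across the toolkit."""


class EcofacetError(Exception):
    """Base class for all toolkit errors."""


class VocabularyLoadError(EcofacetError):
    """A term table violates a structural invariant (duplicate id, dangling
    parent, cycle, ...).  ``term_id`` names the offending term."""

    def __init__(self, message: str, term_id: str | None = None):
        super().__init__(message)
        self.term_id = term_id


class UnknownPathError(EcofacetError):
    """A facet path is not registered.  ``valid_paths`` lists what is."""

    def __init__(self, path: str, valid_paths):
        self.path = path
        self.valid_paths = tuple(sorted(valid_paths))
        listing = ", ".join(self.valid_paths)
        super().__init__(f"unknown facet path {path!r}; valid paths: {listing}")


class UnknownTermError(EcofacetError):
    def __init__(self, term_id: str):
        super().__init__(f"unknown term id {term_id!r}")
        self.term_id = term_id


class ClosedFieldError(EcofacetError):
    """Raised when proposing a term on a content-restricted field."""


class DuplicateLabelError(EcofacetError):
    def __init__(self, label: str, facet_path: str, existing_id: str):
        super().__init__(
            f"label {label!r} already exists at {facet_path!r} as term {existing_id!r}"
        )
        self.existing_id = existing_id


class CurationError(EcofacetError):
    """Invalid curation action (curating a core term, merging into a
    non-core target, ...)."""


class ClassificationError(EcofacetError):
    """Input outside the domain of a classifier (non-positive area,
    age beyond the packaged chart span, ...)."""


class SerializationError(EcofacetError):
    """Record refused for serialization; ``issues`` carries the validation
    issues that caused the refusal."""

    def __init__(self, message: str, issues=()):
        super().__init__(message)
        self.issues = list(issues)


class DocumentError(EcofacetError):
    """Malformed or unsupported input document."""
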