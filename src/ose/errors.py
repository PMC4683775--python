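"""Exception hierarchy.

All errors raised by the library derive from :class:`OseError` so callers
(and the CLI) can distinguish library failures from programming errors.
"""


class OseError(Exception):
    """Base class for all errors raised by this package."""


class ModelError(OseError):
    """Structural problem in the ontology model (categories, slots, instances)."""


class DuplicateNameError(ModelError):
    pass


class UnknownEntityError(ModelError):
    pass


class ValueKindError(ModelError):
    """A slot value does not match the slot's declared value kind."""


class HiddenParentError(ModelError):
    """A visible study-element category was placed under a hidden parent."""


class HierarchyError(OseError):
    """Violation of the containment-forest invariants (cycle, second parent...)."""


class MappingError(OseError):
    """Bad mapping document or a document that does not fit the mapping."""


class AnnotationError(OseError):
    """Bad annotation, annotating-ontology or range literal."""


class ExpressionError(OseError):
    """Parse, type or evaluation failure in the rule-expression language."""


class ProjectIOError(OseError):
    """Project persistence failure (schema violation, version mismatch)."""


class SchemaError(ProjectIOError):
    """Project document violates the schema; ``path`` names the offending node."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class VersionError(ProjectIOError):
    pass
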