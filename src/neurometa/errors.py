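"""Exception hierarchy.

Model validation deliberately does *not* raise: :func:`neurometa.meta.validate_model`
returns findings so a front end can report every problem at once.  Exceptions are
reserved for contract violations (bad arguments, unresolvable paths, illegal
lifecycle transitions) and for parse failures.
"""


class NeurometaError(Exception):
    """Base class for all package errors."""


class UnknownTypeError(NeurometaError):
    """A type reference does not resolve to any type in the model's libraries."""


class InheritanceCycleError(NeurometaError):
    """A supertype chain revisits one of its own members."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("inheritance cycle: " + " -> ".join(self.cycle))


class ModelValidationError(NeurometaError):
    """Raised when an operation requires a clean model but validation found errors."""

    def __init__(self, report):
        self.report = report
        msgs = "; ".join(f"{f.path}: {f.message}" for f in report)
        super().__init__(f"model has {len(report)} validation error(s): {msgs}")


class PathNotFoundError(NeurometaError):
    """A path segment names a node that does not exist.

    ``valid_prefix`` is the deepest prefix of the path that did resolve.
    """

    def __init__(self, path, valid_prefix):
        self.path = path
        self.valid_prefix = valid_prefix
        super().__init__(
            f"path not found: {path!r} (deepest valid prefix: {valid_prefix!r})"
        )


class IndexOutOfRangeError(NeurometaError):
    def __init__(self, path, index, size):
        self.path = path
        self.index = index
        self.size = size
        super().__init__(f"index {index} out of range (size {size}) at {path!r}")


class QuerySchemaError(NeurometaError):
    """A query filter references a field absent from the record schema."""


class ParseError(NeurometaError):
    """Malformed document; carries line/column when known."""

    def __init__(self, message, line=None, column=None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"line {line}: {message}" if column is None else (
                f"line {line}, column {column}: {message}")
        super().__init__(message)


class UnsupportedVersionError(NeurometaError):
    def __init__(self, version, supported):
        self.version = version
        super().__init__(
            f"unsupported schema version {version!r}; supported: {sorted(supported)}"
        )


class DanglingParentError(ParseError):
    """An SWC node references a parent id that was not declared before it."""

    def __init__(self, node_id, parent_id, line=None):
        self.node_id = node_id
        self.parent_id = parent_id
        super().__init__(
            f"node {node_id} references undeclared parent {parent_id}", line=line
        )


class InvalidRadiusError(ParseError):
    def __init__(self, node_id, radius, line=None):
        self.node_id = node_id
        self.radius = radius
        super().__init__(f"node {node_id} has non-positive radius {radius}", line=line)


class EmptyGeometryError(ParseError):
    """An OBJ stream contained no vertex/face records."""


class IllegalStateError(NeurometaError):
    """An operation was attempted in a lifecycle state that does not permit it."""


class BoundsError(NeurometaError):
    def __init__(self, value, lo, hi, what="value"):
        self.value, self.lo, self.hi = value, lo, hi
        super().__init__(f"{what} {value} outside declared bounds [{lo}, {hi}]")


class CapabilityNotSupportedError(NeurometaError):
    def __init__(self, path, kind):
        super().__init__(f"instance {path!r} does not carry capability {kind!r}")


class UnknownInterpreterError(NeurometaError):
    def __init__(self, interpreter_id):
        self.interpreter_id = interpreter_id
        super().__init__(f"no interpreter registered under id {interpreter_id!r}")
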