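"""Domain-agnostic meta-model: types, variables, values and model-level operations.

The meta-model is a small object system. A :class:`Model` owns ordered
:class:`Library` collections of :class:`Type` definitions plus root
:class:`Variable` declarations; a ``Variable`` is a named slot of a given type
and a :class:`Value` is concrete data filling a slot.  Types support single
inheritance (``supertype``) and composition (:class:`CompositeType` contains
variables of other types), which together let hierarchical models and datasets
be described declaratively, independent of any domain format.

Type references are strings. A qualified reference ``"lib.TypeName"`` names a
type inside a specific library; an unqualified ``"TypeName"`` is accepted when
the name is unique across libraries.

Addressing uses dot-separated paths with zero-based bracket indices, e.g.
``"net.excitatory[2].v"``. The same grammar addresses both model structure and
runtime instance trees.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Optional, Sequence

from .errors import (
    IndexOutOfRangeError,
    InheritanceCycleError,
    PathNotFoundError,
    QuerySchemaError,
    UnknownTypeError,
)

IDENTIFIER_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

# type kinds
COMPOSITE = "composite"
ARRAY = "array"
IMPORT = "import"
STATE_VARIABLE = "state_variable"
PARAMETER = "parameter"
PRIMITIVE = "primitive"
VISUAL_GROUP = "visual_group"


# ---------------------------------------------------------------------------
# Values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scalar:
    """A real number with a unit string (empty unit = dimensionless)."""

    value: float
    unit: str = ""

    def check(self):
        return []


@dataclass(frozen=True)
class Sphere:
    """Sphere geometry; center in µm, radius in µm."""

    center: tuple
    radius: float

    def check(self):
        if not self.radius > 0:
            return [f"sphere radius must be > 0, got {self.radius}"]
        return []


@dataclass(frozen=True)
class Cylinder:
    """Tapered cylinder (frustum) between two points, radii at each end (µm)."""

    p1: tuple
    p2: tuple
    r1: float
    r2: float

    def check(self):
        problems = []
        if not (self.r1 > 0 and self.r2 > 0):
            problems.append(f"cylinder radii must be > 0, got {self.r1}, {self.r2}")
        if tuple(self.p1) == tuple(self.p2):
            problems.append("cylinder endpoints coincide")
        return problems


@dataclass(frozen=True)
class Mesh:
    """Triangle mesh: vertices as 3-tuples (µm), faces as vertex-index triples."""

    vertices: tuple
    faces: tuple

    def check(self):
        n = len(self.vertices)
        bad = [f for f in self.faces if any(i < 0 or i >= n for i in f)]
        if bad:
            return [f"{len(bad)} face(s) reference vertex indices outside 0..{n - 1}"]
        return []


@dataclass(frozen=True)
class TimeSeries:
    """Sampled trace: times in seconds, strictly increasing; one value per time."""

    times: tuple
    values: tuple
    unit: str = ""

    def check(self):
        problems = []
        if len(self.times) != len(self.values):
            problems.append(
                f"times ({len(self.times)}) and values ({len(self.values)}) differ in length"
            )
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            problems.append("times are not strictly increasing")
        return problems

    def __len__(self):
        return len(self.times)


@dataclass(frozen=True)
class Pointer:
    """A reference to another node by path."""

    path: str

    def check(self):
        return []


Value = Any  # tagged union: Scalar | Sphere | Cylinder | Mesh | TimeSeries | Pointer

VALUE_KINDS = {
    Scalar: "scalar",
    Sphere: "sphere",
    Cylinder: "cylinder",
    Mesh: "mesh",
    TimeSeries: "time_series",
    Pointer: "pointer",
}


# ---------------------------------------------------------------------------
# Types and variables
# ---------------------------------------------------------------------------

@dataclass
class Variable:
    """A named slot of a given type, optionally pre-filled with values."""

    name: str
    type: str  # type reference, preferably qualified "lib.Type"
    initial_values: list = field(default_factory=list)


@dataclass
class Type:
    """Abstract base for all type kinds; ``supertype`` is a type reference or None."""

    name: str
    supertype: Optional[str] = None
    kind: str = PRIMITIVE


@dataclass
class CompositeType(Type):
    """A type containing variables of other types (composition)."""

    variables: list = field(default_factory=list)

    def __post_init__(self):
        self.kind = COMPOSITE

    def variable(self, name: str) -> Optional[Variable]:
        for v in self.variables:
            if v.name == name:
                return v
        return None


@dataclass
class ArrayType(Type):
    """Instantiation expands to ``size`` ordered element instances."""

    element_type: str = ""
    size: int = 0

    def __post_init__(self):
        self.kind = ARRAY


@dataclass
class ImportType(Type):
    """Placeholder for data not yet loaded; resolved on demand by an interpreter.

    ``source_ref`` is a locator (typically a relative file path) handed to the
    interpreter registered under ``interpreter_id``.  Once resolved, the concrete
    type is cached in ``concrete`` and ``resolved`` flips to True.
    """

    interpreter_id: str = ""
    source_ref: str = ""
    resolved: bool = False
    concrete: Optional[Type] = None

    def __post_init__(self):
        self.kind = IMPORT


@dataclass
class StateVariableType(Type):
    """A dynamical quantity recorded over time, e.g. a membrane potential in mV."""

    unit: str = ""
    initial_value: float = 0.0

    def __post_init__(self):
        self.kind = STATE_VARIABLE


@dataclass
class ParameterType(Type):
    """A settable constant with a unit, default and optional closed bounds."""

    unit: str = ""
    default_value: float = 0.0
    bounds: Optional[tuple] = None  # (lo, hi), closed interval

    def __post_init__(self):
        self.kind = PARAMETER


@dataclass
class VisualGroupType(Type):
    """Marker type for slots holding geometric values (spheres, cylinders, meshes)."""

    def __post_init__(self):
        self.kind = VISUAL_GROUP


@dataclass
class Library:
    id: str
    types: list = field(default_factory=list)

    def type(self, name: str) -> Optional[Type]:
        for t in self.types:
            if t.name == name:
                return t
        return None


@dataclass
class QueryDecl:
    """A named conjunctive query: every (field, predicate, operand) filter must hold."""

    id: str
    filters: list = field(default_factory=list)


@dataclass
class DataSourceDecl:
    id: str
    backend_id: str = "memory"
    config: dict = field(default_factory=dict)


@dataclass
class Model:
    """Root container: libraries of types, root variables, data sources and queries."""

    id: str
    libraries: list = field(default_factory=list)
    variables: list = field(default_factory=list)
    datasources: list = field(default_factory=list)
    queries: list = field(default_factory=list)
    schema_version: str = "1"

    # -- lookups ------------------------------------------------------------
    def library(self, lib_id: str) -> Optional[Library]:
        for lib in self.libraries:
            if lib.id == lib_id:
                return lib
        return None

    def find_type(self, ref: str) -> Type:
        """Resolve a type reference (qualified or unique unqualified name)."""
        if "." in ref:
            lib_id, tname = ref.split(".", 1)
            lib = self.library(lib_id)
            if lib is not None:
                t = lib.type(tname)
                if t is not None:
                    return t
            raise UnknownTypeError(f"unknown type reference {ref!r}")
        hits = [t for lib in self.libraries for t in lib.types if t.name == ref]
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise UnknownTypeError(f"unknown type reference {ref!r}")
        raise UnknownTypeError(f"ambiguous type reference {ref!r}")

    def qualified_name(self, t: Type) -> str:
        for lib in self.libraries:
            if any(x is t for x in lib.types):
                return f"{lib.id}.{t.name}"
        raise UnknownTypeError(f"type {t.name!r} not owned by any library")


# ---------------------------------------------------------------------------
# Inheritance
# ---------------------------------------------------------------------------

def resolve_supertypes(t: Type, m: Model) -> list:
    """Return the inheritance lineage of ``t``: itself first, root ancestor last.

    Raises :class:`InheritanceCycleError` if the chain revisits a member and
    :class:`UnknownTypeError` for a dangling supertype reference.
    """
    lineage = [t]
    seen = {id(t)}
    names = [t.name]
    cur = t
    while cur.supertype is not None:
        nxt = m.find_type(cur.supertype)
        if id(nxt) in seen:
            raise InheritanceCycleError(names + [nxt.name])
        lineage.append(nxt)
        seen.add(id(nxt))
        names.append(nxt.name)
        cur = nxt
    return lineage


_FIELD_ATTRS = {
    STATE_VARIABLE: ("unit", "initial_value"),
    PARAMETER: ("unit", "default_value", "bounds"),
    ARRAY: ("element_type", "size"),
    IMPORT: ("interpreter_id", "source_ref", "resolved"),
}


def _own_fields(t: Type) -> dict:
    if isinstance(t, CompositeType):
        return {v.name: v for v in t.variables}
    attrs = _FIELD_ATTRS.get(t.kind, ())
    return {a: getattr(t, a) for a in attrs}


def effective_fields(t: Type, m: Model) -> dict:
    """Merge the field maps along the lineage of ``t``, nearest descendant winning.

    For composite types the map is variable-name → :class:`Variable`; for scalar
    kinds it is attribute-name → value.  Merging proceeds root-down so that a
    descendant's same-named entry overrides the ancestor's.
    """
    merged: dict = {}
    for ancestor in reversed(resolve_supertypes(t, m)):
        merged.update(_own_fields(ancestor))
    return merged


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    path: str
    rule: str
    message: str


def _check_values(values: Iterable, path: str, findings: list):
    for i, v in enumerate(values):
        check = getattr(v, "check", None)
        if check is None:
            findings.append(Finding("error", f"{path}[{i}]", "value-kind",
                                    f"unknown value kind {type(v).__name__}"))
            continue
        for problem in check():
            findings.append(Finding("error", f"{path}[{i}]", "value-invariant", problem))


def validate_model(m: Model) -> list:
    """Check every structural invariant; return findings (empty iff the model is valid).

    Findings are data, not exceptions, so callers can report all problems at
    once.  The report is deterministically ordered by (path, rule, message).
    """
    findings: list = []

    seen_libs: set = set()
    fq_names: set = set()
    for lib in m.libraries:
        lib_path = f"libraries.{lib.id}"
        if lib.id in seen_libs:
            findings.append(Finding("error", lib_path, "duplicate-library-id",
                                    f"duplicate library id {lib.id!r}"))
        seen_libs.add(lib.id)
        seen_types: set = set()
        for t in lib.types:
            t_path = f"{lib_path}.{t.name}"
            if t.name in seen_types:
                findings.append(Finding("error", t_path, "duplicate-type-name",
                                        f"duplicate type name {t.name!r} in library {lib.id!r}"))
            seen_types.add(t.name)
            fq = f"{lib.id}.{t.name}"
            if fq in fq_names:
                findings.append(Finding("error", t_path, "duplicate-qualified-name",
                                        f"duplicate fully-qualified type name {fq!r}"))
            fq_names.add(fq)

    def check_type_ref(ref: str, path: str, rule: str):
        try:
            return m.find_type(ref)
        except UnknownTypeError as exc:
            findings.append(Finding("error", path, rule, str(exc)))
            return None

    def check_variable(v: Variable, path: str):
        if not IDENTIFIER_RE.match(v.name):
            findings.append(Finding("error", path, "identifier-grammar",
                                    f"variable name {v.name!r} is not a valid identifier"))
        check_type_ref(v.type, path, "unknown-type")
        _check_values(v.initial_values, path, findings)
        for value in v.initial_values:
            if isinstance(value, Pointer):
                try:
                    resolve_path(m, value.path)
                except IndexOutOfRangeError as exc:
                    findings.append(Finding("error", path, "pointer-index", str(exc)))
                except PathNotFoundError as exc:
                    findings.append(Finding("error", path, "pointer-target", str(exc)))
                except (UnknownTypeError, InheritanceCycleError):
                    pass  # the underlying defect is reported by the type checks

    for lib in m.libraries:
        for t in lib.types:
            t_path = f"libraries.{lib.id}.{t.name}"
            try:
                lineage = resolve_supertypes(t, m)
            except InheritanceCycleError as exc:
                findings.append(Finding("error", t_path, "inheritance-cycle", str(exc)))
                lineage = [t]
            except UnknownTypeError as exc:
                findings.append(Finding("error", t_path, "unknown-supertype", str(exc)))
                lineage = [t]

            if isinstance(t, CompositeType):
                seen_vars: set = set()
                for v in t.variables:
                    v_path = f"{t_path}.{v.name}"
                    if v.name in seen_vars:
                        findings.append(Finding("error", v_path, "duplicate-variable-name",
                                                f"duplicate variable name {v.name!r}"))
                    seen_vars.add(v.name)
                    check_variable(v, v_path)
                # inherited variables may be overridden by value only, never by type
                for anc in lineage[1:]:
                    if not isinstance(anc, CompositeType):
                        continue
                    for v in t.variables:
                        base = anc.variable(v.name)
                        if base is not None and base.type != v.type:
                            findings.append(Finding(
                                "error", f"{t_path}.{v.name}", "type-redefinition",
                                f"variable {v.name!r} redefines inherited type "
                                f"{base.type!r} as {v.type!r}"))
            elif isinstance(t, ArrayType):
                check_type_ref(t.element_type, t_path, "unknown-element-type")
                if t.size < 0:
                    findings.append(Finding("error", t_path, "array-size",
                                            f"array size must be >= 0, got {t.size}"))
            elif isinstance(t, StateVariableType):
                if not t.unit:
                    findings.append(Finding("error", t_path, "empty-unit",
                                            "state variable unit must be non-empty"))
            elif isinstance(t, ParameterType):
                if t.bounds is not None:
                    lo, hi = t.bounds
                    if not (lo <= t.default_value <= hi):
                        findings.append(Finding(
                            "error", t_path, "default-outside-bounds",
                            f"default {t.default_value} outside bounds [{lo}, {hi}]"))

    # composition cycles (a composite containing itself, directly or via
    # arrays/other composites) would make instantiation diverge
    edges: dict = {}
    for lib in m.libraries:
        for t in lib.types:
            fq = f"{lib.id}.{t.name}"
            refs = []
            if isinstance(t, CompositeType):
                refs = [v.type for v in t.variables]
                if t.supertype is not None:
                    refs.append(t.supertype)
            elif isinstance(t, ArrayType):
                refs = [t.element_type]
            targets = []
            for ref in refs:
                try:
                    targets.append(m.qualified_name(m.find_type(ref)))
                except UnknownTypeError:
                    pass  # reported above
            edges[fq] = targets

    state: dict = {}  # 0 = visiting, 1 = done

    def visit(node: str, trail: list):
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            cycle = trail[trail.index(node):] + [node]
            findings.append(Finding("error", f"types.{node}", "composition-cycle",
                                    "composition cycle: " + " -> ".join(cycle)))
            return
        state[node] = 0
        for target in edges.get(node, ()):
            visit(target, trail + [node])
        state[node] = 1

    for fq in edges:
        visit(fq, [])

    seen_roots: set = set()
    for v in m.variables:
        v_path = v.name
        if v.name in seen_roots:
            findings.append(Finding("error", v_path, "duplicate-root-variable",
                                    f"duplicate root variable {v.name!r}"))
        seen_roots.add(v.name)
        check_variable(v, v_path)

    findings.sort(key=lambda f: (f.path, f.rule, f.message))
    return findings


def errors_in(report: Sequence[Finding]) -> list:
    return [f for f in report if f.severity == "error"]


# ---------------------------------------------------------------------------
# Path resolution
# ---------------------------------------------------------------------------

_SEGMENT_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)((?:\[\d+\])*)$")


def parse_path(path: str) -> list:
    """Split a path into (name, [indices]) segments; '' parses to no segments."""
    if path == "":
        return []
    segments = []
    for raw in path.split("."):
        match = _SEGMENT_RE.match(raw)
        if match is None:
            raise PathNotFoundError(path, "")
        name, idx_part = match.groups()
        indices = [int(s) for s in re.findall(r"\[(\d+)\]", idx_part)]
        segments.append((name, indices))
    return segments


def join_path(prefix: str, segment: str) -> str:
    return segment if prefix == "" else f"{prefix}.{segment}"


class _ModelCursor:
    """Walks model structure (variables/types) while resolving a path."""

    def __init__(self, m: Model):
        self.model = m
        self.node: Any = m

    def _children_of(self, node) -> Optional[dict]:
        m = self.model
        if isinstance(node, Model):
            return {v.name: v for v in node.variables}
        if isinstance(node, Variable):
            return self._children_of(m.find_type(node.type))
        if isinstance(node, ImportType) and node.resolved and node.concrete is not None:
            return self._children_of(node.concrete)
        if isinstance(node, CompositeType):
            return dict(effective_fields(node, m))
        return None

    def step_name(self, name: str) -> Optional[Any]:
        kids = self._children_of(self.node)
        if kids is None or name not in kids:
            return None
        self.node = kids[name]
        return self.node

    def step_index(self, index: int, at_path: str):
        node = self.node
        t = self.model.find_type(node.type) if isinstance(node, Variable) else node
        if not isinstance(t, ArrayType):
            return None
        if index >= t.size:
            raise IndexOutOfRangeError(at_path, index, t.size)
        self.node = self.model.find_type(t.element_type)
        return self.node


def resolve_path(root, path: str):
    """Address a node by path in either a :class:`Model` or an instance tree.

    Returns the addressed node; the empty path returns ``root``.  Unknown
    segments raise :class:`PathNotFoundError` carrying the deepest valid prefix;
    an index at or beyond an array's size raises :class:`IndexOutOfRangeError`.
    """
    # instance trees resolve themselves (duck-typed to avoid circular import)
    if hasattr(root, "_resolve_instance_path"):
        return root._resolve_instance_path(path)

    segments = parse_path(path)
    cursor = _ModelCursor(root)
    prefix = ""
    for name, indices in segments:
        if cursor.step_name(name) is None:
            raise PathNotFoundError(path, prefix)
        prefix = join_path(prefix, name)
        for index in indices:
            if cursor.step_index(index, prefix) is None:
                raise PathNotFoundError(path, prefix)
            prefix += f"[{index}]"
    return cursor.node


# ---------------------------------------------------------------------------
# Queries over in-memory data sources
# ---------------------------------------------------------------------------

_PREDICATES: dict = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "contains": lambda a, b: b in a,
}


@dataclass
class QueryResult:
    records: list
    count: int


class InMemoryDataSource:
    """The only data-source backend implemented: records held as dicts in memory."""

    backend_id = "memory"

    def __init__(self, records: Sequence[dict] = ()):
        self.records = list(records)


def run_query(ds: InMemoryDataSource, q: QueryDecl, records: Optional[Sequence[dict]] = None) -> QueryResult:
    """Apply a conjunctive query: keep records satisfying *all* filters, in input order.

    An empty filter list matches everything.  A filter naming a field absent
    from the record schema raises :class:`QuerySchemaError`.
    """
    data = list(records) if records is not None else list(ds.records)
    if data:
        schema = set(data[0].keys())
        for field_name, predicate, _ in q.filters:
            if field_name not in schema:
                raise QuerySchemaError(
                    f"query {q.id!r}: unknown field {field_name!r} "
                    f"(schema: {sorted(schema)})")
            if predicate not in _PREDICATES:
                raise QuerySchemaError(f"query {q.id!r}: unknown predicate {predicate!r}")
    out = []
    for rec in data:
        if all(_PREDICATES[p](rec[f], operand) for f, p, operand in q.filters):
            out.append(rec)
    return QueryResult(out, len(out))
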