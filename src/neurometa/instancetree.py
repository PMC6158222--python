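"""Runtime expansion of a model into an addressable instance tree.

Instantiation turns declarations into live objects: every root variable of a
model becomes a root :class:`Instance`, array types expand into ``size``
children named ``name[0] … name[size−1]``, and unresolved import types become
first-class *placeholder* instances that can be listed and addressed before
their data is loaded.  Each instance is augmented with capabilities according
to its type kind — a state variable gains an API for its unit, initial value
and recorded trace; a parameter gains bounds-checked set-value; visual slots
expose their geometry.

Lazy loading: :func:`resolve_import` swaps a placeholder for the interpreter's
output subtree in place, leaving every other path untouched.  Eager loading of
all imports at model-build time (:func:`resolve_imports_in_model`) yields a
structurally identical tree.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Optional

from . import interpreters
from .errors import (
    BoundsError,
    CapabilityNotSupportedError,
    IndexOutOfRangeError,
    ModelValidationError,
    PathNotFoundError,
    UnknownInterpreterError,
)
from .meta import (
    ArrayType,
    CompositeType,
    ImportType,
    Model,
    ParameterType,
    Scalar,
    StateVariableType,
    Type,
    Variable,
    effective_fields,
    errors_in,
    join_path,
    parse_path,
    validate_model,
)

# capability kinds
STATE_VARIABLE_CAPABILITY = "state_variable"
PARAMETER_CAPABILITY = "parameter"
VISUAL_CAPABILITY = "visual"


class _NoData:
    """Explicit 'no recording yet' indicator returned by time-series queries."""

    def __repr__(self):
        return "NO_DATA"

    def __bool__(self):
        return False


NO_DATA = _NoData()

#: Default interpreter registry used by import resolution.
INTERPRETERS: dict = {
    "swc": interpreters.interpret_swc,
}


@dataclass
class Instance:
    path: str
    kind: str  # type kind, or "import" for unresolved placeholders
    type: Optional[Type] = None
    children: list = field(default_factory=list)
    capabilities: set = field(default_factory=set)
    values: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.path.rsplit(".", 1)[-1]

    def child(self, segment: str) -> Optional["Instance"]:
        for c in self.children:
            if c.name == segment:
                return c
        return None

    def is_placeholder(self) -> bool:
        return self.kind == "import" and not self.values.get("resolved", False)


class InstanceTree:
    """Addressable runtime tree; ``index`` maps every reachable path to its instance."""

    def __init__(self, model: Model):
        self.model = model
        self.roots: list = []
        self.index: dict = {}

    # -- navigation ---------------------------------------------------------
    def _resolve_instance_path(self, path: str) -> "Instance | InstanceTree":
        segments = parse_path(path)
        if not segments:
            return self
        prefix = ""
        node: Optional[Instance] = None
        for name, indices in segments:
            pool = self.roots if node is None else node.children
            hit = next((c for c in pool if c.name == name), None)
            if hit is None:
                raise PathNotFoundError(path, prefix)
            node = hit
            prefix = join_path(prefix, name)
            for idx in indices:
                size = len(node.children) if node.kind == "array" else 0
                if node.kind == "array" and isinstance(node.type, ArrayType):
                    size = node.type.size
                if node.kind != "array":
                    raise PathNotFoundError(path, prefix)
                if idx >= size:
                    raise IndexOutOfRangeError(prefix, idx, size)
                node = node.children[idx]
                prefix += f"[{idx}]"
        return node

    resolve = _resolve_instance_path

    # -- traversal ----------------------------------------------------------
    def walk(self):
        stack = list(reversed(self.roots))
        while stack:
            inst = stack.pop()
            yield inst
            stack.extend(reversed(inst.children))

    def instances_with_capability(self, kind: str) -> list:
        return [i for i in self.walk() if kind in i.capabilities]

    def leaf_instances_of_kind(self, kind: str) -> list:
        return [i for i in self.walk() if i.kind == kind]

    def placeholders(self) -> list:
        return [i for i in self.walk() if i.is_placeholder()]

    def structure(self):
        """Canonical structural digest used for tree equality checks."""
        def digest(inst: Instance):
            values = {k: v for k, v in inst.values.items() if k != "time_series"}
            return (inst.path, inst.kind, tuple(sorted(inst.capabilities)),
                    tuple(sorted((k, repr(v)) for k, v in values.items())),
                    tuple(digest(c) for c in inst.children))
        return tuple(digest(r) for r in self.roots)

    def _reindex(self):
        self.index = {inst.path: inst for inst in self.walk()}


# ---------------------------------------------------------------------------
# Instantiation
# ---------------------------------------------------------------------------

def _capabilities_for(kind: str) -> set:
    return {
        "state_variable": {STATE_VARIABLE_CAPABILITY},
        "parameter": {PARAMETER_CAPABILITY},
        "visual_group": {VISUAL_CAPABILITY},
    }.get(kind, set())


def _build_instance(m: Model, var: Variable, t: Type, path: str) -> Instance:
    if isinstance(t, ImportType):
        if t.resolved and t.concrete is not None:
            return _build_instance(m, var, t.concrete, path)
        return Instance(path=path, kind="import", type=t, values={
            "resolved": False,
            "interpreter_id": t.interpreter_id,
            "source_ref": t.source_ref,
        })

    inst = Instance(path=path, kind=t.kind, type=t,
                    capabilities=_capabilities_for(t.kind))

    if isinstance(t, CompositeType):
        for fv in effective_fields(t, m).values():
            if isinstance(fv, Variable):
                child_t = m.find_type(fv.type)
                inst.children.append(
                    _build_instance(m, fv, child_t, join_path(path, fv.name)))
    elif isinstance(t, ArrayType):
        elem = m.find_type(t.element_type)
        base = path.rsplit(".", 1)[-1]
        prefix = path[: len(path) - len(base)]
        for i in range(t.size):
            elem_var = Variable(name=f"{base}[{i}]", type=t.element_type)
            inst.children.append(
                _build_instance(m, elem_var, elem, f"{prefix}{base}[{i}]"))
    elif isinstance(t, StateVariableType):
        eff = effective_fields(t, m)
        initial = eff.get("initial_value", t.initial_value)
        for v in var.initial_values:
            if isinstance(v, Scalar):
                initial = v.value  # value override declared on the variable
        inst.values = {"unit": eff.get("unit", t.unit), "initial_value": initial,
                       "time_series": None}
    elif isinstance(t, ParameterType):
        eff = effective_fields(t, m)
        default = eff.get("default_value", t.default_value)
        for v in var.initial_values:
            if isinstance(v, Scalar):
                default = v.value
        inst.values = {"unit": eff.get("unit", t.unit), "value": default,
                       "default_value": default, "bounds": eff.get("bounds", t.bounds)}
    else:
        if var.initial_values:
            inst.values = {"initial_values": list(var.initial_values)}
    return inst


def instantiate(m: Model) -> InstanceTree:
    """Expand a validated model into an instance tree.

    Refuses models whose validation report contains errors, raising
    :class:`ModelValidationError` with the full report.  Traversal order is
    declaration order, so two runs over the same model produce identical
    path sets.
    """
    report = errors_in(validate_model(m))
    if report:
        raise ModelValidationError(report)
    tree = InstanceTree(m)
    for var in m.variables:
        t = m.find_type(var.type)
        tree.roots.append(_build_instance(m, var, t, var.name))
    tree._reindex()
    return tree


# ---------------------------------------------------------------------------
# Lazy loading
# ---------------------------------------------------------------------------

def resolve_import(tree: InstanceTree, path: str,
                   registry: Optional[dict] = None,
                   base_dir: str = ".") -> InstanceTree:
    """Resolve the import placeholder at ``path`` in place; idempotent.

    The interpreter registered under the placeholder's ``interpreter_id`` is
    run on its ``source_ref`` (read relative to ``base_dir``) and the resulting
    concrete type is instantiated in the placeholder's slot.  All other paths
    are unchanged.  If ``path`` no longer addresses a placeholder the call is a
    no-op.  An unregistered interpreter id raises
    :class:`UnknownInterpreterError`; a read failure propagates as an
    ``OSError`` — in both cases the placeholder is left intact.

    Imports are resolved one level per call: if the interpreter output itself
    contains import types they stay unresolved placeholders.
    """
    registry = INTERPRETERS if registry is None else registry
    inst = tree.resolve(path)
    if not isinstance(inst, Instance) or not inst.is_placeholder():
        return tree
    imp: ImportType = inst.type  # type: ignore[assignment]

    if imp.concrete is None:
        if imp.interpreter_id not in registry:
            raise UnknownInterpreterError(imp.interpreter_id)
        interp = registry[imp.interpreter_id]
        source = os.path.join(base_dir, imp.source_ref)
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
        imp.concrete = interp(text)
        imp.resolved = True

    var = Variable(name=inst.name, type=imp.concrete.name)
    new_inst = _build_instance(tree.model, var, imp.concrete, inst.path)
    _replace(tree, inst, new_inst)
    tree._reindex()
    return tree


def resolve_all_imports(tree: InstanceTree, registry: Optional[dict] = None,
                        base_dir: str = ".") -> InstanceTree:
    """Resolve every placeholder, repeating until none remain (nested imports)."""
    while True:
        pending = tree.placeholders()
        if not pending:
            return tree
        for inst in pending:
            resolve_import(tree, inst.path, registry=registry, base_dir=base_dir)


def resolve_imports_in_model(m: Model, registry: Optional[dict] = None,
                             base_dir: str = ".") -> Model:
    """Eagerly load every import type in the model (the non-lazy route)."""
    registry = INTERPRETERS if registry is None else registry
    for lib in m.libraries:
        for t in lib.types:
            if isinstance(t, ImportType) and not t.resolved:
                if t.interpreter_id not in registry:
                    raise UnknownInterpreterError(t.interpreter_id)
                with open(os.path.join(base_dir, t.source_ref), encoding="utf-8") as fh:
                    t.concrete = registry[t.interpreter_id](fh.read())
                t.resolved = True
    return m


def _replace(tree: InstanceTree, old: Instance, new: Instance):
    pools = [tree.roots] + [i.children for i in tree.walk()]
    for pool in pools:
        for i, inst in enumerate(pool):
            if inst is old:
                pool[i] = new
                return
    raise PathNotFoundError(old.path, "")  # pragma: no cover - index out of sync


# ---------------------------------------------------------------------------
# Capabilities
# ---------------------------------------------------------------------------

class StateVariableView:
    """API of a state-variable instance: unit, initial value, recorded trace."""

    def __init__(self, instance: Instance):
        self._instance = instance

    def get_unit(self) -> str:
        return self._instance.values["unit"]

    def get_initial_value(self) -> float:
        return self._instance.values["initial_value"]

    def get_time_series(self):
        """The recorded trace, or :data:`NO_DATA` before any simulation."""
        ts = self._instance.values.get("time_series")
        return NO_DATA if ts is None else ts


class ParameterView:
    """API of a parameter instance: unit, current value, bounds-checked set."""

    def __init__(self, instance: Instance):
        self._instance = instance

    def get_unit(self) -> str:
        return self._instance.values["unit"]

    def get_value(self) -> float:
        return self._instance.values["value"]

    def get_bounds(self):
        return self._instance.values.get("bounds")

    def set_value(self, value: float):
        bounds = self.get_bounds()
        if bounds is not None:
            lo, hi = bounds
            if not (lo <= value <= hi):
                raise BoundsError(value, lo, hi,
                                  what=f"parameter {self._instance.path!r}")
        self._instance.values["value"] = float(value)


class VisualView:
    """API of a visual instance: the geometric values it holds."""

    def __init__(self, instance: Instance):
        self._instance = instance

    def get_values(self) -> list:
        vals = self._instance.values.get("initial_values")
        if vals is None and self._instance.type is not None:
            vals = []
        return list(vals or [])


_VIEWS = {
    STATE_VARIABLE_CAPABILITY: StateVariableView,
    PARAMETER_CAPABILITY: ParameterView,
    VISUAL_CAPABILITY: VisualView,
}


def get_capability_view(instance: Instance, capability_kind: str):
    """Return the capability API handle for ``instance``.

    Raises :class:`CapabilityNotSupportedError` when the instance's type kind
    did not confer the requested capability.
    """
    if capability_kind not in instance.capabilities:
        raise CapabilityNotSupportedError(instance.path, capability_kind)
    return _VIEWS[capability_kind](instance)
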