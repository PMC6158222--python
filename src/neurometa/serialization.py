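"""Bit-stable reading and writing of model and project documents.

The on-disk dialect is JSON (UTF-8) with a top-level ``"schemaVersion": "1"``.
Output is canonical — keys sorted, two-space indent, floats in Python's
shortest round-trip representation — so writing the same document twice is
byte-identical and ``read(write(m)) == m`` structurally, including unresolved
import types.  Experiment results export as RFC 4180 CSV with ``.`` as the
decimal separator.

A project holds exactly one model, given inline, by relative path reference
(``{"$ref": "model.json"}``) or implicitly through an embedded ``"network"``
document which is expanded by the network interpreter on load.  The project's
``view_state`` is opaque application state and round-trips verbatim.
"""

from __future__ import annotations

import csv
import io
import json
import os
from dataclasses import dataclass, field
from typing import Optional

from .errors import IllegalStateError, ParseError, UnsupportedVersionError
from .instancetree import InstanceTree, instantiate
from .interpreters import CellDef, Connection, NetworkDoc, Population, interpret_network
from .meta import (
    ArrayType,
    CompositeType,
    Cylinder,
    DataSourceDecl,
    ImportType,
    Library,
    Mesh,
    Model,
    ParameterType,
    Pointer,
    QueryDecl,
    Scalar,
    Sphere,
    StateVariableType,
    TimeSeries,
    Type,
    Variable,
    VisualGroupType,
)
from .simulation import COMPLETED, Experiment

SUPPORTED_VERSIONS = {"1"}


# ---------------------------------------------------------------------------
# Project container
# ---------------------------------------------------------------------------

@dataclass
class Project:
    """Application entry point: one model, its experiments, persisted view state."""

    id: str
    name: str = ""
    model: Optional[Model] = None
    experiments: list = field(default_factory=list)
    view_state: dict = field(default_factory=dict)
    network: Optional[NetworkDoc] = None
    model_ref: Optional[str] = None
    base_dir: str = field(default=".", compare=False)
    _tree: Optional[InstanceTree] = field(default=None, compare=False, repr=False)

    def tree(self) -> InstanceTree:
        """The instantiated model (cached)."""
        if self._tree is None:
            if self.model is None:
                raise IllegalStateError(f"project {self.id!r} has no model attached")
            self._tree = instantiate(self.model)
        return self._tree

    def experiment(self, experiment_id: str) -> Experiment:
        for exp in self.experiments:
            if exp.id == experiment_id:
                return exp
        raise IllegalStateError(f"no experiment with id {experiment_id!r}")


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def _value_doc(v) -> dict:
    if isinstance(v, Scalar):
        return {"kind": "scalar", "value": v.value, "unit": v.unit}
    if isinstance(v, Sphere):
        return {"kind": "sphere", "center": list(v.center), "radius": v.radius}
    if isinstance(v, Cylinder):
        return {"kind": "cylinder", "p1": list(v.p1), "p2": list(v.p2),
                "r1": v.r1, "r2": v.r2}
    if isinstance(v, Mesh):
        return {"kind": "mesh", "vertices": [list(p) for p in v.vertices],
                "faces": [list(f) for f in v.faces]}
    if isinstance(v, TimeSeries):
        return {"kind": "time_series", "times": list(v.times),
                "values": list(v.values), "unit": v.unit}
    if isinstance(v, Pointer):
        return {"kind": "pointer", "path": v.path}
    raise ParseError(f"cannot serialize value of type {type(v).__name__}")


def _variable_doc(v: Variable) -> dict:
    return {"name": v.name, "type": v.type,
            "initialValues": [_value_doc(x) for x in v.initial_values]}


def _type_doc(t: Type) -> dict:
    doc = {"name": t.name, "kind": t.kind, "supertype": t.supertype}
    if isinstance(t, CompositeType):
        doc["variables"] = [_variable_doc(v) for v in t.variables]
    elif isinstance(t, ArrayType):
        doc["elementType"] = t.element_type
        doc["size"] = t.size
    elif isinstance(t, ImportType):
        doc["interpreterId"] = t.interpreter_id
        doc["sourceRef"] = t.source_ref
        doc["resolved"] = t.resolved
        if t.resolved and t.concrete is not None:
            doc["concrete"] = _type_doc(t.concrete)
    elif isinstance(t, StateVariableType):
        doc["unit"] = t.unit
        doc["initialValue"] = t.initial_value
    elif isinstance(t, ParameterType):
        doc["unit"] = t.unit
        doc["defaultValue"] = t.default_value
        doc["bounds"] = list(t.bounds) if t.bounds is not None else None
    return doc


def _model_doc(m: Model) -> dict:
    return {
        "schemaVersion": m.schema_version,
        "kind": "model",
        "id": m.id,
        "libraries": [{"id": lib.id, "types": [_type_doc(t) for t in lib.types]}
                      for lib in m.libraries],
        "variables": [_variable_doc(v) for v in m.variables],
        "datasources": [{"id": d.id, "backendId": d.backend_id, "config": d.config}
                        for d in m.datasources],
        "queries": [{"id": q.id, "filters": [list(f) for f in q.filters]}
                    for q in m.queries],
    }


def _experiment_doc(e: Experiment) -> dict:
    return {
        "id": e.id, "name": e.name, "state": e.state,
        "parameterOverrides": dict(e.parameter_overrides),
        "watched": sorted(e.watched),
        "duration": e.duration, "dt": e.dt, "simulatorId": e.simulator_id,
        "results": {path: _value_doc(ts) for path, ts in sorted(e.results.items())},
        "errorMessage": e.error_message,
    }


def _network_doc(n: NetworkDoc) -> dict:
    return {
        "id": n.id,
        "cellDefs": {cd.name: {"morphology": cd.morphology,
                               "dynamics": dict(cd.dynamics),
                               "bounds": {k: list(v) for k, v in cd.bounds.items()}}
                     for cd in n.cell_defs.values()},
        "populations": [{"name": p.name, "cellDef": p.cell_def, "size": p.size}
                        for p in n.populations],
        "connections": [{"pre": c.pre, "post": c.post, "weight": c.weight}
                        for c in n.connections],
    }


def _dump(doc: dict) -> str:
    return json.dumps(doc, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def write_model(m: Model) -> str:
    """Serialize a model to canonical JSON text (byte-stable for equal models)."""
    return _dump(_model_doc(m))


def write_project(p: Project) -> str:
    doc = {
        "schemaVersion": "1",
        "kind": "project",
        "id": p.id,
        "name": p.name,
        "experiments": [_experiment_doc(e) for e in p.experiments],
        "viewState": p.view_state,
    }
    if p.model_ref is not None:
        doc["model"] = {"$ref": p.model_ref}
    elif p.model is not None:
        doc["model"] = _model_doc(p.model)
    else:
        doc["model"] = None
    if p.network is not None:
        doc["network"] = _network_doc(p.network)
    return _dump(doc)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _require(doc: dict, keys, where: str):
    for key in keys:
        if key not in doc:
            raise ParseError(f"{where}: missing required key {key!r}")


def _parse_value(doc: dict):
    _require(doc, ["kind"], "value")
    kind = doc["kind"]
    if kind == "scalar":
        _require(doc, ["value", "unit"], "scalar value")
        return Scalar(value=doc["value"], unit=doc["unit"])
    if kind == "sphere":
        _require(doc, ["center", "radius"], "sphere value")
        return Sphere(center=tuple(doc["center"]), radius=doc["radius"])
    if kind == "cylinder":
        _require(doc, ["p1", "p2", "r1", "r2"], "cylinder value")
        return Cylinder(p1=tuple(doc["p1"]), p2=tuple(doc["p2"]),
                        r1=doc["r1"], r2=doc["r2"])
    if kind == "mesh":
        _require(doc, ["vertices", "faces"], "mesh value")
        return Mesh(vertices=tuple(tuple(p) for p in doc["vertices"]),
                    faces=tuple(tuple(f) for f in doc["faces"]))
    if kind == "time_series":
        _require(doc, ["times", "values", "unit"], "time series value")
        return TimeSeries(times=tuple(doc["times"]), values=tuple(doc["values"]),
                          unit=doc["unit"])
    if kind == "pointer":
        _require(doc, ["path"], "pointer value")
        return Pointer(path=doc["path"])
    raise ParseError(f"unknown value kind {kind!r}")


def _parse_variable(doc: dict) -> Variable:
    _require(doc, ["name", "type", "initialValues"], "variable")
    return Variable(name=doc["name"], type=doc["type"],
                    initial_values=[_parse_value(v) for v in doc["initialValues"]])


def _parse_type(doc: dict) -> Type:
    _require(doc, ["name", "kind", "supertype"], "type")
    name, kind, sup = doc["name"], doc["kind"], doc["supertype"]
    if kind == "composite":
        _require(doc, ["variables"], f"composite type {name!r}")
        return CompositeType(name=name, supertype=sup,
                             variables=[_parse_variable(v) for v in doc["variables"]])
    if kind == "array":
        _require(doc, ["elementType", "size"], f"array type {name!r}")
        return ArrayType(name=name, supertype=sup,
                         element_type=doc["elementType"], size=doc["size"])
    if kind == "import":
        _require(doc, ["interpreterId", "sourceRef", "resolved"], f"import type {name!r}")
        concrete = _parse_type(doc["concrete"]) if doc.get("concrete") else None
        return ImportType(name=name, supertype=sup,
                          interpreter_id=doc["interpreterId"],
                          source_ref=doc["sourceRef"], resolved=doc["resolved"],
                          concrete=concrete)
    if kind == "state_variable":
        _require(doc, ["unit", "initialValue"], f"state variable type {name!r}")
        return StateVariableType(name=name, supertype=sup, unit=doc["unit"],
                                 initial_value=doc["initialValue"])
    if kind == "parameter":
        _require(doc, ["unit", "defaultValue", "bounds"], f"parameter type {name!r}")
        bounds = tuple(doc["bounds"]) if doc["bounds"] is not None else None
        return ParameterType(name=name, supertype=sup, unit=doc["unit"],
                             default_value=doc["defaultValue"], bounds=bounds)
    if kind == "visual_group":
        return VisualGroupType(name=name, supertype=sup)
    if kind == "primitive":
        return Type(name=name, supertype=sup, kind="primitive")
    raise ParseError(f"unknown type kind {kind!r}")


def _loads(text: str) -> dict:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(exc.msg, line=exc.lineno, column=exc.colno) from None
    if not isinstance(doc, dict):
        raise ParseError("top-level document must be a JSON object")
    _require(doc, ["schemaVersion"], "document")
    if str(doc["schemaVersion"]) not in SUPPORTED_VERSIONS:
        raise UnsupportedVersionError(doc["schemaVersion"], SUPPORTED_VERSIONS)
    return doc


def _model_from_doc(doc: dict) -> Model:
    _require(doc, ["id", "libraries", "variables", "datasources", "queries"], "model")
    libraries = []
    for lib_doc in doc["libraries"]:
        _require(lib_doc, ["id", "types"], "library")
        libraries.append(Library(id=lib_doc["id"],
                                 types=[_parse_type(t) for t in lib_doc["types"]]))
    return Model(
        id=doc["id"],
        libraries=libraries,
        variables=[_parse_variable(v) for v in doc["variables"]],
        datasources=[DataSourceDecl(id=d["id"], backend_id=d["backendId"],
                                    config=d.get("config", {}))
                     for d in doc["datasources"]],
        queries=[QueryDecl(id=q["id"], filters=[tuple(f) for f in q["filters"]])
                 for q in doc["queries"]],
        schema_version=str(doc["schemaVersion"]),
    )


def read_model(text: str) -> Model:
    """Parse a model document; malformed text raises :class:`ParseError` with position."""
    return _model_from_doc(_loads(text))


def _parse_experiment(doc: dict) -> Experiment:
    _require(doc, ["id", "state", "duration", "dt", "watched"], "experiment")
    return Experiment(
        id=doc["id"], name=doc.get("name", ""), state=doc["state"],
        parameter_overrides=dict(doc.get("parameterOverrides", {})),
        watched=set(doc["watched"]), duration=doc["duration"], dt=doc["dt"],
        simulator_id=doc.get("simulatorId", "lif"),
        results={path: _parse_value(v)
                 for path, v in doc.get("results", {}).items()},
        error_message=doc.get("errorMessage"),
    )


def _parse_network(doc: dict) -> NetworkDoc:
    _require(doc, ["id", "cellDefs", "populations", "connections"], "network")
    cell_defs = {}
    for name, cd in doc["cellDefs"].items():
        cell_defs[name] = CellDef(
            name=name, morphology=cd.get("morphology"),
            dynamics=dict(cd.get("dynamics", {})),
            bounds={k: tuple(v) for k, v in cd.get("bounds", {}).items()})
    return NetworkDoc(
        id=doc["id"], cell_defs=cell_defs,
        populations=[Population(name=p["name"], cell_def=p["cellDef"], size=p["size"])
                     for p in doc["populations"]],
        connections=[Connection(pre=c["pre"], post=c["post"],
                                weight=c.get("weight", 1.0))
                     for c in doc["connections"]],
    )


def read_project(text: str, base_dir: str = ".") -> Project:
    """Parse a project document; a ``{"$ref": path}`` model is loaded from disk
    relative to ``base_dir``; an embedded network document is expanded into the
    model by the network interpreter."""
    doc = _loads(text)
    _require(doc, ["id", "name", "model", "experiments", "viewState"], "project")
    model = None
    model_ref = None
    model_doc = doc["model"]
    if isinstance(model_doc, dict) and "$ref" in model_doc:
        model_ref = model_doc["$ref"]
        with open(os.path.join(base_dir, model_ref), encoding="utf-8") as fh:
            model = read_model(fh.read())
    elif isinstance(model_doc, dict):
        model = _model_from_doc(model_doc)
    network = _parse_network(doc["network"]) if doc.get("network") else None
    if model is None and network is not None:
        model = interpret_network(network)
    return Project(
        id=doc["id"], name=doc["name"], model=model,
        experiments=[_parse_experiment(e) for e in doc["experiments"]],
        view_state=doc["viewState"], network=network, model_ref=model_ref,
        base_dir=base_dir,
    )


def load_project(path: str) -> Project:
    with open(path, encoding="utf-8") as fh:
        return read_project(fh.read(), base_dir=os.path.dirname(path) or ".")


# ---------------------------------------------------------------------------
# Results export
# ---------------------------------------------------------------------------

def export_results(exp: Experiment) -> str:
    """Render a completed experiment's recordings as RFC 4180 CSV.

    One time column plus one column per watched variable (sorted by path);
    the header carries full variable paths with units.  Row count is the
    series length plus the header.
    """
    if exp.state != COMPLETED:
        raise IllegalStateError(
            f"experiment {exp.id!r} is {exp.state}, not {COMPLETED}; "
            "results can only be exported from completed experiments")
    paths = sorted(exp.results)
    n = int(exp.duration / exp.dt) + 1
    if paths:
        times = exp.results[paths[0]].times
    else:
        times = tuple(i * exp.dt for i in range(n))
    out = io.StringIO()
    writer = csv.writer(out, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
    writer.writerow(["time (ms)"] +
                    [f"{p} ({exp.results[p].unit})" for p in paths])
    for i, t in enumerate(times):
        writer.writerow([repr(float(t))] +
                        [repr(float(exp.results[p].values[i])) for p in paths])
    return out.getvalue()
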