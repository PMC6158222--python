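"""Model interpreters: build meta-model structures from domain formats.

An interpreter converts a description in a domain language into meta-model
types and values.  Three interpreters are provided:

* :func:`interpret_swc` — segmented neuronal reconstructions in the 7-column
  SWC text format, rendered as spheres (root soma nodes) and tapered cylinders
  (parent→child segments).
* :func:`interpret_obj` — Wavefront OBJ surface meshes (``v``/``f`` records
  only), with polygon faces fan-triangulated.
* :func:`interpret_network` — a small declarative network dialect (cell
  definitions with point-neuron dynamics, fixed-size populations, weighted
  connections) expanded into a full :class:`~neurometa.meta.Model`.

Interpreters are pure: the same input stream always yields a structurally
identical output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import (
    DanglingParentError,
    EmptyGeometryError,
    InvalidRadiusError,
    ParseError,
)
from .meta import (
    ArrayType,
    CompositeType,
    Cylinder,
    ImportType,
    Library,
    Mesh,
    Model,
    ParameterType,
    Pointer,
    Scalar,
    Sphere,
    StateVariableType,
    Type,
    Variable,
    VisualGroupType,
    VISUAL_GROUP,
    effective_fields,
    resolve_supertypes,
)

SOMA = 1  # SWC structure code for soma samples

# Units for the point-neuron dynamics parameters of the network dialect.
DYNAMICS_UNITS = {
    "v_rest": "mV",
    "v_thr": "mV",
    "v_reset": "mV",
    "r_m": "Mohm",
    "tau_m": "ms",
    "i_ext": "nA",
    "t_ref": "ms",
}


def _as_stream(stream: Union[str, io.TextIOBase]):
    return io.StringIO(stream) if isinstance(stream, str) else stream


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwcNode:
    """One SWC sample: id, structure code, position (µm), radius (µm), parent id.

    ``parent_id`` is −1 for a root.  Structure codes follow the common
    convention (1 soma, 2 axon, 3 basal dendrite, 4 apical dendrite); other
    codes are preserved untouched.
    """

    id: int
    structure_code: int
    position: tuple
    radius: float
    parent_id: int


def parse_swc(stream: Union[str, io.TextIOBase]) -> list:
    """Parse SWC text into nodes, enforcing declaration order.

    ``#`` comment lines and blank lines are skipped.  A child must appear
    after its parent; forward references are rejected with a
    :class:`DanglingParentError` rather than buffered.
    """
    nodes: list = []
    seen: set = set()
    for lineno, raw in enumerate(_as_stream(stream), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise ParseError(
                f"expected 7 whitespace-separated fields, got {len(fields)}",
                line=lineno)
        try:
            nid = int(fields[0])
            code = int(fields[1])
            x, y, z, radius = (float(f) for f in fields[2:6])
            parent = int(fields[6])
        except ValueError as exc:
            raise ParseError(f"malformed field: {exc}", line=lineno) from None
        if radius <= 0:
            raise InvalidRadiusError(nid, radius, line=lineno)
        if nid in seen:
            raise ParseError(f"duplicate node id {nid}", line=lineno)
        if parent != -1 and parent not in seen:
            raise DanglingParentError(nid, parent, line=lineno)
        seen.add(nid)
        nodes.append(SwcNode(nid, code, (x, y, z), radius, parent))
    return nodes


def interpret_swc(stream: Union[str, io.TextIOBase], name: str = "morphology") -> CompositeType:
    """Build a composite type of visual values from an SWC reconstruction.

    Root soma nodes become :class:`~neurometa.meta.Sphere` values (radius =
    node radius); every non-root node becomes a tapered
    :class:`~neurometa.meta.Cylinder` spanning parent→node with r1 = parent
    radius and r2 = node radius — except that no cylinder is emitted between
    two soma samples, which are instead each rendered as a sphere (multi-node
    soma convention).  Hence #cylinders = #nodes − #root-spheres − extra soma
    spheres, and for single-sphere-per-root files cylinders = nodes − roots.
    """
    nodes = parse_swc(stream)
    by_id = {n.id: n for n in nodes}
    composite = CompositeType(name=name)
    for node in nodes:
        if node.parent_id == -1:
            value: object = Sphere(center=node.position, radius=node.radius)
        else:
            parent = by_id[node.parent_id]
            if node.structure_code == SOMA and parent.structure_code == SOMA:
                # consecutive soma samples: sphere per sample, no connecting frustum
                value = Sphere(center=node.position, radius=node.radius)
            else:
                value = Cylinder(p1=parent.position, p2=node.position,
                                 r1=parent.radius, r2=node.radius)
        composite.variables.append(
            Variable(name=f"seg{node.id}", type="common.Visual",
                     initial_values=[value]))
    return composite


def visual_values(composite: CompositeType, model: Optional[Model] = None) -> list:
    """Collect the geometric values held by a composite's visual variables."""
    variables = composite.variables
    if model is not None:
        variables = [v for v in effective_fields(composite, model).values()
                     if isinstance(v, Variable)]
    out = []
    for v in variables:
        if v.type.endswith("Visual") or v.type.endswith("visual"):
            out.extend(v.initial_values)
    return out


# ---------------------------------------------------------------------------
# OBJ
# ---------------------------------------------------------------------------

def interpret_obj(stream: Union[str, io.TextIOBase]) -> Mesh:
    """Read a Wavefront OBJ stream into a triangle :class:`~neurometa.meta.Mesh`.

    Only ``v`` and ``f`` records are honored; normals, texture coordinates,
    materials and groups are ignored.  Face indices are 1-based in the format
    and converted to 0-based; ``v/vt/vn`` compounds keep the vertex index.
    Polygon faces with more than three vertices are fan-triangulated around
    their first vertex (n − 2 triangles).
    """
    vertices: list = []
    faces: list = []
    for lineno, raw in enumerate(_as_stream(stream), start=1):
        fields = raw.split()
        if not fields:
            continue
        tag = fields[0]
        if tag == "v":
            if len(fields) < 4:
                raise ParseError("vertex record needs 3 coordinates", line=lineno)
            vertices.append(tuple(float(f) for f in fields[1:4]))
        elif tag == "f":
            idx = []
            for token in fields[1:]:
                try:
                    i = int(token.split("/")[0])
                except ValueError:
                    raise ParseError(f"bad face index {token!r}", line=lineno) from None
                idx.append(i - 1 if i > 0 else len(vertices) + i)
            if len(idx) < 3:
                raise ParseError("face needs at least 3 vertices", line=lineno)
            for k in range(1, len(idx) - 1):  # fan around the first vertex
                faces.append((idx[0], idx[k], idx[k + 1]))
    if not vertices and not faces:
        raise EmptyGeometryError("no geometry records (v/f) found")
    mesh = Mesh(vertices=tuple(vertices), faces=tuple(faces))
    problems = mesh.check()
    if problems:
        raise ParseError("; ".join(problems))
    return mesh


# ---------------------------------------------------------------------------
# Network dialect
# ---------------------------------------------------------------------------

@dataclass
class CellDef:
    """A cell archetype: optional morphology source plus point-neuron dynamics."""

    name: str
    morphology: Optional[str] = None  # SWC path, loaded lazily as an import
    dynamics: dict = field(default_factory=dict)  # parameter name -> value
    bounds: dict = field(default_factory=dict)    # parameter name -> (lo, hi)


@dataclass
class Population:
    name: str
    cell_def: str
    size: int


@dataclass
class Connection:
    pre: str   # instance path, e.g. "net.excitatory[0]"
    post: str
    weight: float = 1.0


@dataclass
class NetworkDoc:
    """Declarative network description: cell archetypes, populations, connections."""

    id: str = "net"
    cell_defs: dict = field(default_factory=dict)  # name -> CellDef
    populations: list = field(default_factory=list)
    connections: list = field(default_factory=list)


def interpret_network(doc: NetworkDoc) -> Model:
    """Expand a network document into a model.

    The model gets a single root variable named after the document, typed by a
    composite holding one array variable per population (array size as
    declared) plus a ``connections`` composite.  Each cell composite contains
    a membrane-potential state variable ``v`` (mV), one parameter variable per
    dynamics entry, and — when the cell definition names a morphology file —
    an unresolved import placeholder to be loaded on demand.

    Structural problems (e.g. a population referencing an undeclared cell
    definition, or a connection pointing past a population's size) surface as
    validation findings on the returned model, not exceptions.
    """
    lib = Library(id="net")
    model = Model(id=doc.id, libraries=[common_library(), lib])

    for cd in doc.cell_defs.values():
        cell = CompositeType(name=f"{cd.name}_cell")
        vtype = StateVariableType(name=f"{cd.name}_v", unit="mV",
                                  initial_value=float(cd.dynamics.get("v_rest", -65.0)))
        lib.types.append(vtype)
        cell.variables.append(Variable(name="v", type=f"net.{vtype.name}"))
        for pname in sorted(cd.dynamics):
            ptype = ParameterType(
                name=f"{cd.name}_{pname}",
                unit=DYNAMICS_UNITS.get(pname, ""),
                default_value=float(cd.dynamics[pname]),
                bounds=tuple(cd.bounds[pname]) if pname in cd.bounds else None)
            lib.types.append(ptype)
            cell.variables.append(Variable(name=pname, type=f"net.{ptype.name}"))
        if cd.morphology is not None:
            imp = ImportType(name=f"{cd.name}_morphology", interpreter_id="swc",
                             source_ref=cd.morphology)
            lib.types.append(imp)
            cell.variables.append(Variable(name="morphology", type=f"net.{imp.name}"))
        lib.types.append(cell)

    root = CompositeType(name=f"{doc.id}_root")
    for pop in doc.populations:
        arr = ArrayType(name=f"{pop.name}_array",
                        element_type=f"net.{pop.cell_def}_cell", size=pop.size)
        lib.types.append(arr)
        root.variables.append(Variable(name=pop.name, type=f"net.{arr.name}"))

    conns = CompositeType(name="connections_group")
    lib.types.append(Type(name="connection", kind="primitive"))
    for i, conn in enumerate(doc.connections):
        conns.variables.append(Variable(
            name=f"c{i}", type="net.connection",
            initial_values=[Pointer(conn.pre), Pointer(conn.post),
                            Scalar(float(conn.weight))]))
    lib.types.append(conns)
    root.variables.append(Variable(name="connections", type="net.connections_group"))
    lib.types.append(root)

    model.variables.append(Variable(name=doc.id, type=f"net.{root.name}"))
    return model


def common_library() -> Library:
    """The shared library of primitive building-block types."""
    return Library(id="common", types=[
        VisualGroupType(name="Visual"),
        Type(name="Text", kind="primitive"),
    ])


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def _population_of(path: str, populations: list) -> Optional[int]:
    # connection endpoints look like "<root>.<population>[i]" or "<population>[i]..."
    for segment in path.split("."):
        name = segment.split("[", 1)[0]
        for i, pop in enumerate(populations):
            if pop == name:
                return i
    return None


def connectivity_matrix(model: Model, weights: bool = False):
    """Population-level connection counts (or summed weights) as a square matrix.

    Rows index presynaptic populations, columns postsynaptic, both in
    declaration order.  Returns ``(matrix, population_names)``.
    """
    root_var = model.variables[0]
    root_type = model.find_type(root_var.type)
    pops = [v.name for v in root_type.variables
            if isinstance(model.find_type(v.type), ArrayType)]
    matrix = np.zeros((len(pops), len(pops)))
    conn_var = root_type.variable("connections")
    if conn_var is None:
        return matrix, pops
    group = model.find_type(conn_var.type)
    for cv in group.variables:
        pointers = [v for v in cv.initial_values if isinstance(v, Pointer)]
        scalars = [v for v in cv.initial_values if isinstance(v, Scalar)]
        if len(pointers) != 2:
            continue
        i = _population_of(pointers[0].path, pops)
        j = _population_of(pointers[1].path, pops)
        if i is None or j is None:
            continue
        matrix[i, j] += scalars[0].value if (weights and scalars) else 1.0
    return matrix, pops
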