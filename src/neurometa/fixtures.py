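"""Deterministic synthetic fixtures: SWC morphologies, networks, projects.

Everything is driven by a single seed through one ``numpy`` generator per
call — no hidden entropy sources — so the same spec always produces
byte-identical files.  The generated study conditions are desk-scale but
structurally faithful: random binary-tree morphologies with tapering radii,
a few fixed-size LIF populations with random connectivity, and one
ready-to-run experiment watching every membrane potential.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .interpreters import CellDef, Connection, NetworkDoc, Population, interpret_network
from .serialization import Project, write_project
from .simulation import Experiment


@dataclass
class FixtureSpec:
    """Knobs of the synthetic generator.

    ``population_sizes`` gives one LIF population per entry; each population
    gets its own cell archetype and (optionally) its own random morphology of
    ``n_nodes`` SWC samples.  ``branching_prob`` is the per-node probability of
    attaching to a random earlier node instead of extending the current chain.
    """

    seed: int = 0
    n_nodes: int = 20
    branching_prob: float = 0.3
    population_sizes: tuple = (2, 3)
    n_connections: int = 4
    with_morphology: bool = True
    duration: float = 50.0  # ms
    dt: float = 0.1         # ms

    def check(self):
        if self.n_nodes < 1:
            raise ValueError(f"n_nodes must be >= 1, got {self.n_nodes}")
        if not 0.0 <= self.branching_prob <= 1.0:
            raise ValueError(f"branching_prob must be in [0, 1], got {self.branching_prob}")
        if any(s < 0 for s in self.population_sizes):
            raise ValueError(f"population sizes must be >= 0, got {self.population_sizes}")
        if self.n_connections < 0:
            raise ValueError(f"n_connections must be >= 0, got {self.n_connections}")


def _radius(rng) -> float:
    # uniform over (0.1, 5] µm
    return 5.0 - rng.uniform(0.0, 4.9)


def generate_swc(n_nodes: int, branching_prob: float = 0.3, seed: int = 0) -> str:
    """Generate a random rooted morphology as SWC text.

    Node 1 is a root soma at the origin; each subsequent node is a dendrite
    sample attached either to the previous node (chain extension) or, with
    probability ``branching_prob``, to a uniformly chosen earlier node.  Radii
    fall in (0.1, 5] µm.  Identical arguments yield byte-identical text.
    """
    if n_nodes < 1:
        raise ValueError(f"n_nodes must be >= 1, got {n_nodes}")
    if not 0.0 <= branching_prob <= 1.0:
        raise ValueError(f"branching_prob must be in [0, 1], got {branching_prob}")
    rng = np.random.default_rng(seed)
    positions = {1: np.zeros(3)}
    lines = ["# synthetic morphology fixture",
             f"# n_nodes={n_nodes} branching_prob={branching_prob} seed={seed}"]
    r = _radius(rng)
    lines.append(f"1 1 0.0 0.0 0.0 {r!r} -1")
    for nid in range(2, n_nodes + 1):
        if branching_prob > 0 and rng.random() < branching_prob:
            parent = int(rng.integers(1, nid))  # uniform over declared nodes
        else:
            parent = nid - 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = positions[parent] + direction * rng.uniform(1.0, 5.0)
        positions[nid] = pos
        r = _radius(rng)
        x, y, z = (float(c) for c in pos)
        lines.append(f"{nid} 3 {x!r} {y!r} {z!r} {r!r} {parent}")
    return "\n".join(lines) + "\n"


#: Default LIF dynamics given to every generated cell archetype: a neuron at
#: rest −65 mV with a 15 mV gap to threshold, τ = 10 ms, R = 10 MΩ, driven by
#: a suprathreshold 2 nA current so generated experiments actually spike.
DEFAULT_DYNAMICS = {
    "v_rest": -65.0,
    "v_thr": -50.0,
    "v_reset": -65.0,
    "r_m": 10.0,
    "tau_m": 10.0,
    "i_ext": 2.0,
    "t_ref": 0.0,
}

DEFAULT_BOUNDS = {"i_ext": (0.0, 10.0)}


def generate_network(spec: FixtureSpec) -> NetworkDoc:
    """Build a random network document: one archetype + population per size entry."""
    spec.check()
    rng = np.random.default_rng(spec.seed)
    doc = NetworkDoc(id="net")
    for p, size in enumerate(spec.population_sizes):
        name = f"cell{p}"
        morphology = f"morph{p}.swc" if spec.with_morphology else None
        doc.cell_defs[name] = CellDef(name=name, morphology=morphology,
                                      dynamics=dict(DEFAULT_DYNAMICS),
                                      bounds=dict(DEFAULT_BOUNDS))
        doc.populations.append(Population(name=f"pop{p}", cell_def=name, size=size))

    cells = [(f"pop{p}", i)
             for p, size in enumerate(spec.population_sizes) for i in range(size)]
    if cells:
        for _ in range(spec.n_connections):
            pre = cells[int(rng.integers(len(cells)))]
            post = cells[int(rng.integers(len(cells)))]
            weight = float(rng.uniform(0.0, 1.0))
            doc.connections.append(Connection(
                pre=f"net.{pre[0]}[{pre[1]}]", post=f"net.{post[0]}[{post[1]}]",
                weight=weight))
    return doc


def generate_model(seed: int = 0):
    """Generate a random valid model exercising every serializable construct.

    Beyond the network expansion this adds an inheritance chain, a query, a
    data source, an unresolved import type and root variables carrying scalar,
    pointer and time-series values, so serialization round-trip sweeps cover
    the whole dialect.
    """
    from .meta import (DataSourceDecl, ImportType, Library, ParameterType,
                       Pointer, QueryDecl, Scalar, StateVariableType,
                       TimeSeries, Variable)

    rng = np.random.default_rng(seed)
    sizes = tuple(int(s) for s in rng.integers(0, 5, size=int(rng.integers(1, 4))))
    spec = FixtureSpec(seed=seed, population_sizes=sizes,
                       n_connections=int(rng.integers(0, 6)),
                       with_morphology=False)
    model = interpret_network(generate_network(spec))

    extra = Library(id="extra", types=[
        StateVariableType(name="base_v", unit="mV",
                          initial_value=float(rng.normal(-65.0, 5.0))),
        StateVariableType(name="derived_v", supertype="extra.base_v", unit="mV",
                          initial_value=float(rng.normal(-60.0, 5.0))),
        ParameterType(name="gain", unit="", default_value=float(rng.uniform(0, 1)),
                      bounds=(0.0, 1.0)),
        ImportType(name="deferred", interpreter_id="swc",
                   source_ref=f"pending_{seed}.swc"),
    ])
    model.libraries.append(extra)
    n = int(rng.integers(2, 8))
    times = tuple(float(t) for t in np.arange(n) * 0.001)
    series = TimeSeries(times=times,
                        values=tuple(float(v) for v in rng.normal(size=n)),
                        unit="mV")
    model.variables.append(Variable(
        name="probe", type="extra.derived_v",
        initial_values=[Scalar(float(rng.normal()), "mV"), series]))
    model.variables.append(Variable(name="note", type="common.Text",
                                    initial_values=[Pointer("probe")]))
    model.datasources.append(DataSourceDecl(id="records", backend_id="memory",
                                            config={"n": int(rng.integers(1, 99))}))
    model.queries.append(QueryDecl(id="by_label",
                                   filters=[("label", "contains", "RME")]))
    return model


def generate_project(spec: FixtureSpec, out_dir: str) -> Project:
    """Write a loadable project fixture (project.json + SWC files) to ``out_dir``.

    The project embeds the network document and its expanded model, and one
    ready-to-run experiment ``exp0`` watching every membrane potential.
    Returns the in-memory project (``base_dir`` set to ``out_dir``).
    """
    spec.check()
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    morph_seeds = [int(rng.integers(2 ** 31)) for _ in spec.population_sizes]

    doc = generate_network(spec)
    if spec.with_morphology:
        for p, _ in enumerate(spec.population_sizes):
            text = generate_swc(spec.n_nodes, spec.branching_prob, seed=morph_seeds[p])
            with open(os.path.join(out_dir, f"morph{p}.swc"), "w",
                      encoding="utf-8", newline="\n") as fh:
                fh.write(text)

    watched = {f"net.pop{p}[{i}].v"
               for p, size in enumerate(spec.population_sizes) for i in range(size)}
    experiment = Experiment(id="exp0", name="default run", watched=watched,
                            duration=spec.duration, dt=spec.dt)

    project = Project(id=f"fixture_seed{spec.seed}", name="synthetic fixture project",
                      model=interpret_network(doc), network=doc,
                      experiments=[experiment], base_dir=out_dir)
    with open(os.path.join(out_dir, "project.json"), "w",
              encoding="utf-8", newline="\n") as fh:
        fh.write(write_project(project))
    return project
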