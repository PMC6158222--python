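# neurometa

A headless middleware core for neuroscience models and data.  Neuroscience
tooling has to juggle heterogeneous artifacts — reconstructed morphologies,
surface meshes, network models, simulation results — each in its own format.
`neurometa` decouples infrastructure from those formats through a small,
domain-agnostic **meta-model**: *Types* describe structure (with single
inheritance and composition), *Variables* are named slots of a Type, and
*Values* (scalars, spheres, cylinders, meshes, time series, pointers) fill
them.  Once a format is expressed in the meta-model, the whole stack —
validation, addressing, serialization, instantiation, simulation, export —
works on it uniformly.

It is aimed at developers of desk-scale analysis tools and at modellers who
want a scriptable, deterministic pipeline from a declarative model to
simulated traces, without a GUI or server.

The package provides:

- **Meta-model** (`neurometa.meta`) — types/variables/values, validation
  reports, path addressing (`net.excitatory[2].v`), and conjunctive queries
  over in-memory data sources.
- **Model interpreters** (`neurometa.interpreters`) — SWC neuronal
  morphologies (root soma → sphere, each child segment → tapered cylinder),
  Wavefront OBJ meshes (fan-triangulated), and a small declarative network
  dialect with populations of leaky integrate-and-fire cells, plus
  population-level connectivity matrices.
- **Instantiation** (`neurometa.instancetree`) — expands a model into an
  addressable instance tree; array types become fixed-size populations;
  import types become lazy-loading placeholders resolved on demand;
  instances get capabilities (state variable / parameter / visual APIs)
  according to their type kind.
- **Simulation** (`neurometa.simulation`) — a pluggable simulator contract
  with a reference RK4 leaky integrate-and-fire engine, and an experiment
  lifecycle (DESIGN → QUEUED → RUNNING → COMPLETED/ERROR) with parameter
  overrides, sweeps, and one-call watch-all recording.
- **Serialization** (`neurometa.serialization`) — canonical, byte-stable
  JSON documents for models and projects, and RFC 4180 CSV export of results.
- **Fixtures & CLI** (`neurometa.fixtures`, `neurometa.cli`) — seeded
  synthetic morphology/network/project generators and a `neurometa`
  command-line tool.

## The reference neuron model

The built-in simulator integrates the leaky integrate-and-fire equation

    τ_m dV/dt = −(V − V_rest) + R_m I_ext

with fixed-step RK4 from `V(0) = V_rest`; when `V ≥ V_thr` a spike is recorded
and `V` is clamped to `V_reset` for the refractory period `t_ref`.  For
constant drive and `V_reset = V_rest` the interspike interval has the closed
form `ISI = τ_m ln(R_m I / (R_m I − (V_thr − V_rest))) + t_ref`, which the
tests use as an independent oracle (e.g. τ_m = 10 ms, R_m = 10 MΩ,
I = 2 nA, 15 mV gap ⇒ ISI = 10 ln 4 ≈ 13.86 ms ⇒ 72 spikes per second).

## Worked example

```python
from neurometa import (FixtureSpec, generate_project, resolve_all_imports,
                       run_experiment, connectivity_matrix)

project = generate_project(FixtureSpec(seed=42, population_sizes=(2, 3),
                                       n_connections=6, n_nodes=12), "demo")
tree = project.tree()
print("instances:", sum(1 for _ in tree.walk()))
print("placeholders:", [i.path for i in tree.placeholders()])
resolve_all_imports(tree, base_dir=project.base_dir)
print("after resolve-all:", sum(1 for _ in tree.walk()), "instances")
matrix, pops = connectivity_matrix(project.model)
print("connection counts:\n", matrix)
exp = run_experiment(project, "exp0")
print("experiment state:", exp.state)
```

prints

```
instances: 60
placeholders: ['net.pop0[0].morphology', 'net.pop0[1].morphology', 'net.pop1[0].morphology', 'net.pop1[1].morphology', 'net.pop1[2].morphology']
after resolve-all: 120 instances
connection counts:
 [[1. 1.]
 [2. 2.]]
experiment state: COMPLETED
```

The generated project holds two populations (2 + 3 cells), each cell with a
membrane potential `v`, its LIF parameters, and a 12-node random morphology
declared as an *import* — the five placeholders above.  Resolving the imports
swaps each placeholder for its interpreted morphology subtree (12 visual
segments per cell), doubling the tree to 120 instances while leaving every
other path untouched.  The connectivity matrix counts the 6 random
connections by (pre, post) population.  Running the bundled experiment
(50 ms at dt = 0.1 ms, all 5 membrane potentials watched) records five
501-sample traces; with the default 2 nA drive each cell fires every
10 ln 4 ≈ 13.86 ms, i.e. 3 spikes in the 50 ms window.  The same flow is
available from the shell:

```sh
neurometa fixture project --seed 42 -o demo
neurometa load demo/project.json
neurometa tree demo/project.json
neurometa resolve demo/project.json all
neurometa run demo/project.json exp0
neurometa export demo/project.json exp0 -o traces.csv
```

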