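# Methods

This note documents the modelling and numerical choices behind `neurometa`:
what the meta-model assumes, how the interpreters map formats onto it, how
instantiation and lazy loading behave, what the reference simulator computes,
and what the synthetic fixtures do and do not emulate.

## The meta-model

The meta-model is a minimal object system: a `Model` owns libraries of
`Type`s plus root `Variable`s; a `Variable` is a named slot of a `Type`; a
`Value` is concrete data filling a slot.  Two composition mechanisms give it
expressive power:

- **Single inheritance.** A type may name one supertype; lineages are finite,
  acyclic lists (self first, root last).  Field merging proceeds root-down so
  the nearest descendant's same-named field wins — the conventional override
  rule of mainstream object systems.  A subtype may override an inherited
  variable's *value* but not its *type*; type redefinition is rejected by
  validation (`type-redefinition`).  Multiple inheritance is deliberately
  excluded: it would make lineage a DAG and the override rule ambiguous,
  with no benefit for the representational use cases targeted here.
- **Composition.** A `CompositeType` contains variables of other types;
  `ArrayType` expands into a fixed-size ordered population of its element
  type; `ImportType` is a placeholder for data not yet loaded.

**Validation** returns an ordered report of findings (severity, path, rule)
rather than raising, so a front end or the CLI can show every problem at
once.  The report order is deterministic (sorted by path, then rule, then
message).  Operations that require a clean model (`instantiate`,
`write_model`) refuse models whose report contains errors.

**Addressing** uses dot-separated paths with zero-based bracket indices
(`net.pop1[2].v`).  Zero-based indexing matches the array semantics of the
scripting environments these models are driven from.  The same grammar
addresses both the static model (navigating variables and their types) and
runtime instance trees; failures carry the deepest valid prefix, which makes
typos easy to locate in deep trees.

**Queries** over the in-memory data source are conjunctive: a record matches
if every `(field, predicate, operand)` filter holds, and output preserves
input order.  Conjunction with stable order is the simplest semantics that
composes predictably (`|q(f1 ∧ f2)| ≤ min(|q(f1)|, |q(f2)|)`); disjunction
and ordering clauses can be layered on top by callers.  Only the in-memory
backend is implemented; the declaration carries a `backend_id` so remote
backends can be registered without touching the model format.

## Serialization

Documents are JSON with a top-level `"schemaVersion": "1"`.  Output is
canonical: keys sorted, two-space indent, floats in Python's shortest
round-trip representation (`repr`), trailing newline.  Canonical form makes
equality checks and caching trivial — equal models serialize to identical
bytes — and float `repr` guarantees lossless round-trips (the test suite
checks recorded traces to full precision).  Unresolved import types
round-trip with `resolved: false` and their locator intact; resolved ones
embed their concrete type.  A project's `viewState` is opaque application
state and round-trips verbatim; the library never interprets it.

Results export is CSV (RFC 4180 quoting, CRLF, `.` decimal separator): one
time column plus one column per watched path in sorted order, header cells
carrying the full instance path and unit.  Export requires the COMPLETED
state, since results are defined only there.

## Interpreters

**SWC.**  Input is the 7-column text format (id, structure code, x, y, z,
radius, parent).  Mapping: every root node becomes a `Sphere` of the node's
radius; every non-root node becomes a `Cylinder` *frustum* from the parent's
position/radius to the node's (linear taper), except that no frustum is
emitted between two consecutive soma samples — multi-sample somas are
rendered as one sphere per sample.  The SWC "standard" has several dialects;
this convention keeps value counts predictable: #spheres = #roots + #extra
soma samples, #cylinders = #nodes − #spheres.  Children must appear after
their parents; forward references are rejected with a clear error rather
than buffered, which keeps the parser single-pass and the error local to the
offending line.  Coordinates and radii are taken as µm (the format declares
no units).  Unknown structure codes are preserved and rendered as cylinders.

**OBJ.**  Only `v` and `f` records are honored; normals, texture
coordinates, materials and groups are silently ignored since only geometry
reaches the mesh value.  Indices are 1-based in the format (negative indices
count from the end) and stored 0-based.  Faces with more than three vertices
are fan-triangulated around their first vertex (n − 2 triangles), which is
area-preserving for planar convex polygons — verified in the tests against a
shoelace-formula oracle to 1e−9 relative.

**Network dialect.**  A document declares cell archetypes (dynamics
parameters, optional SWC morphology), fixed-size populations, and weighted
connections.  Expansion produces one composite cell type per archetype
(membrane potential `v` in mV, one parameter variable per dynamics entry,
morphology as an import type), one array type per population, and a
connections group whose entries hold two `Pointer`s and a weight `Scalar`.
Structural problems — undeclared archetypes, connection indices past a
population's size — surface as validation findings, not exceptions, so a
whole document is diagnosed in one pass.  `connectivity_matrix` aggregates
connections by (pre, post) population in declaration order; the count
variant conserves the number of connection records, the weights variant sums
weights.

## Instantiation and lazy loading

`instantiate` maps declarations to live instances: root variables → root
instances, composites → children per (inheritance-merged) variable, arrays →
`size` children named `name[0] … name[size−1]`, import types → placeholder
instances.  Traversal is declaration order, so instantiation is
deterministic and two runs yield identical path sets.  Placeholders are
first-class and addressable, so trees can be listed and navigated before any
data is loaded.

Capabilities are injected by type kind: state variables expose
`get_unit()` / `get_initial_value()` / `get_time_series()`, parameters expose
bounds-checked `set_value`, visual slots expose their geometry.  Querying a
recording before any simulation returns the explicit `NO_DATA` indicator
rather than raising — absence of data is a normal state, not an error.

`resolve_import` runs the registered interpreter on the placeholder's
locator and swaps the resulting subtree in place; every other path is
unchanged, and re-resolving a path is a no-op.  Replacement is in-place
rather than copy-on-write; the tree contract is single-threaded.  Resolution
is one level per call: imports nested inside interpreter output stay
placeholders (resolved by `resolve_all_imports`, which iterates to a fixed
point).  The concrete type is cached on the shared import *type*, so in
memory each placeholder instance still resolves individually (lazy per
instance), while a persisted project records the type as resolved and all
instances of that archetype load resolved thereafter.  Eager loading
(`resolve_imports_in_model` before instantiation) and deferred per-instance
resolution yield structurally identical trees; the test suite compares the
two routes on random fixtures.

## Reference simulator and experiments

The LIF membrane equation `τ_m dV/dt = −(V − V_rest) + R_m I_ext` is
integrated with classical fixed-step RK4 from `V(0) = V_rest`.  Parameters
and units: `v_rest`, `v_thr`, `v_reset` (mV), `r_m` (MΩ), `tau_m`, `t_ref`
(ms), `i_ext` (nA) — with these units `R_m·I_ext` is already in mV, so no
conversion factors appear.  Defaults are a standard cortical-style point
neuron: rest −65 mV, threshold −50 mV, reset −65 mV, τ = 10 ms, R = 10 MΩ,
`t_ref` = 0, dt = 0.025 ms.

Threshold crossing is detected after each full RK4 step, with the spike time
recorded as the step's end time and no sub-step interpolation — a documented
O(dt) bias chosen for simplicity and determinism.  During the refractory
period the potential is held at `v_reset`.  The trace always has
`floor(duration/dt) + 1` samples starting at t = 0.

Two closed forms serve as oracles: the subthreshold charging curve
`V(t) = V_rest + R_m I (1 − e^{−t/τ})` (the RK4 trace matches it to better
than 1e−6 mV at dt = 0.01 ms over a 10 τ horizon, and halving dt shrinks the
maximum error ≈16×, i.e. fourth order), and the interspike interval
`ISI = τ ln(R I/(R I − (V_thr − V_rest))) + t_ref` for `V_reset = V_rest`
(the simulated spike count over 1 s matches `floor(1000/ISI)` within one
spike — the residual being the threshold-detection bias).

Experiments are a five-state machine, DESIGN → QUEUED → RUNNING →
{COMPLETED, ERROR}, with no other transitions.  "Asynchronous" execution is
modelled as this state machine run synchronously in-process — queue/worker
infrastructure is out of scope, but the contract (failures land in ERROR
with a message and empty results, nothing raised mid-run) is the one an
asynchronous executor would honour.  Calling `run` on an experiment already
in a terminal state is a caller error and raises, since no legal transition
to ERROR exists from there.  Parameter overrides are applied through the
parameter capability (hence bounds-checked) in sorted path order; watched
paths are simulated in sorted order; each watched cell's dynamics are
assembled from its sibling parameter instances.  `sweep` validates every
value against the parameter's bounds before creating anything, so a single
bad value rejects the whole batch atomically.  `watch_all` is set-valued and
only legal in DESIGN.

## Synthetic fixtures

The generators exist to exercise every code path deterministically; one seed
drives one `numpy` default generator per call, with no hidden entropy.

- Morphologies: node 1 is a root soma at the origin; each later node attaches
  to the previous node, or with probability `branching_prob` to a uniformly
  chosen earlier node; step lengths are 1–5 µm, radii uniform in (0.1, 5] µm.
  This produces random rooted trees with realistic branching statistics but
  no biological geometry (no tortuosity model, no type-specific calibers).
- Networks/projects: one LIF archetype per population (default two
  populations of 2 and 3 cells), dynamics at the standard values above with
  a suprathreshold 2 nA drive so generated experiments actually spike,
  `i_ext` bounded to [0, 10] nA, uniform random connectivity, and one
  ready-to-run experiment (50 ms at dt = 0.1 ms) watching every membrane
  potential.
- `generate_model` additionally splices in an inheritance chain, a query, a
  data source, an unresolved import and scalar/pointer/time-series values so
  serialization sweeps cover the whole dialect.

Passing tests on these fixtures demonstrates structural correctness —
conservation laws, round-trips, determinism, lazy/eager equivalence — not
biological fidelity: the fixtures have no dialectal SWC quirks (negative
radii sentinels, custom codes beyond preservation), no synapse dynamics
(connection weights are bookkeeping, not coupling — cells are simulated
independently), and desk-scale sizes (≤ ~1000 morphology nodes, ≤ tens of
cells).

## Numerical and degenerate-input choices

- Floats serialize via shortest round-trip `repr`; no tolerance is needed
  anywhere in serialization — equality is exact.
- Empty arrays (size 0) are valid everywhere: the array instance exists,
  has no children, and its path prefix resolves.
- A zero-duration simulation returns the single t = 0 sample.
- Tie-breaks are lexicographic: validation findings by (path, rule,
  message), watched paths and overrides by path, CSV columns by path.
- Exit codes in the CLI: 0 success, 1 validation/user error, 2 internal.

## Known limitations

- No transport, persistence or concurrency layer; single-process,
  single-threaded contracts throughout.
- One simulator engine (the reference LIF); the registry accepts external
  wrappers but none are bundled.
- No cross-cell coupling in simulation; connections inform structure and
  connectivity analysis only.
- The JSON dialect is versioned but only version "1" exists; no migration
  machinery.
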