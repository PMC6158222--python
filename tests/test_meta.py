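"""Meta-model: inheritance, validation, path addressing and queries."""

import itertools

import pytest

from neurometa import (
    ArrayType,
    CompositeType,
    InMemoryDataSource,
    Library,
    Model,
    QueryDecl,
    Scalar,
    StateVariableType,
    Type,
    Variable,
    effective_fields,
    resolve_path,
    resolve_supertypes,
    run_query,
    validate_model,
)
from neurometa.errors import (
    IndexOutOfRangeError,
    InheritanceCycleError,
    PathNotFoundError,
    QuerySchemaError,
    UnknownTypeError,
)
from neurometa.meta import errors_in


def model_with(types, variables=()):
    return Model(id="m", libraries=[Library(id="lib", types=list(types))],
                 variables=list(variables))


class TestSupertypes:
    def test_base_type_lineage_is_itself(self):
        a = Type(name="A")
        m = model_with([a])
        assert resolve_supertypes(a, m) == [a]

    def test_chain_orders_self_first_root_last(self):
        a = Type(name="A")
        b = Type(name="B", supertype="lib.A")
        c = Type(name="C", supertype="lib.B")
        m = model_with([a, b, c])
        assert resolve_supertypes(c, m) == [c, b, a]

    def test_cycle_raises_naming_members(self):
        a = Type(name="A", supertype="lib.B")
        b = Type(name="B", supertype="lib.A")
        m = model_with([a, b])
        with pytest.raises(InheritanceCycleError) as exc:
            resolve_supertypes(a, m)
        assert "A" in str(exc.value) and "B" in str(exc.value)

    def test_dangling_supertype_raises_unknown_type(self):
        a = Type(name="A", supertype="lib.Ghost")
        with pytest.raises(UnknownTypeError):
            resolve_supertypes(a, model_with([a]))


class TestEffectiveFields:
    def setup_method(self):
        self.v_parent = Variable(name="v", type="lib.volt",
                                 initial_values=[Scalar(-65.0, "mV")])
        self.v_child = Variable(name="v", type="lib.volt",
                                initial_values=[Scalar(-70.0, "mV")])
        self.g = Variable(name="g", type="lib.volt")
        parent = CompositeType(name="P", variables=[self.v_parent])
        child = CompositeType(name="C", supertype="lib.P",
                              variables=[self.v_child, self.g])
        self.m = model_with([StateVariableType(name="volt", unit="mV"),
                             parent, child])
        self.child = child
        self.parent = parent

    def test_child_adds_field_to_parents(self):
        assert set(effective_fields(self.child, self.m)) == {"v", "g"}

    def test_nearest_descendant_value_wins(self):
        merged = effective_fields(self.child, self.m)
        assert merged["v"].initial_values == [Scalar(-70.0, "mV")]

    def test_lineage_of_one_is_identity(self):
        assert effective_fields(self.parent, self.m) == {"v": self.v_parent}

    def test_idempotent_on_already_merged_type(self):
        merged = effective_fields(self.child, self.m)
        flat = CompositeType(name="Flat", variables=list(merged.values()))
        m2 = model_with([StateVariableType(name="volt", unit="mV"), flat])
        assert effective_fields(flat, m2) == merged


class TestValidation:
    def test_clean_model_has_empty_report(self):
        m = model_with([Type(name="A")])
        assert validate_model(m) == []

    def test_variable_with_absent_type_is_one_error(self):
        m = model_with([], [Variable(name="x", type="lib.Foo")])
        report = errors_in(validate_model(m))
        assert len(report) == 1
        assert report[0].severity == "error"

    def test_three_same_named_types_yield_two_findings(self):
        m = model_with([Type(name="Dup"), Type(name="Dup"), Type(name="Dup")])
        dupes = [f for f in validate_model(m) if f.rule == "duplicate-type-name"]
        assert len(dupes) == 2

    def test_type_redefinition_of_inherited_variable_is_flagged(self):
        parent = CompositeType(name="P", variables=[
            Variable(name="v", type="lib.volt")])
        child = CompositeType(name="C", supertype="lib.P", variables=[
            Variable(name="v", type="lib.amp")])
        m = model_with([StateVariableType(name="volt", unit="mV"),
                        StateVariableType(name="amp", unit="nA"), parent, child])
        assert any(f.rule == "type-redefinition" for f in validate_model(m))

    def test_bad_identifier_and_bad_bounds_are_flagged(self):
        from neurometa import ParameterType
        m = model_with(
            [ParameterType(name="p", unit="nA", default_value=5.0, bounds=(0.0, 1.0))],
            [Variable(name="9bad", type="lib.p")])
        rules = {f.rule for f in validate_model(m)}
        assert "identifier-grammar" in rules
        assert "default-outside-bounds" in rules

    def test_composition_cycle_is_flagged(self):
        a = CompositeType(name="A", variables=[Variable(name="b", type="lib.B")])
        b = CompositeType(name="B", variables=[Variable(name="a", type="lib.A")])
        m = model_with([a, b])
        assert any(f.rule == "composition-cycle" for f in validate_model(m))

    def test_array_of_composite_is_not_a_false_cycle(self, project):
        assert not any(f.rule == "composition-cycle"
                       for f in validate_model(project.model))

    def test_report_order_is_deterministic(self):
        m = model_with([Type(name="Dup"), Type(name="Dup")],
                       [Variable(name="x", type="lib.Ghost")])
        assert validate_model(m) == validate_model(m)


class TestResolvePath:
    def test_empty_path_returns_root(self, project):
        assert resolve_path(project.model, "") is project.model

    def test_cell_state_variable_in_population(self, project):
        node = resolve_path(project.model, "net.pop1[2].v")
        assert node.name == "v"

    def test_index_beyond_population_size(self, project):
        with pytest.raises(IndexOutOfRangeError):
            resolve_path(project.model, "net.pop0[99]")

    def test_unknown_segment_reports_deepest_valid_prefix(self, project):
        with pytest.raises(PathNotFoundError) as exc:
            resolve_path(project.model, "net.pop0[1].nope")
        assert exc.value.valid_prefix == "net.pop0[1]"

    def test_every_tree_path_resolves_and_mutations_fail(self, project):
        tree = project.tree()
        paths = [inst.path for inst in tree.walk()]
        for path in paths:
            assert tree.resolve(path).path == path
        known = set(paths)
        # single-character mutations that keep the grammar intact must miss
        checked = 0
        for path in paths[:20]:
            for i, ch in enumerate(path):
                if not ch.isalnum():
                    continue
                mutated = path[:i] + ("z" if ch != "z" else "y") + path[i + 1:]
                if mutated in known:
                    continue
                with pytest.raises((PathNotFoundError, IndexOutOfRangeError)):
                    tree.resolve(mutated)
                checked += 1
        assert checked > 0


RECORDS = [
    {"label": "RMED", "n_synapses": 12, "region": "head"},
    {"label": "RMEV", "n_synapses": 7, "region": "head"},
    {"label": "AVAL", "n_synapses": 40, "region": "body"},
    {"label": "AVAR", "n_synapses": 38, "region": "body"},
    {"label": "PVCL", "n_synapses": 15, "region": "tail"},
    {"label": "PVCR", "n_synapses": 14, "region": "tail"},
    {"label": "DB1", "n_synapses": 5, "region": "body"},
    {"label": "DB2", "n_synapses": 6, "region": "body"},
    {"label": "VA8", "n_synapses": 4, "region": "body"},
    {"label": "VA9", "n_synapses": 3, "region": "body"},
]


class TestQueries:
    def test_any_query_on_empty_source_counts_zero(self):
        q = QueryDecl(id="q", filters=[("label", "contains", "RME")])
        assert run_query(InMemoryDataSource([]), q).count == 0

    def test_label_contains_matches_exactly_two(self):
        q = QueryDecl(id="q", filters=[("label", "contains", "RME")])
        result = run_query(InMemoryDataSource(RECORDS), q)
        assert result.count == 2
        assert [r["label"] for r in result.records] == ["RMED", "RMEV"]

    def test_chained_filters_equal_intersection_of_singles(self):
        # brute-force both sides on a 20-record source
        records = RECORDS + [dict(r, label=r["label"] + "_b") for r in RECORDS]
        ds = InMemoryDataSource(records)
        f1 = ("region", "eq", "body")
        f2 = ("n_synapses", "ge", 6)
        chained = run_query(ds, QueryDecl(id="q", filters=[f1, f2]))
        only1 = run_query(ds, QueryDecl(id="q1", filters=[f1]))
        only2 = run_query(ds, QueryDecl(id="q2", filters=[f2]))
        ids1 = {id(r) for r in only1.records}
        ids2 = {id(r) for r in only2.records}
        assert [id(r) for r in chained.records] == \
            [id(r) for r in records if id(r) in ids1 and id(r) in ids2]

    def test_empty_filter_list_is_identity(self):
        ds = InMemoryDataSource(RECORDS)
        result = run_query(ds, QueryDecl(id="all"))
        assert result.records == RECORDS
        assert result.count == 10

    @pytest.mark.parametrize("f1,f2", list(itertools.combinations(
        [("region", "eq", "body"), ("n_synapses", "ge", 6),
         ("label", "contains", "V"), ("n_synapses", "lt", 15)], 2)))
    def test_conjunction_never_exceeds_either_side(self, f1, f2):
        ds = InMemoryDataSource(RECORDS)
        both = run_query(ds, QueryDecl(id="q", filters=[f1, f2])).count
        assert both <= min(run_query(ds, QueryDecl(id="a", filters=[f1])).count,
                           run_query(ds, QueryDecl(id="b", filters=[f2])).count)

    def test_unknown_field_raises_schema_error(self):
        ds = InMemoryDataSource(RECORDS)
        with pytest.raises(QuerySchemaError):
            run_query(ds, QueryDecl(id="q", filters=[("nope", "eq", 1)]))
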