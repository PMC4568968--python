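import numpy as np
import pytest

from agepath.mapping import CategoryGeneSets
from agepath.ontology import GoDag, compile_term_sets, read_annotations, read_obo
from conftest import random_dag

MINI_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: child one
namespace: biological_process
alt_id: GO:0000099
is_a: GO:0000001

[Term]
id: GO:0000003
name: child two
namespace: biological_process
relationship: part_of GO:0000001

[Term]
id: GO:0000004
name: gone
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture
def mini_obo(tmp_path):
    path = tmp_path / "mini.obo"
    path.write_text(MINI_OBO, encoding="utf-8")
    return path


class TestReadObo:
    def test_terms_and_typed_edges(self, mini_obo):
        dag = read_obo(mini_obo)
        assert len(dag.terms) == 4
        assert dag.parents["GO:0000002"] == (("GO:0000001", "is_a"),)
        assert dag.parents["GO:0000003"] == (("GO:0000001", "part_of"),)
        assert dag.roots() == {"GO:0000001"}

    def test_alt_id_resolves_to_primary(self, mini_obo):
        dag = read_obo(mini_obo)
        assert dag.resolve("GO:0000099") == "GO:0000002"
        assert "GO:0000099" in dag

    def test_obsolete_term_flagged_and_edge_free(self, mini_obo):
        dag = read_obo(mini_obo)
        assert dag.is_obsolete("GO:0000004")
        assert "GO:0000004" not in dag.parents

    def test_cycle_is_fatal(self):
        terms = {t: {"name": t, "namespace": "biological_process", "obsolete": False}
                 for t in ("A", "B")}
        with pytest.raises(ValueError, match="cycle"):
            GoDag(terms=terms,
                  parents={"A": (("B", "is_a"),), "B": (("A", "is_a"),)})

    def test_dangling_edge_is_fatal(self):
        terms = {"A": {"name": "A", "namespace": "biological_process",
                       "obsolete": False}}
        with pytest.raises(ValueError, match="dangling"):
            GoDag(terms=terms, parents={"A": (("GHOST", "is_a"),)})


class TestReadAnnotations:
    def gaf_row(self, gene, term, qualifier="", evidence="IDA"):
        fields = ["DB", gene, gene, qualifier, term, "REF", evidence, "", "P",
                  "", "", "protein", "taxon:9606", "20130101", "DB", "", ""]
        return "\t".join(fields)

    def test_not_qualified_rows_excluded(self, mini_obo, tmp_path):
        dag = read_obo(mini_obo)
        path = tmp_path / "ann.gaf"
        path.write_text(
            "!gaf-version: 2.1\n"
            + self.gaf_row("geneA", "GO:0000002", qualifier="NOT") + "\n"
            + self.gaf_row("geneB", "GO:0000002") + "\n",
            encoding="utf-8",
        )
        amap = read_annotations(path, dag)
        assert amap.by_gene == {"geneB": {"GO:0000002"}}
        assert amap.n_dropped_not == 1

    def test_two_column_tsv_and_alt_id(self, mini_obo, tmp_path):
        dag = read_obo(mini_obo)
        path = tmp_path / "ann.tsv"
        path.write_text("geneA\tGO:0000099\ngeneB\tGO:0000003\n", encoding="utf-8")
        amap = read_annotations(path, dag)
        assert amap.by_gene["geneA"] == {"GO:0000002"}  # alt_id resolved

    def test_unknown_and_obsolete_terms_dropped_with_counts(self, mini_obo, tmp_path):
        dag = read_obo(mini_obo)
        path = tmp_path / "ann.tsv"
        path.write_text(
            "geneA\tGO:0099999\ngeneA\tGO:0000004\ngeneA\tGO:0000002\n",
            encoding="utf-8",
        )
        amap = read_annotations(path, dag)
        assert amap.n_dropped_unknown == 1 and amap.n_dropped_obsolete == 1
        assert amap.by_gene["geneA"] == {"GO:0000002"}

    def test_namespace_filter(self, tmp_path):
        terms = {
            "GO:1": {"name": "bp", "namespace": "biological_process", "obsolete": False},
            "GO:2": {"name": "mf", "namespace": "molecular_function", "obsolete": False},
        }
        dag = GoDag(terms=terms, parents={})
        path = tmp_path / "ann.tsv"
        path.write_text("g\tGO:1\ng\tGO:2\n", encoding="utf-8")
        amap = read_annotations(path, dag, namespace_filter="biological_process")
        assert amap.by_gene["g"] == {"GO:1"}
        assert amap.n_dropped_namespace == 1

    def test_zero_surviving_annotations_fatal(self, mini_obo, tmp_path):
        dag = read_obo(mini_obo)
        path = tmp_path / "ann.tsv"
        path.write_text("geneA\tGO:0099999\n", encoding="utf-8")
        with pytest.raises(ValueError, match="no surviving"):
            read_annotations(path, dag)

    def test_evidence_exclusion(self, mini_obo, tmp_path):
        dag = read_obo(mini_obo)
        path = tmp_path / "ann.gaf"
        path.write_text(
            self.gaf_row("geneA", "GO:0000002", evidence="IEA") + "\n"
            + self.gaf_row("geneB", "GO:0000002") + "\n",
            encoding="utf-8",
        )
        amap = read_annotations(path, dag, exclude_evidence=["IEA"])
        assert "geneA" not in amap.by_gene and amap.n_dropped_evidence == 1


class TestCompileTermSets:
    def make_inputs(self, mini_obo):
        from agepath.ontology import AnnotationMap

        dag = read_obo(mini_obo)
        amap = AnnotationMap(by_gene={"A": {"GO:0000002"}, "B": {"GO:0000003"}})
        gene_sets = CategoryGeneSets(sets={"cat1": {"A", "B"}, "cat2": {"A"}})
        return dag, amap, gene_sets

    def test_direct_union(self, mini_obo):
        dag, amap, gene_sets = self.make_inputs(mini_obo)
        tsets, unannotated = compile_term_sets(gene_sets, amap, dag=dag)
        assert tsets.sets["cat1"] == {"GO:0000002", "GO:0000003"}
        assert tsets.sets["cat2"] == {"GO:0000002"}
        assert unannotated == {"cat1": 0, "cat2": 0}

    def test_propagation_adds_ancestors_minus_root(self, mini_obo):
        dag, amap, gene_sets = self.make_inputs(mini_obo)
        tsets, _ = compile_term_sets(gene_sets, amap, dag=dag, propagate=True)
        # the only ancestor is the namespace root, excluded by default
        assert tsets.sets["cat1"] == {"GO:0000002", "GO:0000003"}
        tsets_root, _ = compile_term_sets(gene_sets, amap, dag=dag,
                                          propagate=True, exclude_roots=False)
        assert "GO:0000001" in tsets_root.sets["cat1"]

    def test_unannotated_category_empty_with_count(self, mini_obo):
        from agepath.ontology import AnnotationMap

        dag = read_obo(mini_obo)
        amap = AnnotationMap(by_gene={"A": {"GO:0000002"}})
        gene_sets = CategoryGeneSets(sets={"cat1": {"Z1", "Z2"}, "cat2": {"A"}})
        tsets, unannotated = compile_term_sets(gene_sets, amap, dag=dag)
        assert tsets.sets["cat1"] == set()
        assert unannotated["cat1"] == 2

    def test_propagation_idempotent_and_monotone(self):
        rng = np.random.default_rng(11)
        dag = random_dag(rng, 60)
        ids = sorted(dag.terms)
        from agepath.ontology import AnnotationMap

        genes = {f"g{i}": {ids[int(j)] for j in rng.choice(60, size=3, replace=False)}
                 for i in range(10)}
        amap = AnnotationMap(by_gene=genes)
        small = CategoryGeneSets(sets={"c1": {"g0", "g1"}, "c2": {"g2"}})
        bigger = CategoryGeneSets(sets={"c1": {"g0", "g1", "g3"}, "c2": {"g2"}})
        t1, _ = compile_term_sets(small, amap, dag=dag, propagate=True)
        # idempotence: propagating an already-closed set changes nothing
        closed_genes = {f"t_{t}": {t} | set(dag.ancestors(t))
                        for t in t1.sets["c1"]}
        amap2 = AnnotationMap(by_gene=closed_genes)
        closure_sets = CategoryGeneSets(sets={"c1": set(closed_genes), "c2": {next(iter(closed_genes))}})
        t2, _ = compile_term_sets(closure_sets, amap2, dag=dag, propagate=True)
        t2_direct, _ = compile_term_sets(closure_sets, amap2, dag=dag, propagate=False)
        assert t2.sets["c1"] == t2_direct.sets["c1"]
        # monotone: adding a gene never removes a term
        t3, _ = compile_term_sets(bigger, amap, dag=dag, propagate=True)
        assert t1.sets["c1"] <= t3.sets["c1"]

    def test_ancestors_match_naive_transitive_closure(self):
        rng = np.random.default_rng(5)
        dag = random_dag(rng, 100)

        def naive(term):
            out = set()
            frontier = {p for p, _ in dag.parents.get(term, ())}
            while frontier:
                out |= frontier
                frontier = {
                    p for t in frontier for p, _ in dag.parents.get(t, ())
                } - out
            return out

        for term in sorted(dag.terms):
            assert set(dag.ancestors(term)) == naive(term)
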