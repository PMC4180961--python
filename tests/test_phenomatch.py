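import math

import numpy as np
import pytest

from cnvmech.genome import GeneRecord, GenomicInterval
from cnvmech.ontology import (
    AnnotationTable,
    ICTable,
    OntologyDAG,
    information_content,
    propagate,
)
from cnvmech.phenomatch import (
    AMBIGUOUS,
    ASSIGNED,
    UNASSIGNED,
    PatientRecord,
    TargetTermSet,
    assign_target_term,
    common_ancestors,
    phenogram_score,
    phenomatch_score,
    score_vs_random_placement,
)

from conftest import (
    oracle_phenomatch,
    random_annotations,
    random_parent_edges,
)


@pytest.fixture
def two_branch_dag():
    # root -> T1 -> {x1, x2}; root -> T2 -> {y1}
    return OntologyDAG.from_edges(
        [("T1", "root"), ("T2", "root"), ("x1", "T1"), ("x2", "T1"), ("y1", "T2")]
    )


@pytest.fixture
def two_targets(two_branch_dag):
    return TargetTermSet(("T1", "T2"), {"T1": "tissueA", "T2": "tissueB"})


def _patient_ic(dag, patients):
    table = propagate(dag, AnnotationTable("patient", patients))
    return information_content(dag, table, "patients"), table


class TestAssignTarget:
    def test_single_branch(self, two_branch_dag, two_targets):
        ic, table = _patient_ic(
            two_branch_dag,
            {"p1": frozenset({"x1"}), "p2": frozenset({"y1"})},
        )
        a = assign_target_term(table.propagated["p1"], two_targets, ic, two_branch_dag)
        assert a.status == ASSIGNED and a.target == "T1"

    def test_unassigned_when_no_overlap(self, two_branch_dag, two_targets):
        ic, table = _patient_ic(two_branch_dag, {"p1": frozenset({"root"})})
        a = assign_target_term(table.propagated["p1"], two_targets, ic, two_branch_dag)
        assert a.status == UNASSIGNED and a.target is None

    def test_ambiguous_on_tied_maximum(self, two_branch_dag, two_targets):
        # symmetric cohort: x1 and y1 have identical frequencies -> equal IC sums
        ic, table = _patient_ic(
            two_branch_dag,
            {"p1": frozenset({"x1", "y1"}), "p2": frozenset({"x1", "y1"})},
        )
        a = assign_target_term(table.propagated["p1"], two_targets, ic, two_branch_dag)
        assert a.status == AMBIGUOUS

    def test_requires_propagated_terms(self, two_branch_dag, two_targets):
        ic, _ = _patient_ic(two_branch_dag, {"p1": frozenset({"x1"})})
        with pytest.raises(ValueError, match="propagated"):
            assign_target_term(frozenset({"x1"}), two_targets, ic, two_branch_dag)

    def test_order_invariance(self, two_branch_dag):
        ic, table = _patient_ic(
            two_branch_dag,
            {"p1": frozenset({"x1", "x2"}), "p2": frozenset({"y1"})},
        )
        fwd = TargetTermSet(("T1", "T2"), {"T1": "a", "T2": "b"})
        rev = TargetTermSet(("T2", "T1"), {"T1": "a", "T2": "b"})
        a1 = assign_target_term(table.propagated["p1"], fwd, ic, two_branch_dag)
        a2 = assign_target_term(table.propagated["p1"], rev, ic, two_branch_dag)
        assert a1.status == a2.status == ASSIGNED
        assert a1.target == a2.target


class TestCommonAncestors:
    def test_contains_term_on_exact_match(self, diamond_dag):
        ca = common_ancestors(diamond_dag, "a", frozenset({"a"}))
        assert "a" in ca

    def test_disjoint_branches_root_only(self, diamond_dag):
        ca = common_ancestors(diamond_dag, "b", frozenset({"c"}))
        assert ca == {"root"}

    def test_never_empty(self, diamond_dag):
        for t in diamond_dag.terms:
            assert "root" in common_ancestors(diamond_dag, t, frozenset({"a"}))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_intersection(self, seed):
        from conftest import oracle_ancestors

        rng = np.random.default_rng(seed)
        edges = random_parent_edges(rng, 30)
        dag = OntologyDAG(edges)
        terms = sorted(dag.terms)
        for _ in range(20):
            t_g = terms[int(rng.integers(len(terms)))]
            annot = frozenset(
                rng.choice(terms, size=int(rng.integers(1, 4)), replace=False)
            )
            expected = frozenset().union(
                *[oracle_ancestors(edges, t) for t in annot]
            ) & oracle_ancestors(edges, t_g)
            assert common_ancestors(dag, t_g, annot) == expected


class TestPhenomatchScore:
    def test_root_only_gene_scores_zero(self, diamond_dag, diamond_ic):
        assert phenomatch_score(("root",), frozenset({"a"}), diamond_ic, diamond_dag) == 0.0

    def test_exact_match_scores_ic(self, diamond_dag, diamond_ic):
        annot = diamond_dag.ancestors_of_set({"b"})
        s = phenomatch_score(("b",), annot, diamond_ic, diamond_dag)
        assert s == pytest.approx(math.log(2), abs=1e-12)

    def test_frozen_diamond_example(self, diamond_dag, diamond_ic):
        # gene terms (a, b) vs patient {c}: best CA for a is c (ln 2), for b is root (0)
        annot = diamond_dag.ancestors_of_set({"c"})
        s = phenomatch_score(("a", "b"), annot, diamond_ic, diamond_dag)
        assert s == pytest.approx(math.log(2), abs=1e-12)

    def test_self_match_upper_bound(self, diamond_dag, diamond_ic):
        gene_terms = ("a", "b", "c")
        annot = diamond_dag.ancestors_of_set({"a", "b", "c"})
        s = phenomatch_score(gene_terms, annot, diamond_ic, diamond_dag)
        bound = sum(diamond_ic.ic[t] for t in gene_terms)
        assert s <= bound + 1e-12

    def test_monotone_in_patient_terms(self, diamond_dag, diamond_ic):
        s1 = phenomatch_score(
            ("a",), diamond_dag.ancestors_of_set({"b"}), diamond_ic, diamond_dag
        )
        s2 = phenomatch_score(
            ("a",), diamond_dag.ancestors_of_set({"b", "a"}), diamond_ic, diamond_dag
        )
        assert s2 >= s1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        edges = random_parent_edges(rng, int(rng.integers(5, 50)))
        dag = OntologyDAG(edges)
        terms = sorted(dag.terms)
        corpus = propagate(dag, random_annotations(rng, terms, 8))
        ic = information_content(dag, corpus)
        for _ in range(10):
            gene_terms = tuple(
                sorted(rng.choice(terms, size=int(rng.integers(1, 5)), replace=False))
            )
            annot_direct = frozenset(
                rng.choice(terms, size=int(rng.integers(1, 4)), replace=False)
            )
            annot = dag.ancestors_of_set(annot_direct)
            expected = oracle_phenomatch(edges, gene_terms, annot_direct, ic.ic)
            assert phenomatch_score(gene_terms, annot, ic, dag) == expected


class TestGeneTermSetChoice:
    """The gene side of the score uses the DIRECT gene term set; summing over
    the propagated closure would multiply-count one match.  Both behaviors
    are exercised: callers control which set they pass."""

    def test_propagated_set_inflates_score(self, diamond_dag, diamond_ic):
        annot = diamond_dag.ancestors_of_set({"a"})
        direct = ("a",)
        propagated = tuple(sorted(diamond_dag.ancestors_of_set({"a"})))
        s_direct = phenomatch_score(direct, annot, diamond_ic, diamond_dag)
        s_prop = phenomatch_score(propagated, annot, diamond_ic, diamond_dag)
        # direct: IC(a); propagated adds IC(b) + IC(c) + IC(root) on top
        assert s_direct == pytest.approx(math.log(4), abs=1e-12)
        assert s_prop == pytest.approx(
            math.log(4) + math.log(2) + math.log(2), abs=1e-12
        )
        assert s_prop > s_direct


class TestPhenogramScore:
    def test_single_gene_equals_its_score(self, diamond_dag, diamond_ic):
        annot = diamond_dag.ancestors_of_set({"b"})
        single = phenomatch_score(("b",), annot, diamond_ic, diamond_dag)
        assert phenogram_score([("b",)], annot, diamond_ic, diamond_dag) == single

    def test_empty_region_zero(self, diamond_dag, diamond_ic):
        assert phenogram_score([], frozenset({"root"}), diamond_ic, diamond_dag) == 0.0

    def test_max_of_three(self, diamond_dag):
        ic = ICTable("x", {}, {"a": math.log(4), "b": math.log(2)})
        annot = diamond_dag.ancestors_of_set({"a"})
        genes = [("root",), ("a",), ("b",)]
        s = phenogram_score(genes, annot, ic, diamond_dag)
        assert s == pytest.approx(math.log(4), abs=1e-12)

    def test_monotone_in_genes(self, diamond_dag, diamond_ic):
        annot = diamond_dag.ancestors_of_set({"a"})
        s1 = phenogram_score([("b",)], annot, diamond_ic, diamond_dag)
        s2 = phenogram_score([("b",), ("a",)], annot, diamond_ic, diamond_dag)
        assert s2 >= s1


class TestRandomPlacementComparison:
    def _cohort(self, dag, ic, n=8):
        annot = dag.ancestors_of_set({"a"})
        patients = [
            PatientRecord(f"p{i}", annot, GenomicInterval("chr1", i * 2000, i * 2000 + 1000))
            for i in range(n)
        ]
        return patients

    def test_no_annotations_gives_p_one(self, diamond_dag, diamond_ic):
        patients = self._cohort(diamond_dag, diamond_ic)
        report = score_vs_random_placement(
            patients, [], {}, {"chr1": 100_000}, diamond_ic, diamond_dag,
            n_placements=5, seed=0,
        )
        assert report.p_value == 1.0
        assert np.all(report.real_scores == 0) and np.all(report.random_scores == 0)

    def test_planted_enrichment_detected(self, diamond_dag, diamond_ic):
        # every deletion contains a relevant gene; genome is otherwise gene-free
        patients = self._cohort(diamond_dag, diamond_ic, n=12)
        genes = [
            GeneRecord(f"g{i}", GenomicInterval("chr1", i * 2000 + 100, i * 2000 + 200))
            for i in range(12)
        ]
        gene_terms = {g.gene_id: frozenset({"a"}) for g in genes}
        report = score_vs_random_placement(
            patients, genes, gene_terms, {"chr1": 10_000_000},
            diamond_ic, diamond_dag, n_placements=50, seed=1,
        )
        assert report.real_mean > report.random_mean
        assert report.p_value < 0.05

    def test_degenerate_everything_covered(self, diamond_dag, diamond_ic):
        patients = [
            PatientRecord("p0", diamond_dag.ancestors_of_set({"a"}),
                          GenomicInterval("chr1", 0, 1000))
        ]
        genes = [GeneRecord("g0", GenomicInterval("chr1", 0, 10_000))]
        gene_terms = {"g0": frozenset({"a"})}
        report = score_vs_random_placement(
            patients, genes, gene_terms, {"chr1": 10_000},
            diamond_ic, diamond_dag, n_placements=1, seed=2,
        )
        assert np.array_equal(report.real_scores, report.random_scores)

    def test_oversized_deletion_errors(self, diamond_dag, diamond_ic):
        patients = [
            PatientRecord("p0", frozenset({"root"}), GenomicInterval("chr1", 0, 5000))
        ]
        with pytest.raises(ValueError, match="fits on no chromosome"):
            score_vs_random_placement(
                patients, [], {}, {"chr1": 1000}, diamond_ic, diamond_dag,
                n_placements=2, seed=0,
            )
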