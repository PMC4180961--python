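"""Permutation null models and empirical P values.

Two schemes: (1) each patient receives the full phenotype annotation of a
randomly chosen patient from a different target-term group (deletions stay
fixed); (2) gene identifiers are permuted in the gene annotation table,
holding the number of annotated genes and the depth of annotation constant.
The empirical P value is the plain fraction of replicates whose rate is at
least the observed one, with a reporting floor of 1/n_reps when no replicate
reaches it.

``CohortEvaluator`` precomputes the per-deletion geometry (boundary
containment, adjacent regions, genes and enhancer tissues per side) so that
re-classifying a cohort under permuted annotations costs only cached
phenomatch lookups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .classify import classify_deletion, TDBD_ONLY, TDBD_GDE
from .genome import GenomeArchitecture, adjacent_regions, complete_overlap
from .ontology import AnnotationTable, ICTable, OntologyDAG
from .phenomatch import ASSIGNED, PatientRecord, TargetTermSet, assign_target_term

__all__ = [
    "PermutationResult",
    "CohortEvaluator",
    "shuffle_patient_phenotypes",
    "permute_gene_annotations",
    "empirical_p",
    "run_phenotype_shuffle_test",
    "run_gene_permutation_test",
]

RATE_TDBD_ONLY = (TDBD_ONLY,)
RATE_TDBD_OR_MIXED = (TDBD_ONLY, TDBD_GDE)


@dataclass(frozen=True)
class PermutationResult:
    observed_rate: float
    null_rates: Tuple[float, ...]
    n_reps: int
    empirical_p: float
    p_report: str
    seed: Optional[int]

    def __post_init__(self):
        if len(self.null_rates) != self.n_reps:
            raise ValueError("null_rates length must equal n_reps")


def empirical_p(observed: float, nulls: Sequence[float]) -> Tuple[float, str]:
    """p = #{null >= observed} / n; zero is reported as '< 1/n'."""
    n = len(nulls)
    if n == 0:
        raise ValueError("need at least one null replicate")
    count = sum(1 for r in nulls if r >= observed)
    p = count / n
    report = f"< {1.0 / n:g}" if count == 0 else f"{p:g}"
    return p, report


def shuffle_patient_phenotypes(
    patients: Sequence[PatientRecord],
    groups: Mapping[str, Sequence[int]],
    rng: np.random.Generator,
) -> List[int]:
    """Donor index per patient, drawn uniformly (with replacement) from the
    patients in a *different* target group.

    ``groups`` maps target term -> patient indices.  Patients not in any
    group keep themselves (index identity).  Raises with fewer than two
    non-empty groups.
    """
    nonempty = [g for g, idx in groups.items() if len(idx) > 0]
    if len(nonempty) < 2:
        raise ValueError("phenotype shuffling needs >= 2 non-empty target groups")
    member_of: Dict[int, str] = {}
    for g, idx in groups.items():
        for i in idx:
            member_of[i] = g
    all_idx = np.array(sorted(member_of), dtype=int)
    group_arr = np.array([member_of[i] for i in all_idx])
    donors = list(range(len(patients)))
    for i in range(len(patients)):
        g = member_of.get(i)
        if g is None:
            continue
        pool = all_idx[group_arr != g]
        donors[i] = int(pool[rng.integers(len(pool))])
    return donors


def permute_gene_annotations(
    gene_table: AnnotationTable, rng: np.random.Generator
) -> AnnotationTable:
    """Relabel the annotation table by a uniform permutation of gene ids."""
    ids = sorted(gene_table.direct)
    if len(ids) < 2:
        raise ValueError("need >= 2 genes to permute")
    perm = rng.permutation(len(ids))
    direct = {ids[perm[i]]: gene_table.direct[ids[i]] for i in range(len(ids))}
    prop = None
    if gene_table.propagated is not None:
        prop = {ids[perm[i]]: gene_table.propagated[ids[i]] for i in range(len(ids))}
    return AnnotationTable(gene_table.entity_kind, direct, prop)


class CohortEvaluator:
    """Precomputed cohort geometry for fast re-classification under permuted
    annotations.

    The per-deletion geometry (contained boundaries, genes within/adjacent,
    enhancer tissues per adjacent side) is fixed; what varies across
    permutation replicates is which annotation set (and hence target) each
    patient carries, or which gene carries which term set.
    """

    def __init__(
        self,
        patients: Sequence[PatientRecord],
        architecture: GenomeArchitecture,
        dag: OntologyDAG,
        gene_annotations: AnnotationTable,
        targets: TargetTermSet,
        ic_genes: ICTable,
        ic_patients: ICTable,
    ):
        if gene_annotations.propagated is None:
            raise ValueError("gene annotations must be propagated")
        self.patients = list(patients)
        self.arch = architecture
        self.dag = dag
        self.gene_annotations = gene_annotations
        self.targets = targets
        self.ic_genes = ic_genes
        self.ic_patients = ic_patients
        n = len(self.patients)

        # per-patient target assignment (donor side of the shuffle)
        self.assignments = [
            assign_target_term(p.terms, targets, ic_patients, dag) for p in self.patients
        ]
        self.assigned = np.array(
            [a.status == ASSIGNED for a in self.assignments], dtype=bool
        )
        self.target_of = [
            a.target if a.status == ASSIGNED else None for a in self.assignments
        ]
        self.groups: Dict[str, List[int]] = {}
        for i, t in enumerate(self.target_of):
            if t is not None:
                self.groups.setdefault(t, []).append(i)

        # per-deletion fixed geometry
        self.genes_within: List[List[str]] = []
        self.genes_left: List[List[str]] = []
        self.genes_right: List[List[str]] = []
        self.enh_left: List[Set[str]] = []
        self.enh_right: List[Set[str]] = []
        self.has_boundary = np.zeros(n, dtype=bool)
        for i, p in enumerate(self.patients):
            d = p.deletion
            self.has_boundary[i] = any(
                complete_overlap(d, b) for b in architecture.boundaries
            )
            adj = adjacent_regions(d, architecture)
            self.genes_within.append(
                [g.gene_id for g in architecture.genes_within_deletion(d)]
            )
            self.genes_left.append([g.gene_id for g in architecture.genes_in(adj.left)])
            self.genes_right.append(
                [g.gene_id for g in architecture.genes_in(adj.right)]
            )
            self.enh_left.append(
                {
                    t
                    for t in architecture.enhancers
                    if architecture.enhancers_in(t, adj.left)
                }
            )
            self.enh_right.append(
                {
                    t
                    for t in architecture.enhancers
                    if architecture.enhancers_in(t, adj.right)
                }
            )

        # per-term ancestors sorted by gene-corpus IC (descending) for O(depth)
        # best-common-ancestor lookups against ancestor-closed patient sets
        self._anc_by_ic: Dict[str, List[Tuple[float, str]]] = {}
        self._pair_scores: Dict[Tuple[str, int], float] = {}
        self._category_cache = np.full((n, n), -1, dtype=np.int8)
        self._cat_codes = {"TDBD_only": 0, "TDBD_GDE": 1, "GDE": 2, "unexplained": 3}
        self._cat_names = {v: k for k, v in self._cat_codes.items()}

    # -- scoring --------------------------------------------------------------

    def _ranked_ancestors(self, term: str) -> List[Tuple[float, str]]:
        out = self._anc_by_ic.get(term)
        if out is None:
            pairs = [
                (self.ic_genes.ic[a], a)
                for a in self.dag.ancestors(term)
                if a in self.ic_genes.ic
            ]
            pairs.sort(key=lambda x: (-x[0], x[1]))
            out = pairs
            self._anc_by_ic[term] = out
        return out

    def phenomatch(self, gene_id: str, donor: int) -> float:
        """Phenomatch score of a gene against donor patient's term set (cached)."""
        key = (gene_id, donor)
        cached = self._pair_scores.get(key)
        if cached is not None:
            return cached
        annot = self.patients[donor].terms  # ancestor-closed
        total = 0.0
        for t_g in self.gene_annotations.direct.get(gene_id, ()):  # direct terms
            for ic, anc in self._ranked_ancestors(t_g):
                if anc in annot:
                    total += ic
                    break
        self._pair_scores[key] = total
        return total

    def _phenogram(self, gene_ids: Sequence[str], donor: int) -> float:
        best = 0.0
        for g in gene_ids:
            s = self.phenomatch(g, donor)
            if s > best:
                best = s
        return best

    def _tdbd_geom(self, i: int, target: str) -> bool:
        if not self.has_boundary[i]:
            return False
        tissue = self.targets.tissue_of(target)
        prop = self.gene_annotations.propagated
        gene_left = any(target in prop.get(g, ()) for g in self.genes_left[i])
        gene_right = any(target in prop.get(g, ()) for g in self.genes_right[i])
        return (tissue in self.enh_left[i] and gene_right) or (
            tissue in self.enh_right[i] and gene_left
        )

    def category(self, i: int, donor: int) -> int:
        """Classify patient i's deletion carrying donor's annotations; coded."""
        c = self._category_cache[i, donor]
        if c >= 0:
            return int(c)
        target = self.target_of[donor]
        assert target is not None
        tdbd = self._tdbd_geom(i, target)
        s_within = self._phenogram(self.genes_within[i], donor)
        s_adj = max(
            self._phenogram(self.genes_left[i], donor),
            self._phenogram(self.genes_right[i], donor),
        )
        cat = classify_deletion(tdbd, s_within > 0, s_within, s_adj)
        code = self._cat_codes[cat]
        self._category_cache[i, donor] = code
        return code

    def rate(self, donors: Sequence[int], rate_categories: Tuple[str, ...]) -> float:
        """Fraction of assessed patients in the given categories when each
        patient i carries the annotations of patient donors[i]."""
        codes = {self._cat_codes[c] for c in rate_categories}
        hits = 0
        assessed = 0
        for i, d in enumerate(donors):
            if not self.assigned[d]:
                continue
            assessed += 1
            if self.category(i, d) in codes:
                hits += 1
        return hits / assessed if assessed else 0.0

    def observed_rate(self, rate_categories: Tuple[str, ...]) -> float:
        return self.rate(list(range(len(self.patients))), rate_categories)


def run_phenotype_shuffle_test(
    evaluator: CohortEvaluator,
    n_reps: int = 10_000,
    seed: Optional[int] = None,
    rate_categories: Tuple[str, ...] = RATE_TDBD_ONLY,
) -> PermutationResult:
    """Permute patient phenotypes across target groups and recompute the rate
    of boundary-disruption calls per replicate."""
    rng = np.random.default_rng(seed)
    observed = evaluator.observed_rate(rate_categories)
    nulls: List[float] = []
    for _ in range(n_reps):
        donors = shuffle_patient_phenotypes(
            evaluator.patients, evaluator.groups, rng
        )
        nulls.append(evaluator.rate(donors, rate_categories))
    p, report = empirical_p(observed, nulls)
    return PermutationResult(observed, tuple(nulls), n_reps, p, report, seed)


def run_gene_permutation_test(
    evaluator: CohortEvaluator,
    n_reps: int = 1_000,
    seed: Optional[int] = None,
    rate_categories: Tuple[str, ...] = RATE_TDBD_ONLY,
) -> PermutationResult:
    """Permute gene ids in the annotation table and recompute the rate per
    replicate.  Term frequencies (and hence IC) are invariant under the
    permutation, so only gene-to-term-set assignments change."""
    rng = np.random.default_rng(seed)
    observed = evaluator.observed_rate(rate_categories)
    base = evaluator.gene_annotations
    identity = list(range(len(evaluator.patients)))
    nulls: List[float] = []
    for _ in range(n_reps):
        permuted = permute_gene_annotations(base, rng)
        sub = CohortEvaluator.__new__(CohortEvaluator)
        sub.__dict__.update(evaluator.__dict__)
        sub.gene_annotations = permuted
        sub._pair_scores = {}
        sub._anc_by_ic = evaluator._anc_by_ic  # IC-invariant: safe to share
        sub._category_cache = np.full_like(evaluator._category_cache, -1)
        nulls.append(sub.rate(identity, rate_categories))
    p, report = empirical_p(observed, nulls)
    return PermutationResult(observed, tuple(nulls), n_reps, p, report, seed)
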