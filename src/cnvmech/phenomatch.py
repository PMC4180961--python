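"""Phenotypic similarity between patient term sets and genes.

A patient is assigned to one of ten tissue target terms by summing, per
target, the information content of the patient's terms that fall under that
target's subtree and taking the unique argmax.  A gene's phenomatch score
against a patient is the sum, over the gene's direct phenotype terms, of the
best common-ancestor IC with the patient's terms; a region's phenogram score
is the maximum phenomatch score over its genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .genome import GenomicInterval, GeneRecord, random_placement
from .ontology import ICTable, OntologyDAG

__all__ = [
    "DEFAULT_HPO_TARGETS",
    "TargetTermSet",
    "PatientRecord",
    "TargetAssignment",
    "assign_target_term",
    "common_ancestors",
    "phenomatch_score",
    "phenogram_score",
    "RandomPlacementReport",
    "score_vs_random_placement",
]

#: Default tissue -> HPO target-term map for the ten tissues with
#: tissue-specific enhancer tracks.
DEFAULT_HPO_TARGETS: Dict[str, str] = {
    "fetal_adrenal_gland": "HP:0000834",  # Abnormality of the adrenal glands
    "fetal_brain": "HP:0100547",  # Abnormality of the forebrain
    "fetal_heart": "HP:0001627",  # Abnormality of the heart
    "fetal_intestine": "HP:0002242",  # Abnormality of the intestine
    "fetal_kidney": "HP:0000077",  # Abnormality of the kidney
    "fetal_lung": "HP:0002088",  # Abnormality of the lung
    "fetal_muscle": "HP:0003011",  # Abnormality of the musculature
    "fetal_stomach": "HP:0002577",  # Abnormality of the stomach
    "fetal_thymus": "HP:0000777",  # Abnormality of the thymus
    "white_blood_cells": "HP:0001881",  # Abnormality of leukocytes
}


@dataclass(frozen=True)
class TargetTermSet:
    """Ordered target terms and their tissue labels."""

    targets: Tuple[str, ...]
    tissue_map: Mapping[str, str]  # target term -> tissue label

    def __post_init__(self):
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("target terms must be distinct")
        missing = [t for t in self.targets if t not in self.tissue_map]
        if missing:
            raise ValueError(f"targets without tissue label: {missing}")

    @classmethod
    def from_tissue_map(cls, tissue_to_term: Mapping[str, str]) -> "TargetTermSet":
        terms = tuple(tissue_to_term[t] for t in tissue_to_term)
        return cls(terms, {term: tissue for tissue, term in tissue_to_term.items()})

    @classmethod
    def default_hpo(cls) -> "TargetTermSet":
        return cls.from_tissue_map(DEFAULT_HPO_TARGETS)

    def tissue_of(self, term: str) -> str:
        return self.tissue_map[term]


UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"
ASSIGNED = "assigned"


@dataclass(frozen=True)
class TargetAssignment:
    status: str  # assigned | unassigned | ambiguous
    target: Optional[str] = None
    scores: Mapping[str, float] = field(default_factory=dict)


@dataclass
class PatientRecord:
    """A deletion carrier: propagated phenotype terms plus the deletion interval."""

    patient_id: str
    terms: FrozenSet[str]  # propagated annotation set
    deletion: GenomicInterval
    assignment: Optional[TargetAssignment] = None

    @property
    def target(self) -> Optional[str]:
        if self.assignment is not None and self.assignment.status == ASSIGNED:
            return self.assignment.target
        return None


def assign_target_term(
    annot_j: FrozenSet[str],
    targets: TargetTermSet,
    ic_patients: ICTable,
    dag: OntologyDAG,
) -> TargetAssignment:
    """Assign a patient to the target term with maximal summed IC overlap.

    For each target T_i, S_ij = desc(T_i) & annot_j; the score is the sum of
    IC over S_ij.  Returns ``unassigned`` when every S_ij is empty and
    ``ambiguous`` when the maximum is not unique.

    ``annot_j`` must be ancestor-closed (propagated); otherwise an error is
    raised, since subtree membership tests rely on the closure.
    """
    if not dag.is_ancestor_closed(frozenset(annot_j)):
        raise ValueError("patient annotations must be propagated (ancestor-closed)")
    scores: Dict[str, float] = {}
    nonempty: Dict[str, bool] = {}
    for T in targets.targets:
        s_ij = dag.descendants(T) & annot_j
        nonempty[T] = bool(s_ij)
        scores[T] = sum(ic_patients.get(t, 0.0) for t in s_ij)
    candidates = [T for T in targets.targets if nonempty[T]]
    if not candidates:
        return TargetAssignment(UNASSIGNED, None, scores)
    best = max(scores[T] for T in candidates)
    winners = [T for T in candidates if scores[T] == best]
    if len(winners) > 1:
        return TargetAssignment(AMBIGUOUS, None, scores)
    return TargetAssignment(ASSIGNED, winners[0], scores)


def common_ancestors(
    dag: OntologyDAG, t_g: str, annot_j: Iterable[str]
) -> FrozenSet[str]:
    """anc(annot_j) & anc(t_g); contains the root whenever annot_j is non-empty."""
    return dag.ancestors_of_set(annot_j) & dag.ancestors(t_g)


def phenomatch_score(
    gene_terms: Iterable[str],
    annot_j: FrozenSet[str],
    ic_corpus: ICTable,
    dag: OntologyDAG,
) -> float:
    """Sum over the gene's direct terms of the best common-ancestor IC.

    Terms with no corpus IC contribute nothing to the maxima; an empty gene
    term set scores 0.
    """
    anc_annot = dag.ancestors_of_set(annot_j)
    total = 0.0
    for t_g in gene_terms:
        best = 0.0
        for t in dag.ancestors(t_g):
            if t in anc_annot:
                ic = ic_corpus.get(t)
                if ic is not None and ic > best:
                    best = ic
        total += best
    return total


def phenogram_score(
    gene_term_sets: Iterable[Iterable[str]],
    annot_j: FrozenSet[str],
    ic_corpus: ICTable,
    dag: OntologyDAG,
) -> float:
    """Maximum phenomatch score over genes; 0 for an empty gene list."""
    best = 0.0
    for terms in gene_term_sets:
        s = phenomatch_score(terms, annot_j, ic_corpus, dag)
        if s > best:
            best = s
    return best


@dataclass(frozen=True)
class RandomPlacementReport:
    real_scores: np.ndarray
    random_scores: np.ndarray
    real_mean: float
    real_sd: float
    random_mean: float
    random_sd: float
    statistic: float
    p_value: float
    n_placements: int


def score_vs_random_placement(
    patients: Sequence[PatientRecord],
    genes: Sequence[GeneRecord],
    gene_terms: Mapping[str, FrozenSet[str]],
    chrom_lengths: Mapping[str, int],
    ic_corpus: ICTable,
    dag: OntologyDAG,
    n_placements: int = 100,
    seed: Optional[int] = None,
) -> RandomPlacementReport:
    """Compare within-deletion phenogram scores against length-preserving
    random placements with a two-sided rank-sum test.

    Each patient's deletion is placed ``n_placements`` times uniformly at
    random on the genome and re-scored against the same patient's terms.
    """
    if n_placements < 1:
        raise ValueError("n_placements must be >= 1")
    rng = np.random.default_rng(seed)

    def _region_score(region: GenomicInterval, annot: FrozenSet[str]) -> float:
        sets = [
            gene_terms.get(g.gene_id, frozenset())
            for g in genes
            if g.interval.chrom == region.chrom
            and g.interval.start < region.end
            and region.start < g.interval.end
        ]
        return phenogram_score(sets, annot, ic_corpus, dag)

    real = np.array(
        [_region_score(p.deletion, p.terms) for p in patients], dtype=float
    )
    lengths = [len(p.deletion) for p in patients]
    rand_scores: List[float] = []
    placements = random_placement(lengths, chrom_lengths, n_placements, rng=rng)
    for rep in placements:
        for p, iv in zip(patients, rep):
            rand_scores.append(_region_score(iv, p.terms))
    rand = np.array(rand_scores, dtype=float)

    combined = np.concatenate([real, rand])
    if combined.size == 0 or np.all(combined == combined[0]):
        # degenerate: identical distributions, no evidence either way
        stat, pval = float(len(real) * len(rand) / 2.0), 1.0
    else:
        res = stats.mannwhitneyu(real, rand, alternative="two-sided")
        stat, pval = float(res.statistic), float(res.pvalue)
    return RandomPlacementReport(
        real_scores=real,
        random_scores=rand,
        real_mean=float(real.mean()) if real.size else 0.0,
        real_sd=float(real.std(ddof=1)) if real.size > 1 else 0.0,
        random_mean=float(rand.mean()) if rand.size else 0.0,
        random_sd=float(rand.std(ddof=1)) if rand.size > 1 else 0.0,
        statistic=stat,
        p_value=pval,
        n_placements=n_placements,
    )
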