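"""Per-deletion mechanism calls: boundary disruption, gene dosage, mixed, or
unexplained.

A deletion shows boundary-disruption (TDBD) evidence when it completely
contains at least one domain boundary and, in the regions adjacent to the
deletion, an enhancer specific to the patient's target tissue lies on one
side while a gene annotated to the target term (or a descendant) lies on the
other.  Gene-dosage (GDE) evidence is a positive phenogram score over the
genes inside the deletion.  The category lattice then splits TDBD-only from
mixed TDBD+GDE by comparing the adjacent and within phenogram scores.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .genome import (
    AdjacencyPair,
    GenomeArchitecture,
    GenomicInterval,
    adjacent_regions,
    complete_overlap,
    flanking_windows,
)
from .ontology import AnnotationTable, ICTable, OntologyDAG
from .phenomatch import (
    ASSIGNED,
    PatientRecord,
    TargetTermSet,
    phenogram_score,
)

__all__ = [
    "CATEGORIES",
    "MechanismCall",
    "tdbd_evidence",
    "gde_evidence",
    "classify_deletion",
    "classify_patient",
    "classify_cohort",
    "no_boundary_enhancer_adoption",
    "cohort_summary",
]

TDBD_ONLY = "TDBD_only"
TDBD_GDE = "TDBD_GDE"
GDE = "GDE"
UNEXPLAINED = "unexplained"
NOT_ASSESSED = "not_assessed"
CATEGORIES = (TDBD_ONLY, TDBD_GDE, GDE, UNEXPLAINED, NOT_ASSESSED)


@dataclass
class MechanismCall:
    patient_id: str
    category: str
    tdbd_evidence: bool
    gde_evidence: bool
    s_within: float
    s_adjacent: float
    supporting: Dict[str, object] = field(default_factory=dict)


def _genes_with_target(
    gene_ids: Sequence[str],
    target: str,
    gene_annotations: AnnotationTable,
) -> List[str]:
    """Genes whose propagated term set contains the target term (i.e. genes
    annotated to the target or one of its descendants)."""
    assert gene_annotations.propagated is not None
    out = []
    for g in gene_ids:
        terms = gene_annotations.propagated.get(g)
        if terms and target in terms:
            out.append(g)
    return out


def _signature_on_sides(
    target: str,
    tissue: str,
    left: Optional[GenomicInterval],
    right: Optional[GenomicInterval],
    architecture: GenomeArchitecture,
    gene_annotations: AnnotationTable,
) -> Tuple[bool, Dict[str, object]]:
    """Opposite-side enhancer/gene signature within the two given regions."""
    enh_left = architecture.enhancers_in(tissue, left)
    enh_right = architecture.enhancers_in(tissue, right)
    genes_left = _genes_with_target(
        [g.gene_id for g in architecture.genes_in(left)], target, gene_annotations
    )
    genes_right = _genes_with_target(
        [g.gene_id for g in architecture.genes_in(right)], target, gene_annotations
    )
    if enh_left and genes_right:
        return True, {
            "enhancer_side": "left",
            "enhancer": enh_left[0],
            "gene_id": genes_right[0],
        }
    if enh_right and genes_left:
        return True, {
            "enhancer_side": "right",
            "enhancer": enh_right[0],
            "gene_id": genes_left[0],
        }
    return False, {}


def tdbd_evidence(
    deletion: GenomicInterval,
    target: str,
    architecture: GenomeArchitecture,
    gene_annotations: AnnotationTable,
    targets: TargetTermSet,
    adjacency: Optional[AdjacencyPair] = None,
) -> Tuple[bool, Dict[str, object]]:
    """Boundary-disruption evidence for a patient assigned to ``target``.

    Requires (a) complete overlap of at least one boundary, (b) a
    target-tissue enhancer in one adjacent region and (c) a gene annotated to
    the target (or a descendant) in the other; both orientations are checked.
    """
    contained = [b for b in architecture.boundaries if complete_overlap(deletion, b)]
    if not contained:
        return False, {}
    if adjacency is None:
        adjacency = adjacent_regions(deletion, architecture)
    tissue = targets.tissue_of(target)
    ok, detail = _signature_on_sides(
        target, tissue, adjacency.left, adjacency.right, architecture, gene_annotations
    )
    if ok:
        detail["boundaries"] = contained
    return ok, detail


def gde_evidence(
    deletion: GenomicInterval,
    annot_j: FrozenSet[str],
    architecture: GenomeArchitecture,
    gene_annotations: AnnotationTable,
    ic_corpus: ICTable,
    dag: OntologyDAG,
) -> bool:
    """True iff the phenogram score over genes within the deletion is > 0."""
    return _within_score(deletion, annot_j, architecture, gene_annotations, ic_corpus, dag) > 0


def _within_score(deletion, annot_j, architecture, gene_annotations, ic_corpus, dag):
    sets = [
        gene_annotations.direct.get(g.gene_id, frozenset())
        for g in architecture.genes_within_deletion(deletion)
    ]
    return phenogram_score(sets, annot_j, ic_corpus, dag)


def _adjacent_score(adjacency, annot_j, architecture, gene_annotations, ic_corpus, dag):
    sets = [
        gene_annotations.direct.get(g.gene_id, frozenset())
        for region in (adjacency.left, adjacency.right)
        for g in architecture.genes_in(region)
    ]
    return phenogram_score(sets, annot_j, ic_corpus, dag)


def classify_deletion(
    tdbd: bool, gde: bool, s_within: float, s_adjacent: float
) -> str:
    """Category lattice.

    TDBD evidence with a strictly higher adjacent score gives TDBD_only;
    TDBD evidence with gene-dosage evidence and s_adjacent <= s_within gives
    the mixed call; TDBD evidence alone (vacuous within score) stays
    TDBD_only; gene-dosage evidence without TDBD gives GDE; otherwise the
    deletion is unexplained.
    """
    if tdbd:
        if s_adjacent > s_within:
            return TDBD_ONLY
        if gde:
            return TDBD_GDE
        return TDBD_ONLY
    if gde:
        return GDE
    return UNEXPLAINED


def classify_patient(
    patient: PatientRecord,
    architecture: GenomeArchitecture,
    gene_annotations: AnnotationTable,
    targets: TargetTermSet,
    ic_genes: ICTable,
    dag: OntologyDAG,
) -> MechanismCall:
    """Full mechanism call for one patient; unassigned patients are not assessed."""
    if patient.assignment is None or patient.assignment.status != ASSIGNED:
        return MechanismCall(
            patient.patient_id, NOT_ASSESSED, False, False, 0.0, 0.0,
            {"status": patient.assignment.status if patient.assignment else "unassigned"},
        )
    target = patient.assignment.target
    adjacency = adjacent_regions(patient.deletion, architecture)
    tdbd, detail = tdbd_evidence(
        patient.deletion, target, architecture, gene_annotations, targets, adjacency
    )
    s_within = _within_score(
        patient.deletion, patient.terms, architecture, gene_annotations, ic_genes, dag
    )
    s_adjacent = _adjacent_score(
        adjacency, patient.terms, architecture, gene_annotations, ic_genes, dag
    )
    gde = s_within > 0
    category = classify_deletion(tdbd, gde, s_within, s_adjacent)
    detail["target"] = target
    return MechanismCall(
        patient.patient_id, category, tdbd, gde, s_within, s_adjacent, detail
    )


def classify_cohort(
    patients: Sequence[PatientRecord],
    architecture: GenomeArchitecture,
    gene_annotations: AnnotationTable,
    targets: TargetTermSet,
    ic_genes: ICTable,
    dag: OntologyDAG,
) -> List[MechanismCall]:
    return [
        classify_patient(p, architecture, gene_annotations, targets, ic_genes, dag)
        for p in patients
    ]


def no_boundary_enhancer_adoption(
    deletion: GenomicInterval,
    target: str,
    architecture: GenomeArchitecture,
    gene_annotations: AnnotationTable,
    targets: TargetTermSet,
    flank_width: int = 400_000,
) -> bool:
    """Enhancer-adoption signature in fixed flanks for boundary-free deletions.

    Raises if the deletion completely overlaps any boundary: those deletions
    belong to the TDBD analysis, not this control.
    """
    if any(complete_overlap(deletion, b) for b in architecture.boundaries):
        raise ValueError(
            "no_boundary_enhancer_adoption applies only to deletions that "
            "overlap no boundary completely"
        )
    flanks = flanking_windows(deletion, architecture.chrom_lengths, flank_width)
    tissue = targets.tissue_of(target)
    ok, _ = _signature_on_sides(
        target, tissue, flanks.left, flanks.right, architecture, gene_annotations
    )
    return ok


def cohort_summary(calls: Sequence[MechanismCall]) -> Dict[str, object]:
    """Category counts plus fractions over assessed patients."""
    counts = Counter(c.category for c in calls)
    assessed = sum(n for cat, n in counts.items() if cat != NOT_ASSESSED)
    fractions = {
        cat: (counts.get(cat, 0) / assessed if assessed else 0.0)
        for cat in CATEGORIES
        if cat != NOT_ASSESSED
    }
    return {
        "n_patients": len(calls),
        "n_assessed": assessed,
        "counts": {cat: counts.get(cat, 0) for cat in CATEGORIES},
        "fractions": fractions,
    }
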