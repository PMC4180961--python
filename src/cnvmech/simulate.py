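"""Synthetic input generator with planted ground truth.

Produces every input the pipeline consumes: a rooted ontology with ten
disjoint target-term branches, gene and patient annotation tables, a genome
of domains separated by boundary gaps, tissue-labeled enhancers, deletions
with planted mechanisms (boundary disruption, gene dosage, mixed, benign)
and DNase window count matrices with planted tissue-specific windows.

The genome is laid out as a chain of per-patient "slots" separated by
spacer gaps larger than the boundary cap (so slots never interact):

* a boundary-disruption slot is two domains around a <=400-kb gap, with a
  tissue enhancer in the outer part of the left domain and a gene annotated
  to the tissue's target term in the outer part of the right domain; the
  deletion runs from the middle of the left domain to the middle of the
  right one, covering exactly the slot's boundary and no annotated gene;
* a mixed slot additionally carries a second gene, with an identical term
  set, inside the deleted part of the left domain;
* a gene-dosage slot is a single domain whose central annotated gene is
  covered by the deletion;
* a benign slot is a single domain with a small central deletion and no
  genes or boundaries in reach.

Mechanism counts follow the configured mixture exactly (largest-remainder
allocation), so noiseless recovery tests are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .dhs import TissueDesign, WindowCountMatrix
from .genome import GenomeArchitecture, GenomicInterval, GeneRecord
from .ontology import AnnotationTable, OntologyDAG, propagate
from .phenomatch import PatientRecord, TargetTermSet

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "generate_ontology",
    "generate_gene_annotations",
    "generate_architecture",
    "generate_cohort",
    "generate_count_matrix",
    "generate_dataset",
]

MECHANISMS = ("TDBD", "TDBD_GDE", "GDE", "benign")

#: planted mechanism -> category the classifier should produce at zero noise
EXPECTED_CATEGORY = {
    "TDBD": "TDBD_only",
    "TDBD_GDE": "TDBD_GDE",
    "GDE": "GDE",
    "benign": "unexplained",
}


@dataclass
class SimulationConfig:
    seed: int = 0
    # ontology shape
    n_target_branches: int = 10
    branch_depth: int = 3
    branching_factor: int = 2
    # gene annotations
    n_genes: int = 320
    frac_unannotated: float = 0.2
    max_terms_per_gene: int = 5
    # genome architecture
    domain_min: int = 300_000
    domain_max: int = 1_000_000
    boundary_gap_min: int = 50_000
    boundary_gap_max: int = 400_000
    spacer: int = 500_000
    slots_per_chrom: int = 50
    gene_width: int = 10_000
    enhancer_width: int = 1_000
    # cohort
    n_patients: int = 200
    mixture: Dict[str, float] = field(
        default_factory=lambda: {"TDBD": 0.1, "TDBD_GDE": 0.2, "GDE": 0.6, "benign": 0.1}
    )
    noise: float = 0.0
    max_terms_per_patient: int = 3
    decoy_enhancers_per_slot: int = 0
    decoy_genes_per_slot: int = 0
    # DNase count matrix
    n_windows: int = 10_000
    dhs_tissues: int = 4
    dhs_replicates: int = 4
    background_mean: float = 20.0
    planted_per_tissue: int = 200
    log_effect: float = 2.0
    overdispersion: float = 0.0
    window_width: int = 200

    def __post_init__(self):
        total = sum(self.mixture.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture fractions must sum to 1, got {total}")
        unknown = set(self.mixture) - set(MECHANISMS)
        if unknown:
            raise ValueError(f"unknown mechanisms in mixture: {sorted(unknown)}")
        for name in ("n_target_branches", "n_genes", "n_patients", "n_windows",
                     "dhs_tissues", "dhs_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _largest_remainder(n: int, fractions: Mapping[str, float]) -> Dict[str, int]:
    """Integer allocation matching fractions exactly in expectation and in sum."""
    keys = list(fractions)
    raw = [n * fractions[k] for k in keys]
    base = [int(x) for x in raw]
    rem = n - sum(base)
    order = sorted(range(len(keys)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(keys, base))


# ---------------------------------------------------------------------------
# ontology


def generate_ontology(config: SimulationConfig) -> Tuple[OntologyDAG, TargetTermSet]:
    """Rooted DAG: root -> n_target_branches disjoint full k-ary subtrees.

    Each branch head is a target term; the structure is deterministic for a
    given config (no randomness needed).
    """
    counter = 0

    def new_term() -> str:
        nonlocal counter
        t = f"X:{counter:07d}"
        counter += 1
        return t

    root = new_term()
    edges: List[Tuple[str, str]] = []
    tissue_to_term: Dict[str, str] = {}
    for b in range(config.n_target_branches):
        target = new_term()
        edges.append((target, root))
        tissue_to_term[f"tissue_{b + 1:02d}"] = target
        frontier = [target]
        for _ in range(config.branch_depth):
            nxt = []
            for parent in frontier:
                for _ in range(config.branching_factor):
                    child = new_term()
                    edges.append((child, parent))
                    nxt.append(child)
            frontier = nxt
    dag = OntologyDAG.from_edges(edges)
    return dag, TargetTermSet.from_tissue_map(tissue_to_term)


# ---------------------------------------------------------------------------
# gene annotations


def generate_gene_annotations(
    dag: OntologyDAG,
    targets: TargetTermSet,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[AnnotationTable, List[str]]:
    """Gene -> term table plus the list of unannotated gene ids.

    Annotated genes are assigned to target branches round-robin and receive
    1..max_terms_per_gene terms from strictly below their branch head.
    Consecutive genes within a branch come in twin pairs with identical term
    sets, so mixed-mechanism slots can place two genes with equal scores.
    The unannotated fraction is honored exactly (rounded count).
    """
    n_unann = round(config.frac_unannotated * config.n_genes)
    n_ann = config.n_genes - n_unann
    branch_pools = {
        T: sorted(dag.descendants(T) - {T}) for T in targets.targets
    }
    direct: Dict[str, FrozenSet[str]] = {}
    last_in_branch: Dict[str, FrozenSet[str]] = {}
    branch_counts: Dict[str, int] = {T: 0 for T in targets.targets}
    for i in range(n_ann):
        gid = f"gene{i + 1:04d}"
        T = targets.targets[i % len(targets.targets)]
        if branch_counts[T] % 2 == 1:
            terms = last_in_branch[T]  # twin of the previous gene in this branch
        else:
            pool = branch_pools[T]
            k = int(rng.integers(1, min(config.max_terms_per_gene, len(pool)) + 1))
            terms = frozenset(rng.choice(pool, size=k, replace=False).tolist())
            last_in_branch[T] = terms
        branch_counts[T] += 1
        direct[gid] = terms
    unannotated = [f"gene{i + 1:04d}" for i in range(n_ann, config.n_genes)]
    return AnnotationTable("gene", direct), unannotated


def _branch_of(terms: FrozenSet[str], dag: OntologyDAG, targets: TargetTermSet) -> Optional[str]:
    """The target term whose subtree contains all of the gene's terms."""
    for T in targets.targets:
        if terms and terms <= dag.descendants(T):
            return T
    return None


# ---------------------------------------------------------------------------
# architecture + cohort


@dataclass
class _Slot:
    mechanism: str
    tissue: str
    target: str
    chrom: str
    deletion: Tuple[int, int]
    boundary: Optional[Tuple[int, int]]
    adjacent_gene: Optional[str]
    inner_gene: Optional[str]
    source_gene: Optional[str]


def generate_architecture(
    config: SimulationConfig,
    dag: OntologyDAG,
    targets: TargetTermSet,
    gene_table: AnnotationTable,
    unannotated: Sequence[str],
    rng: np.random.Generator,
) -> GenomeArchitecture:
    """Lay out per-patient slots along synthetic chromosomes.

    The returned architecture carries a ``layout`` attribute (list of slot
    records) consumed by :func:`generate_cohort`.
    """
    counts = _largest_remainder(config.n_patients, config.mixture)
    labels: List[str] = []
    for mech in MECHANISMS:
        labels.extend([mech] * counts.get(mech, 0))
    labels = [labels[i] for i in rng.permutation(len(labels))]

    # per-tissue pools of annotated genes, preserving twin adjacency
    pools: Dict[str, List[str]] = {t: [] for t in targets.tissue_map.values()}
    for gid in sorted(gene_table.direct):
        T = _branch_of(gene_table.direct[gid], dag, targets)
        if T is not None:
            pools[targets.tissue_of(T)].append(gid)
    cursor: Dict[str, int] = {t: 0 for t in pools}
    spare_singles: Dict[str, List[str]] = {t: [] for t in pools}

    def take_gene(tissue: str, twin_pair: bool = False) -> List[str]:
        """Consume one gene (or an aligned twin pair) from a tissue pool.

        Twin pairs occupy even-aligned consecutive pool slots; a single take
        splits a pair and banks the leftover twin for a later single.
        """
        pool = pools[tissue]
        i = cursor[tissue]
        if not twin_pair and spare_singles[tissue]:
            return [spare_singles[tissue].pop()]
        need = 2 if twin_pair else 1
        if i + 2 > len(pool) and (twin_pair or i + 1 > len(pool)):
            raise ValueError(
                f"architecture too small: tissue {tissue!r} gene pool exhausted "
                f"(have {len(pool)}, need more)"
            )
        if twin_pair:
            cursor[tissue] = i + 2
            return pool[i : i + 2]
        cursor[tissue] = i + 2 if i + 1 < len(pool) else i + 1
        if i + 1 < len(pool):
            spare_singles[tissue].append(pool[i + 1])
        return [pool[i]]

    tissues = list(targets.tissue_map.values())
    domains: List[GenomicInterval] = []
    genes: List[GeneRecord] = []
    enhancers: Dict[str, List[GenomicInterval]] = {t: [] for t in tissues}
    layout: List[_Slot] = []
    chrom_lengths: Dict[str, int] = {}

    pos = config.spacer
    chrom_idx = 1
    chrom = f"chr{chrom_idx}"
    gw, ew = config.gene_width, config.enhancer_width
    unann_iter = iter(list(unannotated))

    def dlen() -> int:
        return int(rng.integers(config.domain_min, config.domain_max + 1))

    def place_unannotated(lo: int, hi: int) -> None:
        gid = next(unann_iter, None)
        if gid is not None and hi - lo > gw:
            s = int(rng.integers(lo, hi - gw))
            genes.append(GeneRecord(gid, GenomicInterval(chrom, s, s + gw)))

    # round-robin tissues within each mechanism so gene demand per tissue is
    # balanced regardless of the shuffled mechanism order
    mech_counter: Dict[str, int] = {m: 0 for m in MECHANISMS}
    for i, mech in enumerate(labels):
        if i > 0 and i % config.slots_per_chrom == 0:
            chrom_lengths[chrom] = pos + config.spacer
            chrom_idx += 1
            chrom = f"chr{chrom_idx}"
            pos = config.spacer
        tissue = tissues[mech_counter[mech] % len(tissues)]
        mech_counter[mech] += 1
        target = next(T for T, tl in targets.tissue_map.items() if tl == tissue)

        if mech in ("TDBD", "TDBD_GDE"):
            LA, LB = dlen(), dlen()
            gap = int(rng.integers(config.boundary_gap_min, config.boundary_gap_max + 1))
            a0 = pos
            b0 = a0 + LA + gap
            dom_a = GenomicInterval(chrom, a0, a0 + LA)
            dom_b = GenomicInterval(chrom, b0, b0 + LB)
            domains.extend([dom_a, dom_b])
            del_start = a0 + LA // 2
            del_end = b0 + LB // 2
            # planted enhancer in the left adjacent region
            es = int(rng.integers(a0 + LA // 20, a0 + LA * 35 // 100 - ew))
            enhancers[tissue].append(GenomicInterval(chrom, es, es + ew))
            if mech == "TDBD_GDE":
                adj_gid, inner_gid = take_gene(tissue, twin_pair=True)
            else:
                (adj_gid,), inner_gid = take_gene(tissue), None
            # adjacent target gene in the right adjacent region
            gs = int(rng.integers(b0 + LB * 65 // 100, b0 + LB * 90 // 100 - gw))
            genes.append(GeneRecord(adj_gid, GenomicInterval(chrom, gs, gs + gw)))
            if inner_gid is not None:
                # twin gene inside the deleted part of the left domain
                ws = int(rng.integers(a0 + LA * 60 // 100, a0 + LA * 85 // 100 - gw))
                genes.append(GeneRecord(inner_gid, GenomicInterval(chrom, ws, ws + gw)))
            for _ in range(config.decoy_enhancers_per_slot):
                dt = tissues[int(rng.integers(len(tissues)))]
                side_left = bool(rng.integers(2))
                if side_left:
                    s = int(rng.integers(a0 + LA // 20, a0 + LA * 35 // 100 - ew))
                else:
                    s = int(rng.integers(b0 + LB * 65 // 100, b0 + LB * 95 // 100 - ew))
                enhancers[dt].append(GenomicInterval(chrom, s, s + ew))
            for _ in range(config.decoy_genes_per_slot):
                dt = tissues[int(rng.integers(len(tissues)))]
                (dg,) = take_gene(dt)
                side_left = bool(rng.integers(2))
                if side_left:
                    s = int(rng.integers(a0 + LA // 20, a0 + LA * 40 // 100 - gw))
                else:
                    s = int(rng.integers(b0 + LB * 65 // 100, b0 + LB * 90 // 100 - gw))
                genes.append(GeneRecord(dg, GenomicInterval(chrom, s, s + gw)))
            place_unannotated(a0 + LA // 20, a0 + LA * 40 // 100)
            layout.append(
                _Slot(mech, tissue, target, chrom, (del_start, del_end),
                      (a0 + LA, b0), adj_gid, inner_gid,
                      inner_gid if inner_gid is not None else adj_gid)
            )
            pos = b0 + LB + config.spacer
        elif mech == "GDE":
            LD = dlen()
            d0 = pos
            domains.append(GenomicInterval(chrom, d0, d0 + LD))
            (gid,) = take_gene(tissue)
            mid = d0 + LD // 2
            genes.append(GeneRecord(gid, GenomicInterval(chrom, mid, mid + gw)))
            del_start = mid - 20_000
            del_end = mid + gw + 20_000
            place_unannotated(d0 + LD // 20, d0 + LD * 15 // 100)
            layout.append(
                _Slot(mech, tissue, target, chrom, (del_start, del_end),
                      None, None, None, gid)
            )
            pos = d0 + LD + config.spacer
        else:  # benign
            LD = dlen()
            d0 = pos
            domains.append(GenomicInterval(chrom, d0, d0 + LD))
            mid = d0 + LD // 2
            layout.append(
                _Slot(mech, tissue, target, chrom, (mid - 25_000, mid + 25_000),
                      None, None, None, None)
            )
            pos = d0 + LD + config.spacer
    chrom_lengths[chrom] = pos + config.spacer

    arch = GenomeArchitecture(chrom_lengths, domains, genes, enhancers)
    arch.layout = layout  # type: ignore[attr-defined]
    return arch


def generate_cohort(
    architecture: GenomeArchitecture,
    dag: OntologyDAG,
    gene_table: AnnotationTable,
    targets: TargetTermSet,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[List[PatientRecord], List[Dict[str, object]]]:
    """Patients with planted deletions and phenotypes, plus ground-truth labels.

    Phenotype terms are sampled from the slot's source gene (or a random
    branch for benign slots); with probability ``noise`` each term is replaced
    by a uniformly random non-root ontology term.
    """
    layout = getattr(architecture, "layout", None)
    if layout is None:
        raise ValueError("architecture has no slot layout; use generate_architecture")
    non_root = sorted(dag.terms - {dag.root})
    patients: List[PatientRecord] = []
    truth: List[Dict[str, object]] = []
    for i, slot in enumerate(layout):
        pid = f"P{i + 1:04d}"
        if slot.source_gene is not None:
            pool = sorted(gene_table.direct[slot.source_gene])
        else:
            T = targets.targets[int(rng.integers(len(targets.targets)))]
            pool = sorted(dag.descendants(T) - {T})
        k = int(rng.integers(1, min(config.max_terms_per_patient, len(pool)) + 1))
        terms = list(rng.choice(pool, size=k, replace=False))
        if config.noise > 0:
            terms = [
                non_root[int(rng.integers(len(non_root)))]
                if rng.random() < config.noise
                else t
                for t in terms
            ]
        direct = frozenset(terms)
        propagated = dag.ancestors_of_set(direct)
        deletion = GenomicInterval(slot.chrom, *slot.deletion)
        patients.append(PatientRecord(pid, propagated, deletion))
        truth.append(
            {
                "patient_id": pid,
                "mechanism": slot.mechanism,
                "expected_category": EXPECTED_CATEGORY[slot.mechanism],
                "tissue": slot.tissue,
                "target": slot.target,
                "direct_terms": direct,
            }
        )
    return patients, truth


# ---------------------------------------------------------------------------
# DNase count matrix


def generate_count_matrix(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[WindowCountMatrix, TissueDesign, Dict[str, List[int]]]:
    """Poisson window counts with planted tissue-specific windows.

    Background counts are Poisson with a per-sample depth factor; for tissue
    j's planted windows the mean is multiplied by exp(log_effect) in tissue-j
    samples only.  With ``overdispersion`` > 0, a gamma-distributed rate adds
    negative-binomial noise.  Returns the matrix, the design and the planted
    window indices per tissue.
    """
    W = config.n_windows
    tissues = [f"dnase_tissue_{j + 1:02d}" for j in range(config.dhs_tissues)]
    samples: List[str] = []
    sample_tissue: Dict[str, str] = {}
    for t in tissues:
        for r in range(config.dhs_replicates):
            name = f"{t}_rep{r + 1}"
            samples.append(name)
            sample_tissue[name] = t
    n = len(samples)
    depth = rng.uniform(0.6, 1.6, size=n)
    mean = np.full((W, n), config.background_mean) * depth[None, :]

    perm = rng.permutation(W)
    planted: Dict[str, List[int]] = {}
    off = 0
    for j, t in enumerate(tissues):
        idx = perm[off : off + config.planted_per_tissue]
        off += config.planted_per_tissue
        planted[t] = sorted(int(i) for i in idx)
        cols = [k for k, s in enumerate(samples) if sample_tissue[s] == t]
        mean[np.ix_(idx, cols)] *= math.exp(config.log_effect)

    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        mean = rng.gamma(shape, mean / shape)
    counts = rng.poisson(mean)

    windows = tuple(
        GenomicInterval("chrD", i * config.window_width, (i + 1) * config.window_width)
        for i in range(W)
    )
    matrix = WindowCountMatrix(windows, tuple(samples), counts)
    return matrix, TissueDesign(sample_tissue), planted


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    dag: OntologyDAG
    targets: TargetTermSet
    gene_annotations: AnnotationTable  # propagated
    unannotated_genes: List[str]
    architecture: GenomeArchitecture
    patients: List[PatientRecord]
    truth: List[Dict[str, object]]


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate ontology, annotations, architecture and cohort from one seed."""
    rng = np.random.default_rng(config.seed)
    dag, targets = generate_ontology(config)
    gene_table, unannotated = generate_gene_annotations(dag, targets, config, rng)
    arch = generate_architecture(config, dag, targets, gene_table, unannotated, rng)
    patients, truth = generate_cohort(arch, dag, gene_table, targets, config, rng)
    return SimulatedDataset(
        config=config,
        dag=dag,
        targets=targets,
        gene_annotations=propagate(dag, gene_table),
        unannotated_genes=unannotated,
        architecture=arch,
        patients=patients,
        truth=truth,
    )
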