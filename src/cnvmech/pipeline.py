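"""End-to-end pipeline: read inputs, assign targets, score, classify, summarize.

The pipeline is a pure function of (inputs, config, seed): repeated runs write
byte-identical outputs.  Filtering-step counts (assigned / ambiguous /
unassigned; per-category totals) are logged to stderr and recorded in the
summary.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from . import io as cio
from .classify import MechanismCall, classify_cohort, cohort_summary
from .dhs import call_cts_dhs, log_transform_normalize, tissue_t_statistics
from .genome import GenomeArchitecture, GeneRecord, GenomicInterval
from .ontology import AnnotationTable, information_content, propagate
from .phenomatch import PatientRecord, TargetTermSet, assign_target_term

logger = logging.getLogger("cnvmech")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_simulation_bundle"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    Enhancers come either from a BED4 file (name column = tissue label) or
    from a count matrix + design, ranked per tissue and cut at ``top_n``.
    """

    ontology: str
    gene_annotations: str
    domains: str
    chrom_sizes: str
    genes: str
    cohort: str
    targets: str
    enhancers: Optional[str] = None
    count_matrix: Optional[str] = None
    design: Optional[str] = None
    top_n: int = 20_000
    max_boundary_gap: int = 400_000
    flank_width: int = 400_000
    permutation_reps: int = 10_000
    gene_permutation_reps: int = 1_000
    seed: int = 0
    rate_definition: str = "TDBD_only"  # or "TDBD_or_mixed"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    patients: List[PatientRecord]
    calls: List[MechanismCall]
    summary: Dict[str, object]


def _select_largest(
    rows: Sequence[Tuple[str, GenomicInterval, frozenset]]
) -> List[Tuple[str, GenomicInterval, frozenset]]:
    """Keep only the single largest deletion per patient id."""
    best: Dict[str, Tuple[str, GenomicInterval, frozenset]] = {}
    for row in rows:
        pid, iv, terms = row
        cur = best.get(pid)
        if cur is None or len(iv) > len(cur[1]) or (
            len(iv) == len(cur[1]) and (iv.chrom, iv.start) < (cur[1].chrom, cur[1].start)
        ):
            best[pid] = row
    return [best[p] for p in sorted(best)]


def load_architecture(config: PipelineConfig) -> GenomeArchitecture:
    chrom_lengths = cio.read_chrom_sizes(config.chrom_sizes)
    domains = [iv for iv, _ in cio.read_bed(config.domains)]
    genes = [
        GeneRecord(name or f"gene_{i}", iv)
        for i, (iv, name) in enumerate(cio.read_bed(config.genes, min_fields=4))
    ]
    enhancers: Dict[str, List[GenomicInterval]] = {}
    if config.enhancers:
        for iv, tissue in cio.read_bed(config.enhancers, min_fields=4):
            enhancers.setdefault(tissue, []).append(iv)
    elif config.count_matrix and config.design:
        matrix = cio.read_count_matrix(config.count_matrix)
        design = cio.read_design(config.design)
        X = log_transform_normalize(matrix)
        table = tissue_t_statistics(X, matrix.samples, design)
        top_n = min(config.top_n, len(matrix.windows))
        for tissue in table.tissues:
            enhancers[tissue] = call_cts_dhs(table, matrix.windows, tissue, top_n)
    else:
        raise ValueError("config needs either enhancers or count_matrix + design")
    return GenomeArchitecture(
        chrom_lengths, domains, genes, enhancers, config.max_boundary_gap
    )


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> PipelineResult:
    for name in ("ontology", "gene_annotations", "domains", "chrom_sizes",
                 "genes", "cohort", "targets"):
        p = getattr(config, name)
        if p and not Path(p).exists():
            raise FileNotFoundError(f"missing input {name}: {p}")

    dag = cio.read_ontology(config.ontology)
    targets = cio.read_targets(config.targets)
    gene_table = propagate(dag, cio.read_annotations(config.gene_annotations, "gene"))
    architecture = load_architecture(config)

    raw_rows = cio.read_cohort(config.cohort)
    rows = _select_largest(raw_rows)
    logger.info("cohort: %d records, %d patients after largest-deletion selection",
                len(raw_rows), len(rows))

    patient_direct = AnnotationTable(
        "patient", {pid: terms for pid, _, terms in rows}
    )
    patient_prop = propagate(dag, patient_direct)
    ic_patients = information_content(dag, patient_prop, "patients")
    ic_genes = information_content(dag, gene_table, "genes")

    patients: List[PatientRecord] = []
    status_counts = {"assigned": 0, "ambiguous": 0, "unassigned": 0}
    for pid, iv, _ in rows:
        terms = patient_prop.propagated[pid]
        assignment = assign_target_term(terms, targets, ic_patients, dag)
        status_counts[assignment.status] += 1
        patients.append(PatientRecord(pid, terms, iv, assignment))
    logger.info("target assignment: %s", status_counts)

    calls = classify_cohort(patients, architecture, gene_table, targets, ic_genes, dag)
    summary = cohort_summary(calls)
    summary["n_records"] = len(raw_rows)
    summary["assignment"] = status_counts
    summary["seed"] = config.seed
    logger.info("categories: %s", summary["counts"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(out / "results.tsv", patients, calls)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        cio.write_ic_table(out / "ic_patients.tsv", ic_patients)
        cio.write_ic_table(out / "ic_genes.tsv", ic_genes)
    return PipelineResult(patients, calls, summary)


def write_results(
    path, patients: Sequence[PatientRecord], calls: Sequence[MechanismCall]
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "patient_id\tstatus\ttarget\tcategory\ttdbd_evidence\tgde_evidence"
            "\ts_within\ts_adjacent\tsupport_gene\tenhancer_side\n"
        )
        for p, c in zip(patients, calls):
            status = p.assignment.status if p.assignment else "unassigned"
            target = p.target or "."
            fh.write(
                f"{p.patient_id}\t{status}\t{target}\t{c.category}"
                f"\t{int(c.tdbd_evidence)}\t{int(c.gde_evidence)}"
                f"\t{c.s_within:.6f}\t{c.s_adjacent:.6f}"
                f"\t{c.supporting.get('gene_id', '.')}"
                f"\t{c.supporting.get('enhancer_side', '.')}\n"
            )


def analyze_simulated(dataset) -> PipelineResult:
    """Assign targets and classify an in-memory simulated dataset.

    Convenience for tests and reports: builds the patient-frequency IC corpus
    from the cohort itself and the gene IC corpus from the gene annotations.
    """
    pt = AnnotationTable(
        "patient",
        {p.patient_id: p.terms for p in dataset.patients},
        {p.patient_id: p.terms for p in dataset.patients},
    )
    ic_patients = information_content(dataset.dag, pt, "patients")
    ic_genes = information_content(dataset.dag, dataset.gene_annotations, "genes")
    for p in dataset.patients:
        p.assignment = assign_target_term(
            p.terms, dataset.targets, ic_patients, dataset.dag
        )
    calls = classify_cohort(
        dataset.patients,
        dataset.architecture,
        dataset.gene_annotations,
        dataset.targets,
        ic_genes,
        dataset.dag,
    )
    summary = cohort_summary(calls)
    result = PipelineResult(dataset.patients, calls, summary)
    result.ic_patients = ic_patients  # type: ignore[attr-defined]
    result.ic_genes = ic_genes  # type: ignore[attr-defined]
    return result


def write_simulation_bundle(out_dir, dataset, matrix=None, design=None, truth_extra=True):
    """Write every generated input as plain-text files into ``out_dir``.

    Emits ontology.tsv, gene_annotations.tsv, targets.tsv, domains.bed,
    genes.bed, enhancers.bed, chrom_sizes.tsv, cohort.tsv, truth.tsv and a
    config echo; plus counts.tsv / design.tsv when a count matrix is given.
    """
    from dataclasses import asdict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_ontology_tsv(out / "ontology.tsv", dataset.dag)
    # direct annotations only; propagation is recomputed at load time
    direct_table = AnnotationTable("gene", dict(dataset.gene_annotations.direct))
    cio.write_annotations(out / "gene_annotations.tsv", direct_table)
    cio.write_targets(out / "targets.tsv", dataset.targets)
    arch = dataset.architecture
    cio.write_bed(out / "domains.bed", [(d, None) for d in arch.domains])
    cio.write_bed(out / "genes.bed", [(g.interval, g.gene_id) for g in arch.genes])
    enh_rows = [
        (iv, tissue)
        for tissue in sorted(arch.enhancers)
        for iv in arch.enhancers[tissue]
    ]
    cio.write_bed(out / "enhancers.bed", enh_rows)
    cio.write_chrom_sizes(out / "chrom_sizes.tsv", arch.chrom_lengths)
    truth_by_pid = {t["patient_id"]: t for t in dataset.truth}
    cio.write_cohort(
        out / "cohort.tsv",
        [
            (p.patient_id, p.deletion, truth_by_pid[p.patient_id]["direct_terms"])
            for p in dataset.patients
        ],
    )
    with open(out / "truth.tsv", "w") as fh:
        fh.write("patient_id\tmechanism\texpected_category\ttissue\ttarget\n")
        for t in dataset.truth:
            fh.write(
                f"{t['patient_id']}\t{t['mechanism']}\t{t['expected_category']}"
                f"\t{t['tissue']}\t{t['target']}\n"
            )
    cfg = asdict(dataset.config)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    if matrix is not None:
        cio.write_count_matrix(out / "counts.tsv", matrix)
    if design is not None:
        cio.write_design(out / "design.tsv", design)
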