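"""File readers and writers: BED intervals, ontologies, annotation tables,
cohorts and window count matrices.

All interval I/O is 0-based half-open.  Parsers are strict and report line
numbers on malformed input; writers round-trip readers exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .dhs import TissueDesign, WindowCountMatrix
from .genome import GeneRecord, GenomicInterval
from .ontology import AnnotationTable, ICTable, OntologyDAG
from .phenomatch import PatientRecord, TargetTermSet

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_ontology",
    "write_ontology_tsv",
    "read_annotations",
    "write_annotations",
    "read_targets",
    "write_targets",
    "read_cohort",
    "write_cohort",
    "read_count_matrix",
    "write_count_matrix",
    "read_design",
    "write_design",
    "write_ic_table",
]


class ParseError(ValueError):
    """Malformed input; message includes file and line number."""


def _lines(path) -> Iterable[Tuple[int, List[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_bed(path, min_fields: int = 3) -> List[Tuple[GenomicInterval, Optional[str]]]:
    """BED3/BED4+: returns (interval, name-or-None) per line."""
    out: List[Tuple[GenomicInterval, Optional[str]]] = []
    for lineno, fields in _lines(path):
        if len(fields) < min_fields:
            raise ParseError(f"{path}:{lineno}: expected >= {min_fields} fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as e:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from e
        if not (0 <= start < end):
            raise ParseError(
                f"{path}:{lineno}: invalid interval {fields[0]}:{start}-{end}"
            )
        name = fields[3] if len(fields) > 3 else None
        out.append((GenomicInterval(fields[0], start, end), name))
    return out


def write_bed(path, records: Iterable[Tuple[GenomicInterval, Optional[str]]]) -> None:
    with open(path, "w") as fh:
        for iv, name in records:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if name is not None:
                cols.append(name)
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for lineno, fields in _lines(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields")
        try:
            out[fields[0]] = int(fields[1])
        except ValueError as e:
            raise ParseError(f"{path}:{lineno}: non-integer length") from e
    return out


def write_chrom_sizes(path, sizes: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom in sizes:
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_ontology(path) -> OntologyDAG:
    """OBO subset (id / is_a stanzas only) or two-column TSV (child, parent)."""
    text = Path(path).read_text()
    if "[Term]" in text:
        return _read_obo(text, path)
    edges: List[Tuple[str, str]] = []
    for lineno, fields in _lines(path):
        if fields and fields[0].lower() in ("child_id", "child"):
            continue  # optional header
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected child<TAB>parent")
        edges.append((fields[0], fields[1]))
    return OntologyDAG.from_edges(edges)


def _read_obo(text: str, path) -> OntologyDAG:
    edges: List[Tuple[str, str]] = []
    terms: List[str] = []
    current: Optional[str] = None
    in_term = False
    for line in text.splitlines():
        line = line.strip()
        if line == "[Term]":
            in_term, current = True, None
        elif line.startswith("["):
            in_term = False
        elif in_term and line.startswith("id:"):
            current = line[3:].strip()
            terms.append(current)
        elif in_term and line.startswith("is_a:") and current is not None:
            parent = line[5:].strip().split("!")[0].strip()
            edges.append((current, parent))
    pe: Dict[str, set] = {t: set() for t in terms}
    for child, parent in edges:
        pe.setdefault(child, set()).add(parent)
        pe.setdefault(parent, set())
    return OntologyDAG(pe)


def write_ontology_tsv(path, dag: OntologyDAG) -> None:
    with open(path, "w") as fh:
        for t in sorted(dag.terms):
            for p in sorted(dag.parents[t]):
                fh.write(f"{t}\t{p}\n")


def read_annotations(path, entity_kind: str) -> AnnotationTable:
    """Two-column TSV (entity_id, term_id); header optional."""
    pairs: List[Tuple[str, str]] = []
    for lineno, fields in _lines(path):
        if fields and fields[0].lower() in ("entity_id", "entity", "gene_id", "patient_id"):
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected entity<TAB>term")
        pairs.append((fields[0], fields[1]))
    return AnnotationTable.from_pairs(entity_kind, pairs)


def write_annotations(path, table: AnnotationTable) -> None:
    with open(path, "w") as fh:
        for entity in sorted(table.direct):
            for term in sorted(table.direct[entity]):
                fh.write(f"{entity}\t{term}\n")


def read_targets(path) -> TargetTermSet:
    """TSV tissue_label<TAB>term_id."""
    tissue_to_term: Dict[str, str] = {}
    for lineno, fields in _lines(path):
        if fields and fields[0].lower() in ("tissue", "tissue_label"):
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected tissue<TAB>term")
        tissue_to_term[fields[0]] = fields[1]
    return TargetTermSet.from_tissue_map(tissue_to_term)


def write_targets(path, targets: TargetTermSet) -> None:
    with open(path, "w") as fh:
        for term in targets.targets:
            fh.write(f"{targets.tissue_of(term)}\t{term}\n")


def read_cohort(path) -> List[Tuple[str, GenomicInterval, FrozenSet[str]]]:
    """Cohort TSV: patient_id, chrom, start, end, pipe-separated term ids.

    Returns raw (patient_id, deletion, direct term set) triples; propagation
    and largest-deletion selection happen downstream.
    """
    out: List[Tuple[str, GenomicInterval, FrozenSet[str]]] = []
    for lineno, fields in _lines(path):
        if fields and fields[0].lower() == "patient_id":
            continue
        if len(fields) < 5:
            raise ParseError(
                f"{path}:{lineno}: expected patient_id, chrom, start, end, terms"
            )
        try:
            start, end = int(fields[2]), int(fields[3])
        except ValueError as e:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from e
        if not (0 <= start < end):
            raise ParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
        terms = frozenset(t for t in fields[4].split("|") if t)
        out.append((fields[0], GenomicInterval(fields[1], start, end), terms))
    return out


def write_cohort(
    path, rows: Iterable[Tuple[str, GenomicInterval, Iterable[str]]]
) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tchrom\tstart\tend\tterms\n")
        for pid, iv, terms in rows:
            fh.write(
                f"{pid}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                + "|".join(sorted(terms))
                + "\n"
            )


def read_count_matrix(path) -> WindowCountMatrix:
    """TSV: chrom, start, end, then one integer column per sample (with header)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chrom", "start", "end"]:
            raise ParseError(f"{path}:1: header must start with chrom, start, end")
        samples = tuple(header[3:])
        windows: List[GenomicInterval] = []
        rows: List[List[int]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: field count mismatch")
            try:
                windows.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
                rows.append([int(x) for x in fields[3:]])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return WindowCountMatrix(
        tuple(windows), samples, np.array(rows, dtype=np.int64)
    )


def write_count_matrix(path, matrix: WindowCountMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\t" + "\t".join(matrix.samples) + "\n")
        for i, w in enumerate(matrix.windows):
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t"
                + "\t".join(str(int(c)) for c in matrix.counts[i])
                + "\n"
            )


def read_design(path) -> TissueDesign:
    mapping: Dict[str, str] = {}
    for lineno, fields in _lines(path):
        if fields and fields[0].lower() == "sample_id":
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected sample<TAB>tissue")
        mapping[fields[0]] = fields[1]
    return TissueDesign(mapping)


def write_design(path, design: TissueDesign) -> None:
    with open(path, "w") as fh:
        for sample, tissue in design.sample_to_tissue.items():
            fh.write(f"{sample}\t{tissue}\n")


def write_ic_table(path, ic: ICTable) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tfrequency\tic\n")
        for t in sorted(ic.ic):
            fh.write(f"{t}\t{ic.frequencies[t]:.10g}\t{ic.ic[t]:.10g}\n")
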