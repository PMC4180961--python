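"""Interval model of domains, boundaries, genes, enhancers and deletions.

All coordinates are 0-based half-open (BED convention).  A boundary is a
maximal gap of positive length, at most ``MAX_BOUNDARY_GAP`` bp, between two
consecutive topological domains on the same chromosome; larger gaps are
treated as unorganized chromatin and chromosome ends never form boundaries.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MAX_BOUNDARY_GAP",
    "GenomicInterval",
    "GeneRecord",
    "AdjacencyPair",
    "GenomeArchitecture",
    "derive_boundaries",
    "complete_overlap",
    "overlaps",
    "adjacent_regions",
    "flanking_windows",
    "count_complete_overlaps",
    "random_placement",
]

MAX_BOUNDARY_GAP = 400_000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene with genomic coordinates; phenotype terms live in an AnnotationTable."""

    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class AdjacencyPair:
    """Regions adjacent to a deletion, one per side; ``None`` means empty.

    ``provenance`` per side records whether the region ends at the containing
    domain boundary ("domain-bounded") or at a fixed-width fallback flank
    ("400kb-fallback") because the breakpoint fell outside any domain.
    """

    left: Optional[GenomicInterval]
    right: Optional[GenomicInterval]
    left_provenance: str = "domain-bounded"
    right_provenance: str = "domain-bounded"


def overlaps(a: Optional[GenomicInterval], b: Optional[GenomicInterval]) -> bool:
    """True iff the two intervals share >= 1 bp."""
    if a is None or b is None or a.chrom != b.chrom:
        return False
    return a.start < b.end and b.start < a.end


def complete_overlap(deletion: GenomicInterval, feature: GenomicInterval) -> bool:
    """True iff the deletion fully contains the feature (shared endpoints count)."""
    if deletion.chrom != feature.chrom:
        return False
    return deletion.start <= feature.start and feature.end <= deletion.end


def _sorted_nonoverlapping(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    out = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    for a, b in zip(out, out[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping domains: {a} and {b}")
    return out


def derive_boundaries(
    domains: Sequence[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    max_gap: int = MAX_BOUNDARY_GAP,
) -> List[GenomicInterval]:
    """Boundaries are inter-domain gaps of length in (0, max_gap].

    Chromosome ends and zero-length gaps are never boundaries; gaps larger
    than ``max_gap`` are unorganized chromatin and are excluded.
    """
    out: List[GenomicInterval] = []
    srt = _sorted_nonoverlapping(domains)
    for a, b in zip(srt, srt[1:]):
        if a.chrom != b.chrom:
            continue
        gap = b.start - a.end
        if 0 < gap <= max_gap:
            out.append(GenomicInterval(a.chrom, a.end, b.start))
    return out


class GenomeArchitecture:
    """Chromosomes, domains, derived boundaries, genes and tissue enhancers."""

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        domains: Sequence[GenomicInterval],
        genes: Sequence[GeneRecord] = (),
        enhancers: Optional[Mapping[str, Sequence[GenomicInterval]]] = None,
        max_boundary_gap: int = MAX_BOUNDARY_GAP,
    ):
        self.chrom_lengths: Dict[str, int] = dict(chrom_lengths)
        self.domains: List[GenomicInterval] = _sorted_nonoverlapping(domains)
        for d in self.domains:
            if d.chrom not in self.chrom_lengths:
                raise ValueError(f"domain on unknown chromosome {d.chrom!r}")
            if d.end > self.chrom_lengths[d.chrom]:
                raise ValueError(f"domain {d} exceeds chromosome length")
        self.max_boundary_gap = max_boundary_gap
        self.boundaries: List[GenomicInterval] = derive_boundaries(
            self.domains, self.chrom_lengths, max_boundary_gap
        )
        self.genes: List[GeneRecord] = list(genes)
        self.enhancers: Dict[str, List[GenomicInterval]] = {
            tissue: sorted(ivs, key=lambda iv: (iv.chrom, iv.start))
            for tissue, ivs in (enhancers or {}).items()
        }
        # per-chromosome domain index for breakpoint lookup
        self._dom_by_chrom: Dict[str, List[GenomicInterval]] = {}
        for d in self.domains:
            self._dom_by_chrom.setdefault(d.chrom, []).append(d)
        self._dom_starts = {
            c: [d.start for d in ds] for c, ds in self._dom_by_chrom.items()
        }

    def domain_at(self, chrom: str, pos: int) -> Optional[GenomicInterval]:
        """The domain containing position ``pos`` (half-open), or None."""
        ds = self._dom_by_chrom.get(chrom)
        if not ds:
            return None
        i = bisect.bisect_right(self._dom_starts[chrom], pos) - 1
        if i >= 0 and ds[i].start <= pos < ds[i].end:
            return ds[i]
        return None

    def genes_in(self, region: Optional[GenomicInterval]) -> List[GeneRecord]:
        """Genes overlapping the region by >= 1 bp."""
        if region is None:
            return []
        return [g for g in self.genes if overlaps(g.interval, region)]

    def genes_within_deletion(self, deletion: GenomicInterval) -> List[GeneRecord]:
        return self.genes_in(deletion)

    def enhancers_in(
        self, tissue: str, region: Optional[GenomicInterval]
    ) -> List[GenomicInterval]:
        if region is None:
            return []
        return [e for e in self.enhancers.get(tissue, []) if overlaps(e, region)]


def _clip(chrom: str, start: int, end: int, chrom_len: int) -> Optional[GenomicInterval]:
    start = max(0, start)
    end = min(end, chrom_len)
    if start >= end:
        return None
    return GenomicInterval(chrom, start, end)


def adjacent_regions(
    deletion: GenomicInterval,
    architecture: GenomeArchitecture,
    fallback_width: int = MAX_BOUNDARY_GAP,
) -> AdjacencyPair:
    """Regions from each deletion end to the distal end of the containing domain.

    A breakpoint outside any domain falls back to a fixed-width flank clipped
    to the chromosome, with provenance recorded per side.
    """
    chrom = deletion.chrom
    if chrom not in architecture.chrom_lengths:
        raise ValueError(f"deletion on unknown chromosome {chrom!r}")
    clen = architecture.chrom_lengths[chrom]

    left_dom = architecture.domain_at(chrom, deletion.start)
    if left_dom is not None:
        left = _clip(chrom, left_dom.start, deletion.start, clen)
        left_prov = "domain-bounded"
    else:
        left = _clip(chrom, deletion.start - fallback_width, deletion.start, clen)
        left_prov = "400kb-fallback"

    # the right breakpoint position is deletion.end (first base after the deletion)
    right_dom = architecture.domain_at(chrom, deletion.end)
    if right_dom is not None:
        right = _clip(chrom, deletion.end, right_dom.end, clen)
        right_prov = "domain-bounded"
    else:
        right = _clip(chrom, deletion.end, deletion.end + fallback_width, clen)
        right_prov = "400kb-fallback"
    return AdjacencyPair(left, right, left_prov, right_prov)


def flanking_windows(
    deletion: GenomicInterval,
    chrom_lengths: Mapping[str, int],
    width: int = MAX_BOUNDARY_GAP,
) -> AdjacencyPair:
    """Fixed-width flanks on both sides of a deletion, clipped to the chromosome."""
    if width <= 0:
        raise ValueError("flank width must be positive")
    clen = chrom_lengths[deletion.chrom]
    left = _clip(deletion.chrom, deletion.start - width, deletion.start, clen)
    right = _clip(deletion.chrom, deletion.end, deletion.end + width, clen)
    return AdjacencyPair(left, right, "400kb-fallback", "400kb-fallback")


def count_complete_overlaps(
    deletions: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> Tuple[List[int], float]:
    """Per-deletion counts of completely contained features, plus the fraction
    of deletions containing at least one."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    counts = []
    for d in deletions:
        n = sum(1 for f in by_chrom.get(d.chrom, ()) if complete_overlap(d, f))
        counts.append(n)
    frac = (sum(1 for n in counts if n > 0) / len(counts)) if counts else 0.0
    return counts, frac


def random_placement(
    deletion_lengths: Sequence[int],
    chrom_lengths: Mapping[str, int],
    n_reps: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[List[GenomicInterval]]:
    """Place each deletion uniformly at random on the genome, length-preserving.

    A placement is uniform over all valid (chrom, start) pairs: chromosome
    chosen with probability proportional to ``chrom_length - L + 1`` over
    chromosomes that can hold the deletion, then a uniform valid start.
    Deterministic for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    out: List[List[GenomicInterval]] = []
    for _ in range(n_reps):
        rep: List[GenomicInterval] = []
        for L in deletion_lengths:
            valid = lens - L + 1
            valid = np.where(valid > 0, valid, 0)
            total = int(valid.sum())
            if total == 0:
                raise ValueError(f"deletion of length {L} fits on no chromosome")
            ci = rng.choice(len(chroms), p=valid / total)
            start = int(rng.integers(0, valid[ci]))
            rep.append(GenomicInterval(chroms[ci], start, start + L))
        out.append(rep)
    return out
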