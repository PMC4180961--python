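"""Tissue-specific DNase-hypersensitivity ranking from window count matrices.

Counts in fixed-width windows are log-transformed (natural log of count plus
a pseudocount of one) and depth-normalized; per window, tissue means are
compared to the grand mean of tissue means, weighted by the pooled
within-tissue standard deviation regularized by its genome-wide mean, giving
a moderated t-statistic per tissue.  Top-ranked windows per tissue serve as
tissue-specific enhancer proxies; ranking by the grand mean gives the
ubiquitous control set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genome import GenomicInterval

__all__ = [
    "WindowCountMatrix",
    "TissueDesign",
    "SpecificityTable",
    "apply_window_blacklist",
    "log_transform_normalize",
    "pooled_within_tissue_sd",
    "tissue_t_statistics",
    "call_cts_dhs",
    "ubiquitous_ranking",
    "split_half_reproducibility",
    "sample_distance_matrix",
]


@dataclass(frozen=True)
class WindowCountMatrix:
    """Read counts per fixed-width genomic window (rows) per sample (columns)."""

    windows: Tuple[GenomicInterval, ...]
    samples: Tuple[str, ...]
    counts: np.ndarray  # shape (n_windows, n_samples)

    def __post_init__(self):
        if self.counts.shape != (len(self.windows), len(self.samples)):
            raise ValueError("counts shape does not match windows x samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        widths = {len(w) for w in self.windows}
        if len(widths) > 1:
            raise ValueError(f"windows must have a single fixed width, got {widths}")

    def subset_samples(self, keep: Sequence[str]) -> "WindowCountMatrix":
        idx = [self.samples.index(s) for s in keep]
        return WindowCountMatrix(self.windows, tuple(keep), self.counts[:, idx])


@dataclass(frozen=True)
class TissueDesign:
    """Sample -> tissue assignment; each sample belongs to exactly one tissue."""

    sample_to_tissue: Mapping[str, str]

    @property
    def tissues(self) -> List[str]:
        seen: List[str] = []
        for t in self.sample_to_tissue.values():
            if t not in seen:
                seen.append(t)
        return seen

    def groups(self, samples: Sequence[str]) -> Dict[str, List[int]]:
        """Tissue -> column indices, in tissue order of first appearance."""
        out: Dict[str, List[int]] = {t: [] for t in self.tissues}
        for i, s in enumerate(samples):
            if s not in self.sample_to_tissue:
                raise ValueError(f"sample {s!r} missing from design")
            out[self.sample_to_tissue[s]].append(i)
        return {t: idx for t, idx in out.items() if idx}


@dataclass(frozen=True)
class SpecificityTable:
    tissues: Tuple[str, ...]
    tissue_means: np.ndarray  # (n_windows, m)
    grand_mean: np.ndarray  # (n_windows,) unweighted mean of tissue means
    pooled_sd: np.ndarray  # (n_windows,)
    s0: float
    t_stats: np.ndarray  # (n_windows, m)

    def ranking(self, tissue: str) -> np.ndarray:
        """Window indices by decreasing t for the tissue; ties by genomic order."""
        j = self.tissues.index(tissue)
        return np.argsort(-self.t_stats[:, j], kind="stable")

    def ubiquitous_order(self) -> np.ndarray:
        return np.argsort(-self.grand_mean, kind="stable")


def apply_window_blacklist(
    raw: WindowCountMatrix, blacklist: Sequence[GenomicInterval]
) -> WindowCountMatrix:
    """Drop windows overlapping any blacklist interval (>= 1 bp).

    Models upstream repeat filtering; the repeat-annotation source itself is
    out of scope, so the blacklist arrives as plain intervals.
    """
    from .genome import overlaps as _overlaps

    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for b in blacklist:
        by_chrom.setdefault(b.chrom, []).append(b)
    keep = [
        i
        for i, w in enumerate(raw.windows)
        if not any(_overlaps(w, b) for b in by_chrom.get(w.chrom, ()))
    ]
    return WindowCountMatrix(
        tuple(raw.windows[i] for i in keep), raw.samples, raw.counts[keep, :]
    )


def log_transform_normalize(
    raw: WindowCountMatrix, scale_before_log: bool = False
) -> np.ndarray:
    """ln(count + 1), depth-normalized.

    The depth factor of a sample is the grand mean raw count over all samples
    divided by that sample's mean raw count.  By default the factor multiplies
    the log-transformed values; ``scale_before_log=True`` instead scales the
    raw counts before the log transform.
    """
    if raw.counts.size == 0:
        raise ValueError("empty count matrix")
    counts = raw.counts.astype(float)
    sample_means = counts.mean(axis=0)
    if np.any(sample_means == 0):
        bad = [s for s, m in zip(raw.samples, sample_means) if m == 0]
        raise ValueError(f"samples with all-zero counts: {bad}")
    grand = counts.mean()
    factors = grand / sample_means
    if scale_before_log:
        return np.log1p(counts * factors[None, :])
    return np.log1p(counts) * factors[None, :]


def pooled_within_tissue_sd(
    X: np.ndarray,
    groups: Mapping[str, Sequence[int]],
    allow_singletons: bool = False,
) -> np.ndarray:
    """Per-window pooled within-tissue standard deviation.

    s = sqrt( sum_j sum_{i in C_j} (X_i - Xbar_j)^2 / sum_j (n_j - 1) ).
    Tissues with a single sample contribute nothing when ``allow_singletons``;
    otherwise they are an error.
    """
    ss = np.zeros(X.shape[0])
    dof = 0
    for tissue, idx in groups.items():
        n_j = len(idx)
        if n_j < 2:
            if allow_singletons:
                continue
            raise ValueError(
                f"tissue {tissue!r} has {n_j} sample(s); >=2 required for variance"
            )
        sub = X[:, list(idx)]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += n_j - 1
    if dof == 0:
        raise ValueError("no tissue with >=2 samples; pooled sd undefined")
    return np.sqrt(ss / dof)


def tissue_t_statistics(
    X: np.ndarray,
    samples: Sequence[str],
    design: TissueDesign,
    allow_singletons: bool = False,
) -> SpecificityTable:
    """Moderated per-tissue t-statistics.

    t_j = (Xbar_j - Xbar) / ( sqrt(1/m + 1/n_j) * (s + s0) ), where Xbar is
    the unweighted mean of tissue means, s the per-window pooled sd and s0
    the mean of s over all windows.
    """
    groups = design.groups(samples)
    tissues = tuple(groups)
    m = len(tissues)
    tissue_means = np.column_stack(
        [X[:, list(groups[t])].mean(axis=1) for t in tissues]
    )
    grand = tissue_means.mean(axis=1)
    s = pooled_within_tissue_sd(X, groups, allow_singletons=allow_singletons)
    s0 = float(s.mean())
    denom_sd = s + s0
    if np.any(denom_sd == 0):
        raise ValueError("s + s0 is zero (all-constant matrix); t undefined")
    t = np.empty_like(tissue_means)
    for j, tissue in enumerate(tissues):
        n_j = len(groups[tissue])
        t[:, j] = (tissue_means[:, j] - grand) / (
            np.sqrt(1.0 / m + 1.0 / n_j) * denom_sd
        )
    return SpecificityTable(tissues, tissue_means, grand, s, s0, t)


def call_cts_dhs(
    table: SpecificityTable,
    windows: Sequence[GenomicInterval],
    tissue: str,
    top_n: int = 20_000,
) -> List[GenomicInterval]:
    """The top_n windows by the tissue's t-statistic, as intervals."""
    if top_n > len(windows):
        raise ValueError(f"top_n={top_n} exceeds window count {len(windows)}")
    order = table.ranking(tissue)
    return [windows[i] for i in order[:top_n]]


def ubiquitous_ranking(
    table: SpecificityTable,
    windows: Sequence[GenomicInterval],
    top_n: int,
) -> List[GenomicInterval]:
    """Top windows by the grand mean of tissue means (ubiquitous DHS control)."""
    if top_n > len(windows):
        raise ValueError(f"top_n={top_n} exceeds window count {len(windows)}")
    order = table.ubiquitous_order()
    return [windows[i] for i in order[:top_n]]


def _stratified_halves(
    samples: Sequence[str], design: TissueDesign, rng: np.random.Generator
) -> Tuple[List[str], List[str]]:
    groups = design.groups(samples)
    half1: List[str] = []
    half2: List[str] = []
    for tissue, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(
                f"tissue {tissue!r} has a single sample; cannot split in halves"
            )
        perm = rng.permutation(len(idx))
        k = len(idx) // 2
        half1.extend(samples[idx[i]] for i in perm[:k])
        half2.extend(samples[idx[i]] for i in perm[k:])
    return half1, half2


def split_half_reproducibility(
    raw: WindowCountMatrix,
    design: TissueDesign,
    top_n_grid: Sequence[int],
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Correspondence-at-the-top curve between two stratified sample halves.

    Samples are split into two halves stratified by tissue, the full ranking
    pipeline is run per half, and for each n in ``top_n_grid`` the fraction of
    top-n windows shared between the halves (averaged over tissues) is
    computed.  Returns (grid, ratios, n_at_max) where the maximum position is
    located by piecewise-linear interpolation of the curve.
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(sorted(top_n_grid), dtype=int)
    if grid.size == 0 or grid[0] < 1 or grid[-1] > len(raw.windows):
        raise ValueError("top_n_grid must be within [1, n_windows]")
    half1, half2 = _stratified_halves(raw.samples, design, rng)

    def _rankings(names: List[str]) -> Dict[str, np.ndarray]:
        sub = raw.subset_samples(names)
        X = log_transform_normalize(sub)
        table = tissue_t_statistics(X, sub.samples, design, allow_singletons=True)
        return {t: table.ranking(t) for t in table.tissues}

    r1, r2 = _rankings(half1), _rankings(half2)
    tissues = [t for t in r1 if t in r2]
    ratios = np.zeros(grid.size)
    for t in tissues:
        for k, n in enumerate(grid):
            shared = len(set(r1[t][:n].tolist()) & set(r2[t][:n].tolist()))
            ratios[k] += shared / n
    ratios /= len(tissues)

    # locate the curve maximum on a dense piecewise-linear interpolation
    dense_n = np.linspace(grid[0], grid[-1], 2001)
    dense_r = np.interp(dense_n, grid, ratios)
    n_at_max = float(dense_n[int(np.argmax(dense_r))])
    return grid, ratios, n_at_max


def sample_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between sample profiles (columns)."""
    if X.shape[1] < 2:
        raise ValueError("need >=2 samples for a distance matrix")
    d = 1.0 - np.corrcoef(X, rowvar=False)
    np.fill_diagonal(d, 0.0)
    return d
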