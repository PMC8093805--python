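"""Windowed-ratio segmentation of density-sorted Y contigs into k-mer
density blocks (KDBs).

Under continuous Y degeneration, contigs sorted by male-specific k-mer
density should decay smoothly; discrete recombination-suppression events
instead leave runs of contigs sharing a density level, separated by steps.
The scan statistic at position ``i`` is the mean density of the ``window``
contigs just passed (the denser, leading side) divided by the mean density
of the next ``window`` contigs; on a densest-first ordering each ratio is
>= 1 up to sampling noise and a step shows up as a local peak. Breakpoints
are called at sufficiently high, locally maximal ratios and partition the
ordering into blocks, interpreted as candidate evolutionary strata.

Averages are taken over density in k-mers per effective bp. The reciprocal
convention (averaging bp-per-kmer instead, as the density axis is usually
plotted) is available via ``use_bp_per_kmer``; means of reciprocals differ,
so the two conventions can rank near-tied boundaries differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .haplotype_density import ContigKmerStats

DEFAULT_WINDOW = 5
DEFAULT_PEAK_MIN_RATIO = 1.5


@dataclass
class DensityScan:
    """Leading/trailing window means and their ratio along the ordering.

    ``positions[j]`` is the contig index ``i`` whose ratio compares contigs
    ``[i - window, i)`` against ``[i, i + window)``; a breakpoint at ``i``
    means "block boundary before contig i".
    """

    ordered_contigs: list[ContigKmerStats]
    window: int
    positions: np.ndarray
    leading_mean: np.ndarray
    trailing_mean: np.ndarray
    ratios: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "leading_mean": self.leading_mean,
                "trailing_mean": self.trailing_mean,
                "ratio": self.ratios,
            }
        )


@dataclass
class KmerDensityBlock:
    """A maximal run of density-sorted contigs between breakpoints."""

    block_index: int  # 1 = densest
    contigs: list[ContigKmerStats] = field(default_factory=list)

    @property
    def contig_ids(self) -> list[str]:
        return [s.contig_id for s in self.contigs]

    @property
    def total_span(self) -> int:
        return int(sum(s.eff_len for s in self.contigs))

    @property
    def mean_bp_per_kmer(self) -> float:
        return float(np.mean([s.bp_per_kmer for s in self.contigs]))

    @property
    def mean_density(self) -> float:
        return float(np.mean([s.density for s in self.contigs]))


def ratio_scan(
    ordered: Sequence[ContigKmerStats],
    window: int = DEFAULT_WINDOW,
    use_bp_per_kmer: bool = False,
) -> DensityScan:
    """Compute the leading/trailing mean-density ratio at every interior
    position of a densest-first ordering."""
    n = len(ordered)
    if window < 1:
        raise ValueError("window must be >= 1")
    if n < 2 * window:
        raise ValueError(
            f"need at least 2*window={2 * window} contigs, got {n}; use a smaller window"
        )
    values = np.array(
        [s.bp_per_kmer if use_bp_per_kmer else s.density for s in ordered], dtype=float
    )
    if not np.all(values > 0):
        raise ValueError("every contig needs a positive density")
    cum = np.concatenate(([0.0], np.cumsum(values)))
    positions = np.arange(window, n - window + 1, dtype=np.int64)
    leading = (cum[positions] - cum[positions - window]) / window
    trailing = (cum[positions + window] - cum[positions]) / window
    if use_bp_per_kmer:
        # bp-per-kmer grows as density falls; keep "peak at a density drop"
        ratios = trailing / leading
    else:
        ratios = leading / trailing
    return DensityScan(
        ordered_contigs=list(ordered),
        window=window,
        positions=positions,
        leading_mean=leading,
        trailing_mean=trailing,
        ratios=ratios,
    )


def call_breakpoints(
    scan: DensityScan,
    peak_min_ratio: float = DEFAULT_PEAK_MIN_RATIO,
    min_separation: int | None = None,
) -> list[int]:
    """Contig indices where the scan ratio is >= ``peak_min_ratio`` and a
    local maximum within ``min_separation`` positions (default: the window);
    plateau ties resolve to the leftmost position."""
    if peak_min_ratio <= 1:
        raise ValueError("peak_min_ratio must exceed 1")
    sep = scan.window if min_separation is None else min_separation
    r = scan.ratios
    peaks = []
    for j in range(r.size):
        if r[j] < peak_min_ratio:
            continue
        lo, hi = max(0, j - sep), min(r.size, j + sep + 1)
        if np.all(r[lo:j] < r[j]) and np.all(r[j + 1 : hi] <= r[j]):
            peaks.append(int(scan.positions[j]))
    return peaks


def assign_blocks(
    ordered: Sequence[ContigKmerStats], breakpoints: Sequence[int]
) -> list[KmerDensityBlock]:
    """Partition the ordering at ``breakpoints`` (strictly increasing, each in
    (0, n)) into k+1 blocks, block 1 densest."""
    n = len(ordered)
    bps = list(breakpoints)
    if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
        raise ValueError(f"breakpoints must be strictly increasing: {bps}")
    if any(not 0 < b < n for b in bps):
        raise ValueError(f"breakpoints must lie in (0, {n}): {bps}")
    bounds = [0, *bps, n]
    return [
        KmerDensityBlock(block_index=i + 1, contigs=list(ordered[lo:hi]))
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]))
    ]


def blocks_to_frame(blocks: Sequence[KmerDensityBlock]) -> pd.DataFrame:
    rows = []
    rank = 0
    for block in blocks:
        for s in block.contigs:
            rank += 1
            rows.append(
                {
                    "block_index": block.block_index,
                    "contig_id": s.contig_id,
                    "rank": rank,
                    "bp_per_kmer": s.bp_per_kmer,
                    "eff_len": s.eff_len,
                }
            )
    return pd.DataFrame(
        rows, columns=["block_index", "contig_id", "rank", "bp_per_kmer", "eff_len"]
    )
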