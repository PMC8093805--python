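"""Scoring phased contigs against the male-specific k-mer set and selecting
Y-linked contigs.

In a phased diploid assembly of a male, each contig carries two haplotype
sequences. Contigs spanning the hemizygous Y region concentrate male-specific
k-mer matches on the Y-carrying haplotype; well-phased Y contigs therefore
show a strongly asymmetric match ratio between their haplotypes. Selection
uses three inclusive cutoffs: ratio between haplotype match counts of at
least ``min_ratio`` (default 2.5), at least ``min_kmers`` matches on the
Y haplotype (default 30) and a density of at least one match per
``max_bp_per_kmer`` of effective sequence (default 2000 bp).

Density denominators use *effective length*: ambiguous/gap bases (N) never
count, and for externally sequenced contigs with resolved repeats
(``is_bac``) soft-masked lowercase bases are excluded too, since short-read
phased contigs do not resolve those repeats and would otherwise be judged on
a different denominator.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .kmer_core import match_kmer_set
from .male_filter import MaleSpecificKmerSet

DEFAULT_HAP_REGEX = r"^(?P<id>.+)_(?P<hap>[12])$"


@dataclass
class PhasedContig:
    """One contig with its two phased haplotype sequences."""

    contig_id: str
    hap1: str
    hap2: str
    is_bac: bool = False

    def __post_init__(self) -> None:
        if not self.hap1 or not self.hap2:
            raise ValueError(f"{self.contig_id}: empty haplotype sequence")


@dataclass
class ContigKmerStats:
    """Per-contig match counts, haplotype call and density."""

    contig_id: str
    kmers_hap: tuple[int, int]
    eff_len_hap: tuple[int, int]
    ratio: float  # max/min; inf when min == 0 and max > 0; nan when both 0
    y_hap: int  # 1 or 2; 0 = undetermined (exact tie or no matches)
    bp_per_kmer: float  # eff_len of y_hap / kmers on y_hap; nan if undetermined

    @property
    def y_kmers(self) -> int:
        return self.kmers_hap[self.y_hap - 1] if self.y_hap else 0

    @property
    def eff_len(self) -> int:
        return self.eff_len_hap[self.y_hap - 1] if self.y_hap else 0

    @property
    def density(self) -> float:
        """Matches per effective bp on the Y haplotype (1 / bp_per_kmer)."""
        return self.y_kmers / self.eff_len if self.y_hap and self.eff_len else math.nan


@dataclass
class YSelectionConfig:
    min_ratio: float = 2.5
    min_kmers: int = 30
    max_bp_per_kmer: float = 2000.0

    def __post_init__(self) -> None:
        if self.min_ratio <= 0 or self.min_kmers <= 0 or self.max_bp_per_kmer <= 0:
            raise ValueError("selection cutoffs must be strictly positive")


def effective_length(seq: str, mask_aware: bool = False) -> int:
    """Sequence length minus N/n bases; minus soft-masked lowercase bases too
    when ``mask_aware``."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_ambig = int(np.sum((arr == ord("N")) | (arr == ord("n"))))
    if mask_aware:
        lowmask = (arr >= ord("a")) & (arr <= ord("z")) & (arr != ord("n"))
        return len(seq) - n_ambig - int(np.sum(lowmask))
    return len(seq) - n_ambig


def score_contig(contig: PhasedContig, kmers: MaleSpecificKmerSet) -> ContigKmerStats:
    """Match the male-specific set against both haplotypes and call the
    Y-carrying side. Exact ties yield no call: a tie carries no phasing
    signal."""
    n1 = int(match_kmer_set(kmers.codes, contig.hap1, kmers.k).size)
    n2 = int(match_kmer_set(kmers.codes, contig.hap2, kmers.k).size)
    e1 = effective_length(contig.hap1, mask_aware=contig.is_bac)
    e2 = effective_length(contig.hap2, mask_aware=contig.is_bac)
    hi, lo = max(n1, n2), min(n1, n2)
    if hi == 0:
        ratio, y_hap = math.nan, 0
    elif n1 == n2:
        ratio, y_hap = 1.0, 0
    else:
        ratio = math.inf if lo == 0 else hi / lo
        y_hap = 1 if n1 > n2 else 2
    if y_hap:
        eff = (e1, e2)[y_hap - 1]
        bp_per_kmer = eff / hi if hi else math.nan
    else:
        bp_per_kmer = math.nan
    return ContigKmerStats(
        contig_id=contig.contig_id,
        kmers_hap=(n1, n2),
        eff_len_hap=(e1, e2),
        ratio=ratio,
        y_hap=y_hap,
        bp_per_kmer=bp_per_kmer,
    )


def score_unphased(
    contig_id: str, seq: str, kmers: MaleSpecificKmerSet, mask_aware: bool = True
) -> ContigKmerStats:
    """Score a single-haplotype contig already known to be Y-linked (e.g. a
    finished BAC), so it can be injected into the density ordering."""
    n = int(match_kmer_set(kmers.codes, seq, kmers.k).size)
    eff = effective_length(seq, mask_aware=mask_aware)
    return ContigKmerStats(
        contig_id=contig_id,
        kmers_hap=(n, 0),
        eff_len_hap=(eff, 0),
        ratio=math.inf if n else math.nan,
        y_hap=1 if n else 0,
        bp_per_kmer=eff / n if n else math.nan,
    )


def select_y_contigs(
    stats: Iterable[ContigKmerStats], cfg: YSelectionConfig | None = None
) -> list[ContigKmerStats]:
    """Apply the ratio / count / density cutoffs (all inclusive) and sort the
    survivors densest-first, ties broken by contig_id."""
    cfg = cfg or YSelectionConfig()
    selected = [
        s
        for s in stats
        if s.y_hap
        and s.ratio >= cfg.min_ratio
        and s.y_kmers >= cfg.min_kmers
        and s.bp_per_kmer <= cfg.max_bp_per_kmer
    ]
    selected.sort(key=lambda s: (s.bp_per_kmer, s.contig_id))
    return selected


def load_phased_fasta(
    path: str | Path, hap_regex: str = DEFAULT_HAP_REGEX
) -> list[PhasedContig]:
    """Read a phased assembly FASTA whose records pair up via a haplotype
    suffix convention (default ``<id>_1`` / ``<id>_2``)."""
    pattern = re.compile(hap_regex)
    haps: dict[str, dict[int, str]] = {}
    order: list[str] = []
    from .kmer_core import _open_text

    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            m = pattern.match(name)
            if not m:
                raise ValueError(f"{path}: record {name!r} does not match {hap_regex!r}")
            cid, hap = m.group("id"), int(m.group("hap"))
            if cid not in haps:
                haps[cid] = {}
                order.append(cid)
            haps[cid][hap] = seq
    contigs = []
    for cid in order:
        pair = haps[cid]
        if set(pair) != {1, 2}:
            raise ValueError(f"{path}: contig {cid!r} is missing haplotype {3 - next(iter(pair))}")
        contigs.append(PhasedContig(contig_id=cid, hap1=pair[1], hap2=pair[2]))
    return contigs


def stats_to_frame(
    stats: Iterable[ContigKmerStats], selected_ids: set[str] | None = None
) -> pd.DataFrame:
    rows = []
    for s in stats:
        rows.append(
            {
                "contig_id": s.contig_id,
                "kmers_hap1": s.kmers_hap[0],
                "kmers_hap2": s.kmers_hap[1],
                "ratio": s.ratio,
                "y_hap": s.y_hap,
                "eff_len": s.eff_len,
                "bp_per_kmer": s.bp_per_kmer,
                "selected": bool(selected_ids and s.contig_id in selected_ids),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id", "kmers_hap1", "kmers_hap2", "ratio",
            "y_hap", "eff_len", "bp_per_kmer", "selected",
        ],
    )
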