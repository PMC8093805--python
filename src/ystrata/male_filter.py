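"""Derivation of the male-specific k-mer set from per-sample count tables.

A k-mer is *male-specific* when it is present above a coverage-derived lower
bound in every male sample and at or below a small error tolerance in every
female sample. Because the hemizygous Y region has no X counterpart, its
k-mers appear at roughly half the diploid coverage in males and should be
absent from females entirely; the female tolerance only absorbs recurrent
sequencing errors.

The shipped "paper mode" thresholds follow the published date-palm study
design: a deeply sequenced reference male/female pair with strict cutoffs
(male count > 24 kept, female count > 21 excluded) plus additional pairs at
lower depth (male count >= 3 kept, female counts above 9 / 8 excluded). All
exclusive phrasings are normalised to inclusive bounds here: ``male_min`` is
the smallest accepted male count, ``female_max`` the largest tolerated female
count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .kmer_core import CoverageHistogram, KmerCountTable


class TroughNotFoundError(ValueError):
    """The coverage histogram has no interior error trough."""


@dataclass(frozen=True)
class SampleThresholds:
    """Per-sample inclusion/exclusion rule for the male-specific filter."""

    sample_id: str
    sex: str  # "male" | "female"
    role: str = "additional"  # "reference" | "additional"
    male_min: int | None = None
    female_max: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.role not in ("reference", "additional"):
            raise ValueError(f"role must be 'reference' or 'additional', got {self.role!r}")
        if self.sex == "male":
            if self.male_min is None or self.male_min < 1:
                raise ValueError(f"{self.sample_id}: male sample needs male_min >= 1")
            if self.female_max is not None:
                raise ValueError(f"{self.sample_id}: male sample must not set female_max")
        else:
            if self.female_max is None or self.female_max < 0:
                raise ValueError(f"{self.sample_id}: female sample needs female_max >= 0")
            if self.male_min is not None:
                raise ValueError(f"{self.sample_id}: female sample must not set male_min")


#: Published cutoffs for the three male/female date-palm pairs, with the
#: exclusive phrasings normalised to inclusive bounds.
PAPER_THRESHOLDS: tuple[SampleThresholds, ...] = (
    SampleThresholds("deglet_noor_male", "male", "reference", male_min=25),
    SampleThresholds("deglet_noor_female", "female", "reference", female_max=21),
    SampleThresholds("zaghloul_male", "male", "additional", male_min=3),
    SampleThresholds("hayani_male", "male", "additional", male_min=3),
    SampleThresholds("zaghloul_female", "female", "additional", female_max=9),
    SampleThresholds("hayani_female", "female", "additional", female_max=8),
)


@dataclass
class MaleSpecificKmerSet:
    """Sorted canonical codes surviving all per-sample predicates."""

    k: int
    codes: np.ndarray
    provenance: list[SampleThresholds] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)

    def __len__(self) -> int:
        return self.codes.size

    def __contains__(self, code: int) -> bool:
        idx = np.searchsorted(self.codes, np.uint64(code))
        return bool(idx < self.codes.size and self.codes[idx] == np.uint64(code))

    def to_tsv(self, path: str | Path) -> None:
        table = KmerCountTable(
            sample_id="male_specific",
            k=self.k,
            codes=self.codes,
            counts=np.ones(self.codes.size, dtype=np.int64),
        )
        table.to_tsv(path)

    def write_provenance(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"k": self.k, "n_kmers": int(len(self)),
                 "thresholds": [asdict(t) for t in self.provenance]},
                fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MaleSpecificKmerSet":
        table = KmerCountTable.from_tsv(path)
        return cls(k=table.k, codes=table.codes)


def find_error_trough(hist: CoverageHistogram, smooth_window: int = 3) -> int:
    """Count value of the trough separating the low-count error peak from the
    main coverage mode.

    The mode is the argmax of the (3-bin smoothed) histogram over counts >= 2;
    the trough is the observed count in ``[2, mode)`` with the fewest distinct
    k-mers, ties broken toward the smaller count. Histograms that decrease
    monotonically (no interior mode) raise :class:`TroughNotFoundError`, and
    thresholds must then be chosen manually.
    """
    if not hist.bins:
        raise TroughNotFoundError("empty histogram")
    cmax = min(max(hist.bins), 100_000)
    dense = np.zeros(cmax + 1, dtype=np.float64)
    for c, m in hist.bins.items():
        if c <= cmax:
            dense[c] = m
    # the error peak at counts 0-1 must not bleed into the mode search
    peak_src = dense.copy()
    peak_src[:2] = 0
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(peak_src, kernel, mode="same")
    else:
        smoothed = peak_src
    if cmax < 2:
        raise TroughNotFoundError("histogram has no counts >= 2")
    mode = 2 + int(np.argmax(smoothed[2:]))
    interior = [c for c in hist.bins if 2 <= c < mode]
    if not interior:
        raise TroughNotFoundError(
            "no interior trough between count 2 and the histogram mode; "
            "set count thresholds manually"
        )
    return min(interior, key=lambda c: (hist.bins[c], c))


def select_male_specific(
    tables: list[tuple[SampleThresholds, KmerCountTable]],
    female_literal: bool = False,
) -> MaleSpecificKmerSet:
    """Intersect per-sample predicates into the male-specific k-mer set.

    A k-mer is retained iff its count is >= ``male_min`` in every male table
    and <= ``female_max`` in every female table; a k-mer absent from a table
    counts 0, so females lacking it trivially pass. ``female_literal`` flips
    the female rule to "discard when count <= female_max" — an alternative
    reading of the published additional-female cutoffs that is inconsistent
    with retaining female-absent k-mers, provided for comparison only.
    """
    if not tables:
        raise ValueError("no count tables given")
    ks = {tbl.k for _, tbl in tables}
    if len(ks) != 1:
        raise ValueError(f"mixed k across tables: {sorted(ks)}")
    males = [(t, tbl) for t, tbl in tables if t.sex == "male"]
    females = [(t, tbl) for t, tbl in tables if t.sex == "female"]
    if not males:
        raise ValueError("at least one male table required")
    if not females:
        raise ValueError("at least one female table required")

    # seed from the reference male (or the first male), then narrow
    males.sort(key=lambda pair: pair[0].role != "reference")
    first_t, first_tbl = males[0]
    cand = first_tbl.codes[first_tbl.counts >= first_t.male_min]
    for t, tbl in males[1:]:
        cand = cand[tbl.counts_for(cand) >= t.male_min]
    for t, tbl in females:
        counts = tbl.counts_for(cand)
        keep = counts > t.female_max if female_literal else counts <= t.female_max
        cand = cand[keep]
    return MaleSpecificKmerSet(
        k=next(iter(ks)), codes=cand, provenance=[t for t, _ in tables]
    )
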