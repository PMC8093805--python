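"""Canonical k-mer primitives: 2-bit encoding, counting, coverage histograms
and exact matching of k-mer sets against sequences.

A k-mer of length ``k`` (k <= 32) is packed into an unsigned 64-bit integer,
two bits per base with A=0, C=1, G=2, T=3 and the leftmost base most
significant. By default every window is *canonicalised*: the numerically
smaller of the forward and reverse-complement encodings represents both, so
counts from unstranded short reads do not depend on which strand a read was
sampled from. Windows that overlap any non-ACGT character contribute nothing,
matching the behaviour of standard k-mer counters. Soft-masked (lowercase)
bases are read as their uppercase equivalents.

All positions are 0-based; windows are half-open ``[pos, pos + k)``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_K = 16

# base -> 2-bit code; 255 marks ambiguous characters
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _BASE_CODE[_c] = _i
for _i, _c in enumerate(b"acgt"):
    _BASE_CODE[_c] = _i

_CODE_BASE = "ACGT"

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")

# masks for reversing the 2-bit fields inside each byte
_M_03 = np.uint64(0x0303030303030303)
_M_0C = np.uint64(0x0C0C0C0C0C0C0C0C)
_M_30 = np.uint64(0x3030303030303030)
_M_C0 = np.uint64(0xC0C0C0C0C0C0C0C0)


def _check_k(k: int) -> None:
    if not 1 <= k <= 32:
        raise ValueError(f"k must be in [1, 32], got {k}")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of packed k-mer codes."""
    _check_k(k)
    x = np.bitwise_not(np.asarray(codes, dtype=np.uint64))  # 3 - base, per 2 bits
    x = x.byteswap()  # reverse byte order
    x = (
        ((x & _M_03) << np.uint64(6))
        | ((x & _M_0C) << np.uint64(2))
        | ((x & _M_30) >> np.uint64(2))
        | ((x & _M_C0) >> np.uint64(6))
    )  # reverse 2-bit fields within each byte
    return x >> np.uint64(64 - 2 * k)


def encode_kmer(seq: str) -> int:
    """Pack an unambiguous DNA word into its forward-strand integer code."""
    code = 0
    for ch in seq:
        b = _BASE_CODE[ord(ch)]
        if b == 255:
            raise ValueError(f"ambiguous base {ch!r} in k-mer {seq!r}")
        code = (code << 2) | int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    _check_k(k)
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    return "".join(_CODE_BASE[(code >> shift) & 3] for shift in range(2 * k - 2, -2, -2))


def encode_canonical(seq: str, k: int = DEFAULT_K) -> int | None:
    """Canonical code of a single window, or ``None`` if it contains a
    non-ACGT character. Raises ``ValueError`` when the window length is not k."""
    if len(seq) != k:
        raise ValueError(f"window length {len(seq)} != k={k}")
    codes, _ = window_codes(seq, k, canonical=True)
    return int(codes[0]) if codes.size else None


def window_codes(
    seq: str, k: int = DEFAULT_K, canonical: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Codes and start positions of every valid k-length window of ``seq``.

    Returns ``(codes, positions)``; windows overlapping a non-ACGT character
    are dropped. With ``canonical`` the smaller of forward/reverse-complement
    codes is reported per window.
    """
    _check_k(k)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.size - k + 1
    empty = np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    if n <= 0:
        return empty
    b = _BASE_CODE[arr]
    bad = b == 255
    bu = (b & np.uint8(3)).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | bu[j : j + n]
    cum = np.concatenate(([0], np.cumsum(bad, dtype=np.int64)))
    valid = (cum[k:] - cum[:-k]) == 0
    pos = np.flatnonzero(valid).astype(np.int64)
    codes = codes[valid]
    if canonical:
        codes = np.minimum(codes, revcomp_codes(codes, k))
    return codes, pos


@dataclass
class KmerCountTable:
    """Multiset of (by default canonical) k-mers observed in one sample.

    ``codes`` is sorted ascending and parallel to ``counts``; every count is
    at least 1.
    """

    sample_id: str
    k: int
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must be parallel arrays")

    @property
    def total_kmers(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.codes.size

    def counts_for(self, query: np.ndarray) -> np.ndarray:
        """Counts for an array of codes; absent codes count 0."""
        query = np.asarray(query, dtype=np.uint64)
        if self.codes.size == 0:
            return np.zeros(query.size, dtype=np.int64)
        idx = np.searchsorted(self.codes, query)
        idx = np.clip(idx, 0, self.codes.size - 1)
        hit = self.codes[idx] == query
        return np.where(hit, self.counts[idx], 0)

    def count_of(self, code: int) -> int:
        return int(self.counts_for(np.asarray([code], dtype=np.uint64))[0])

    def as_dict(self) -> dict[int, int]:
        return dict(zip(self.codes.tolist(), self.counts.tolist()))

    def to_tsv(self, path: str | Path) -> None:
        """Serialise as ``kmer<TAB>count`` in ascending code order."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            fh.write("kmer\tcount\n")
            for code, count in zip(self.codes.tolist(), self.counts.tolist()):
                fh.write(f"{decode_kmer(code, self.k)}\t{count}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "KmerCountTable":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        codes, counts = [], []
        k = None
        with opener(path, "rt") as fh:
            header = fh.readline()
            if not header.startswith("kmer"):
                raise ValueError(f"{path}: expected 'kmer<TAB>count' header")
            for line in fh:
                word, count = line.rstrip("\n").split("\t")
                if k is None:
                    k = len(word)
                codes.append(encode_kmer(word))
                counts.append(int(count))
        if k is None:
            raise ValueError(f"{path}: empty table, k unknown")
        order = np.argsort(np.asarray(codes, dtype=np.uint64))
        return cls(
            sample_id=sample_id or path.stem,
            k=k,
            codes=np.asarray(codes, dtype=np.uint64)[order],
            counts=np.asarray(counts, dtype=np.int64)[order],
        )


@dataclass
class CoverageHistogram:
    """``bins[c]`` = number of distinct k-mers seen exactly ``c`` times."""

    bins: dict[int, int]

    def total_kmers(self) -> int:
        return sum(c * m for c, m in self.bins.items())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("count\tn_kmers\n")
            for c in sorted(self.bins):
                fh.write(f"{c}\t{self.bins[c]}\n")


def _chunk_codes(buf: list[str], k: int, canonical: bool) -> np.ndarray:
    # 'N' separator invalidates windows spanning read boundaries
    codes, _ = window_codes("N".join(buf), k, canonical=canonical)
    return codes


def count_kmers(
    reads: Iterable[str],
    k: int = DEFAULT_K,
    canonical: bool = True,
    sample_id: str = "sample",
) -> KmerCountTable:
    """Count every valid k-length window across a stream of sequences.

    A read of length L without ambiguous bases contributes L - k + 1 windows.
    """
    _check_k(k)
    chunks: list[np.ndarray] = []
    buf: list[str] = []
    buf_len = 0
    for seq in reads:
        buf.append(seq)
        buf_len += len(seq) + 1
        if buf_len >= 4_000_000:
            chunks.append(_chunk_codes(buf, k, canonical))
            buf, buf_len = [], 0
    if buf:
        chunks.append(_chunk_codes(buf, k, canonical))
    if chunks:
        all_codes = np.concatenate(chunks)
        codes, counts = np.unique(all_codes, return_counts=True)
    else:
        codes = np.empty(0, dtype=np.uint64)
        counts = np.empty(0, dtype=np.int64)
    return KmerCountTable(sample_id=sample_id, k=k, codes=codes, counts=counts.astype(np.int64))


def coverage_histogram(table: KmerCountTable) -> CoverageHistogram:
    vals, mult = np.unique(table.counts, return_counts=True)
    return CoverageHistogram(bins=dict(zip(vals.tolist(), mult.tolist())))


def match_kmer_set(
    kmers: np.ndarray | Iterable[int],
    sequence: str,
    k: int = DEFAULT_K,
    canonical: bool = True,
) -> np.ndarray:
    """Start positions of windows of ``sequence`` whose (canonical) code is in
    ``kmers``. Each window position is counted once regardless of the query
    set's multiplicities."""
    kmer_arr = np.unique(np.fromiter(kmers, dtype=np.uint64)) if not isinstance(
        kmers, np.ndarray
    ) else np.unique(np.asarray(kmers, dtype=np.uint64))
    codes, pos = window_codes(sequence, k, canonical=canonical)
    if codes.size == 0 or kmer_arr.size == 0:
        return np.empty(0, dtype=np.int64)
    idx = np.searchsorted(kmer_arr, codes)
    idx = np.clip(idx, 0, kmer_arr.size - 1)
    hit = kmer_arr[idx] == codes
    return pos[hit]


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_sequences(path: str | Path) -> Iterator[str]:
    """Yield sequences from a FASTA or FASTQ file (optionally gzipped).

    The format is sniffed from the first record character; qualities are
    ignored.
    """
    fh = _open_text(path)
    try:
        first = fh.read(1)
        fh.seek(0)
        if first == "@":
            for _title, seq, _qual in FastqGeneralIterator(fh):
                yield seq
        elif first == ">":
            for _title, seq in SimpleFastaParser(fh):
                yield seq
        elif first == "":
            return
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
    finally:
        fh.close()


def count_kmers_from_files(
    paths: Iterable[str | Path],
    k: int = DEFAULT_K,
    canonical: bool = True,
    sample_id: str = "sample",
) -> KmerCountTable:
    def _all_reads() -> Iterator[str]:
        for p in paths:
            yield from iter_sequences(p)

    return count_kmers(_all_reads(), k=k, canonical=canonical, sample_id=sample_id)
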