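"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: counting and matching go
through Python dictionaries and string slicing, canonicalisation through
string reverse complement and lexicographic comparison.
"""

from __future__ import annotations

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def naive_canonical(word: str) -> str | None:
    word = word.upper()
    if any(b not in _COMP for b in word):
        return None
    rc = naive_revcomp(word)
    return min(word, rc)


def naive_count(reads, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            canon = naive_canonical(read[i : i + k])
            if canon is not None:
                counts[canon] = counts.get(canon, 0) + 1
    return counts


def naive_match_positions(words: set[str], sequence: str, k: int) -> list[int]:
    canon_set = {naive_canonical(w) for w in words}
    canon_set.discard(None)
    hits = []
    for i in range(len(sequence) - k + 1):
        canon = naive_canonical(sequence[i : i + k])
        if canon is not None and canon in canon_set:
            hits.append(i)
    return hits


def random_dna(rng, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))
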