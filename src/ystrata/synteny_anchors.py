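"""Best-hit synteny anchoring of Y contigs against an annotated reference.

Consumes the 12-column tabular alignment dialect (qseqid, sseqid, pident,
length, mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore) of
Y contigs aligned to a reference genome or proteome, reduces each contig to
its single best hit (maximal bitscore, file order as tie-breaker), and
reports per density block: the dominant reference chromosome, the anchor
position range on it, and a Kendall-type rank concordance between the
contigs' density order and their anchor positions. Concordance near +1 or
-1 indicates conserved (collinear) ordering; values near 0 indicate
rearrangement or noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .block_segmentation import KmerDensityBlock

BLAST_TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a tabular alignment file; subject coordinates are 1-based
    inclusive and may be reversed for minus-strand hits."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    rank_in_query: int  # 0-based file order within the query


@dataclass(frozen=True)
class SyntenyAnchor:
    """A contig's approximate location on the reference: the midpoint of its
    best hit's subject interval."""

    contig_id: str
    subject_chrom: str
    anchor_pos: int
    block_index: int


def read_blast_tabular(path: str | Path) -> list[AlignmentHit]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=BLAST_TABULAR_COLUMNS
    )
    hits: list[AlignmentHit] = []
    ranks: dict[str, int] = {}
    for row in df.itertuples(index=False):
        q = str(row.qseqid)
        rank = ranks.get(q, 0)
        ranks[q] = rank + 1
        hits.append(
            AlignmentHit(
                query_id=q,
                subject_id=str(row.sseqid),
                percent_identity=float(row.pident),
                alignment_length=int(row.length),
                mismatches=int(row.mismatch),
                gap_opens=int(row.gapopen),
                query_start=int(row.qstart),
                query_end=int(row.qend),
                subject_start=int(row.sstart),
                subject_end=int(row.send),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
                rank_in_query=rank,
            )
        )
    return hits


def best_hits(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Per query, the hit with maximal bitscore; ties broken by file order
    then lexicographic subject id."""
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
            continue
        key = (-hit.bitscore, hit.rank_in_query, hit.subject_id)
        cur_key = (-cur.bitscore, cur.rank_in_query, cur.subject_id)
        if key < cur_key:
            best[hit.query_id] = hit
    return best


def anchors_from_best_hits(
    best: Mapping[str, AlignmentHit], blocks: Sequence[KmerDensityBlock]
) -> list[SyntenyAnchor]:
    """Turn best hits into block-tagged anchors; contigs outside the blocks
    (or without a hit) yield no anchor."""
    block_of = {
        cid: block.block_index for block in blocks for cid in block.contig_ids
    }
    anchors = []
    for cid, hit in best.items():
        if cid not in block_of:
            continue
        pos = (hit.subject_start + hit.subject_end) // 2
        anchors.append(
            SyntenyAnchor(
                contig_id=cid,
                subject_chrom=hit.subject_id,
                anchor_pos=int(pos),
                block_index=block_of[cid],
            )
        )
    return anchors


def rank_concordance(ranks: Sequence[int], positions: Sequence[int]) -> float:
    """Kendall-type concordance in [-1, 1]: (concordant - discordant) pairs
    over all pairs; position ties count as neither."""
    n = len(ranks)
    if n != len(positions):
        raise ValueError("ranks and positions must be parallel")
    if n < 2:
        return math.nan
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            dr = ranks[j] - ranks[i]
            dp = positions[j] - positions[i]
            prod = dr * dp
            if prod > 0:
                conc += 1
            elif prod < 0:
                disc += 1
    return (conc - disc) / (n * (n - 1) / 2)


def collinearity_report(
    anchors: Sequence[SyntenyAnchor], blocks: Sequence[KmerDensityBlock]
) -> pd.DataFrame:
    """Per-block summary: dominant reference chromosome (mode of anchors),
    fraction of anchors on it, anchor position range, density-rank/position
    concordance among the dominant-chromosome anchors, and counts of
    secondary chromosomes."""
    rank_of: dict[str, int] = {}
    rank = 0
    for block in blocks:
        for cid in block.contig_ids:
            rank += 1
            rank_of[cid] = rank
    by_block: dict[int, list[SyntenyAnchor]] = {}
    for a in anchors:
        if a.block_index not in {b.block_index for b in blocks}:
            raise ValueError(f"anchor {a.contig_id} references unknown block {a.block_index}")
        by_block.setdefault(a.block_index, []).append(a)
    rows = []
    for block in blocks:
        blk_anchors = by_block.get(block.block_index, [])
        if blk_anchors:
            chrom_counts: dict[str, int] = {}
            for a in blk_anchors:
                chrom_counts[a.subject_chrom] = chrom_counts.get(a.subject_chrom, 0) + 1
            dominant = min(chrom_counts, key=lambda c: (-chrom_counts[c], c))
            on_dom = sorted(
                (a for a in blk_anchors if a.subject_chrom == dominant),
                key=lambda a: rank_of[a.contig_id],
            )
            frac = len(on_dom) / len(blk_anchors)
            pos = [a.anchor_pos for a in on_dom]
            conc = rank_concordance([rank_of[a.contig_id] for a in on_dom], pos)
            secondary = ";".join(
                f"{c}:{chrom_counts[c]}" for c in sorted(chrom_counts) if c != dominant
            )
            rows.append(
                {
                    "block_index": block.block_index,
                    "n_contigs": len(block.contigs),
                    "n_anchors": len(blk_anchors),
                    "dominant_chrom": dominant,
                    "frac_dominant": frac,
                    "pos_min": min(pos),
                    "pos_max": max(pos),
                    "concordance": conc,
                    "secondary_chroms": secondary,
                }
            )
        else:
            rows.append(
                {
                    "block_index": block.block_index,
                    "n_contigs": len(block.contigs),
                    "n_anchors": 0,
                    "dominant_chrom": "",
                    "frac_dominant": math.nan,
                    "pos_min": -1,
                    "pos_max": -1,
                    "concordance": math.nan,
                    "secondary_chroms": "",
                }
            )
    return pd.DataFrame(rows)


def anchors_to_frame(anchors: Sequence[SyntenyAnchor]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": a.contig_id,
                "subject_chrom": a.subject_chrom,
                "anchor_pos": a.anchor_pos,
                "block_index": a.block_index,
            }
            for a in anchors
        ],
        columns=["contig_id", "subject_chrom", "anchor_pos", "block_index"],
    )
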