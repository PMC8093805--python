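"""Ground-truthed simulation of the study design the pipeline assumes.

The generator builds an ancestral X sequence and derives a Y from it by
planting male-specific substitutions in contiguous *strata* of differing
density — the generative counterpart of k-mer density blocks. Planted
variants keep a minimum spacing of k bases, so each substitution creates
approximately k novel Y-specific k-mers and the planted k-mer density is
analytically predictable (k times the variant density). The male assembly
individual is emitted as phased contigs tiling the sex region (X window vs
Y window, Y-carrying haplotype index randomised per contig) plus autosomal
contigs, and every individual — one reference male and additional
male/female pairs — is sequenced as uniformly placed error-bearing reads.

All males share the same X and Y; each individual additionally carries its
own private heterozygous variants (density ``het_density``) on one autosomal
haplotype, and each female on one X haplotype, so private variation is
correctly rejected by the male-specific filter while shared Y variation
survives it. A small fraction of contigs receives an N-run (an assembly gap)
to exercise effective-length bookkeeping; reads are always drawn from the
gap-free underlying genome.

Determinism: every random stream is seeded as ``[seed, stream_id]`` with
fixed per-purpose stream ids, so identical configs reproduce byte-identical
outputs and adding a sample does not shift any other sample's reads.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .haplotype_density import PhasedContig
from .kmer_core import DEFAULT_K, window_codes

_LETTERS = np.frombuffer(b"ACGTN", dtype=np.uint8)

# fixed stream ids (combined with the master seed)
_STREAM_SEX = 1
_STREAM_CONTIGS = 2
_STREAM_AUTOSOME = 3
_STREAM_SAMPLE_BASE = 1000


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _codes_to_str(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class StratumSpec:
    """One contiguous Y stratum: ``variant_density`` substitutions per bp are
    introduced on the Y relative to the X."""

    name: str
    length: int
    variant_density: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not 0 <= self.variant_density <= 0.1:
            raise ValueError(f"{self.name}: variant_density must be in [0, 0.1]")


def _default_strata() -> list[StratumSpec]:
    return [
        StratumSpec("stratum1", 200_000, 0.01),
        StratumSpec("stratum2", 200_000, 0.0033),
        StratumSpec("stratum3", 200_000, 0.0011),
    ]


@dataclass
class SimulationConfig:
    """Study-shaped defaults: three strata of 20 x 10 kb contigs each with
    densities 0.01 / 0.0033 / 0.0011, three male/female pairs at 20x
    per-haplotype coverage, 100 bp reads."""

    seed: int
    strata: list[StratumSpec] = field(default_factory=_default_strata)
    autosome_length: int = 200_000
    contig_length: int = 10_000
    n_pairs: int = 3
    coverage: float = 20.0
    read_length: int = 100
    error_rate: float = 0.0
    het_density: float = 0.001
    k: int = DEFAULT_K
    n_run_fraction: float = 0.05  # contigs given an assembly-gap N run
    n_run_span: float = 0.10  # fraction of contig length covered by the run

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")
        for name, value in [
            ("autosome_length", self.autosome_length),
            ("contig_length", self.contig_length),
            ("n_pairs", self.n_pairs),
            ("coverage", self.coverage),
            ("read_length", self.read_length),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        for s in self.strata:
            if s.length < self.contig_length:
                raise ValueError(f"{s.name}: stratum shorter than contig_length")

    @property
    def sex_length(self) -> int:
        return sum(s.length for s in self.strata)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strata"] = [asdict(s) for s in self.strata]
        return d


def default_config(seed: int, **overrides) -> SimulationConfig:
    return SimulationConfig(seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Planted strata coordinates (0-based half-open on the simulated Y),
    planted variant positions, and — after contig emission — per-contig
    origin, Y-haplotype index and planted k-mer count."""

    strata: pd.DataFrame  # name, start, end, variant_density, n_variants
    variant_positions: np.ndarray
    contigs: pd.DataFrame | None = None


def simulate_sex_region(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Ancestral X (uniform ACGT), derived Y, and the planted truth.

    Per stratum the number of substitutions is Poisson(length x density);
    positions are uniform over placements with pairwise spacing >= k and the
    substituted base always differs from the original.
    """
    rng = _rng(cfg.seed, _STREAM_SEX)
    length = cfg.sex_length
    x = rng.integers(0, 4, size=length, dtype=np.uint8)
    y = x.copy()
    rows = []
    all_pos: list[np.ndarray] = []
    offset = 0
    for s in cfg.strata:
        m = int(rng.poisson(s.length * s.variant_density))
        if m > 0:
            span = s.length - (m - 1) * cfg.k
            if span < m:
                raise ValueError(
                    f"{s.name}: cannot place {m} variants with spacing {cfg.k} "
                    f"in {s.length} bp; lower the variant density"
                )
            q = np.sort(rng.choice(span, size=m, replace=False))
            pos = q + np.arange(m, dtype=np.int64) * cfg.k + offset
            y[pos] = (y[pos] + rng.integers(1, 4, size=m, dtype=np.uint8)) % 4
            all_pos.append(pos)
        rows.append(
            {
                "name": s.name,
                "start": offset,
                "end": offset + s.length,
                "variant_density": s.variant_density,
                "n_variants": m,
            }
        )
        offset += s.length
    variant_positions = (
        np.concatenate(all_pos) if all_pos else np.empty(0, dtype=np.int64)
    )
    truth = GroundTruth(strata=pd.DataFrame(rows), variant_positions=variant_positions)
    return x, y, truth


def mutate_sequence(
    seq: np.ndarray, density: float, rng: np.random.Generator
) -> np.ndarray:
    """Copy of ``seq`` with Poisson(len x density) substitutions at uniform
    positions (no spacing constraint), each to a different base."""
    out = seq.copy()
    m = int(rng.poisson(len(seq) * density))
    if m > 0:
        m = min(m, len(seq))
        pos = rng.choice(len(seq), size=m, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=m, dtype=np.uint8)) % 4
    return out


def _planted_kmer_count(y_win: np.ndarray, x_win: np.ndarray, k: int) -> int:
    """Windows of the Y haplotype whose canonical k-mer is absent from the X
    haplotype of the same contig — the contig's expected match count against
    a perfect male-specific set."""
    y_codes, _ = window_codes(_codes_to_str(y_win), k)
    x_codes, _ = window_codes(_codes_to_str(x_win), k)
    x_sorted = np.unique(x_codes)
    if y_codes.size == 0:
        return 0
    if x_sorted.size == 0:
        return int(y_codes.size)
    idx = np.clip(np.searchsorted(x_sorted, y_codes), 0, x_sorted.size - 1)
    return int(np.sum(x_sorted[idx] != y_codes))


def emit_phased_contigs(
    x: np.ndarray,
    y: np.ndarray,
    truth: GroundTruth,
    cfg: SimulationConfig,
    autosome_haps: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[list[PhasedContig], GroundTruth]:
    """Tile the sex region (and the reference male's autosome pair, when
    given) into phased contigs and fill the per-contig truth table.

    Sex contigs pair an X window with a Y window, the Y-carrying haplotype
    index drawn Bernoulli(0.5) per contig; ``n_run_fraction`` of contigs get
    an N run covering ``n_run_span`` of their length on both haplotypes.
    """
    rng = _rng(cfg.seed, _STREAM_CONTIGS)
    clen = cfg.contig_length
    strata = truth.strata
    contigs: list[PhasedContig] = []
    rows = []

    def origin_of(start: int) -> str:
        mid = start + clen // 2
        hit = strata[(strata["start"] <= mid) & (mid < strata["end"])]
        return str(hit.iloc[0]["name"]) if len(hit) else "sex_region"

    n_sex = len(x) // clen
    for i in range(n_sex):
        lo, hi = i * clen, (i + 1) * clen
        x_win, y_win = x[lo:hi].copy(), y[lo:hi].copy()
        y_first = bool(rng.random() < 0.5)
        has_n = bool(rng.random() < cfg.n_run_fraction)
        if has_n:
            run = max(1, int(round(clen * cfg.n_run_span)))
            start = int(rng.integers(0, clen - run + 1))
            x_win[start : start + run] = 4
            y_win[start : start + run] = 4
        planted = _planted_kmer_count(y_win, x_win, cfg.k)
        cid = f"sex_{i:04d}"
        hap1, hap2 = (y_win, x_win) if y_first else (x_win, y_win)
        contigs.append(
            PhasedContig(cid, _codes_to_str(hap1), _codes_to_str(hap2))
        )
        rows.append(
            {
                "contig_id": cid,
                "origin": origin_of(lo),
                "start": lo,
                "end": hi,
                "y_hap": 1 if y_first else 2,
                "planted_kmer_count": planted,
                "has_n_run": has_n,
            }
        )
    if autosome_haps is not None:
        a1, a2 = autosome_haps
        n_auto = len(a1) // clen
        for i in range(n_auto):
            lo, hi = i * clen, (i + 1) * clen
            w1, w2 = a1[lo:hi].copy(), a2[lo:hi].copy()
            has_n = bool(rng.random() < cfg.n_run_fraction)
            if has_n:
                run = max(1, int(round(clen * cfg.n_run_span)))
                start = int(rng.integers(0, clen - run + 1))
                w1[start : start + run] = 4
                w2[start : start + run] = 4
            cid = f"auto_{i:04d}"
            contigs.append(PhasedContig(cid, _codes_to_str(w1), _codes_to_str(w2)))
            rows.append(
                {
                    "contig_id": cid,
                    "origin": "autosome",
                    "start": lo,
                    "end": hi,
                    "y_hap": 0,
                    "planted_kmer_count": 0,
                    "has_n_run": has_n,
                }
            )
    truth.contigs = pd.DataFrame(rows)
    return contigs, truth


def simulate_reads(
    haplotypes: Sequence[np.ndarray],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> Iterator[tuple[str, str]]:
    """Uniform error-bearing reads over every haplotype of one individual.

    Per haplotype of length L the read count is round(coverage x L /
    read_length); starts are uniform, strand is random, and each base is
    substituted with probability ``error_rate``.
    """
    rl = cfg.read_length
    read_no = 0
    for hap_idx, hap in enumerate(haplotypes):
        length = len(hap)
        if length < rl:
            raise ValueError(f"haplotype {hap_idx} shorter than read_length")
        n_reads = int(round(cfg.coverage * length / rl))
        # positions and strands are drawn before errors, so runs differing
        # only in error_rate sample the same fragments
        starts = rng.integers(0, length - rl + 1, size=n_reads)
        flip = rng.random(n_reads) < 0.5
        mat = hap[starts[:, None] + np.arange(rl)]
        if cfg.error_rate > 0:
            mask = rng.random((n_reads, rl)) < cfg.error_rate
            shift = rng.integers(1, 4, size=(n_reads, rl), dtype=np.uint8)
            mat = np.where(mask, (mat + shift) % 4, mat)
        mat[flip] = (3 - mat[flip])[:, ::-1]
        letters = _LETTERS[mat]
        for r in range(n_reads):
            read_no += 1
            yield (
                f"{sample_id}:{hap_idx}:{read_no}",
                letters[r].tobytes().decode("ascii"),
            )


def write_fastq_gz(path: str | Path, reads: Iterator[tuple[str, str]]) -> int:
    """Write reads with constant qualities; gzip mtime pinned to 0 so
    identical content gives identical bytes."""
    n = 0
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", compresslevel=1, mtime=0) as gz:
            buf: list[str] = []
            for name, seq in reads:
                buf.append(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
                n += 1
                if len(buf) >= 10_000:
                    gz.write("".join(buf).encode("ascii"))
                    buf = []
            if buf:
                gz.write("".join(buf).encode("ascii"))
    return n


@dataclass
class SimulatedSample:
    sample_id: str
    sex: str
    role: str
    fastq_path: Path
    n_reads: int


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    outdir: Path
    assembly_path: Path
    samples: list[SimulatedSample]
    contigs: list[PhasedContig]
    truth: GroundTruth

    def default_male_min(self) -> int:
        # a quarter of per-haplotype depth: well under the hemizygous peak,
        # well over recurrent-error counts
        return max(2, int(round(self.config.coverage / 4)))

    def default_female_max(self) -> int:
        return max(1, int(round(self.config.coverage * 0.15)))

    def sample_manifest(self) -> list[dict]:
        """Per-sample entries (path + thresholds) ready for the pipeline."""
        entries = []
        for s in self.samples:
            entry = {
                "sample_id": s.sample_id,
                "path": str(s.fastq_path),
                "sex": s.sex,
                "role": s.role,
            }
            if s.sex == "male":
                entry["male_min"] = self.default_male_min()
            else:
                entry["female_max"] = self.default_female_max()
            entries.append(entry)
        return entries


def write_phased_fasta(path: str | Path, contigs: Sequence[PhasedContig]) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.contig_id}_1\n{c.hap1}\n>{c.contig_id}_2\n{c.hap2}\n")


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> SimulatedDataset:
    """Run the full generator: genome, phased contigs, per-sample reads and
    truth tables, written under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x, y, truth = simulate_sex_region(cfg)

    rng_auto = _rng(cfg.seed, _STREAM_AUTOSOME)
    autosome = rng_auto.integers(0, 4, size=cfg.autosome_length, dtype=np.uint8)
    ref_auto_het = mutate_sequence(autosome, cfg.het_density, rng_auto)

    contigs, truth = emit_phased_contigs(
        x, y, truth, cfg, autosome_haps=(autosome, ref_auto_het)
    )
    assembly_path = outdir / "phased_contigs.fasta"
    write_phased_fasta(assembly_path, contigs)

    samples: list[SimulatedSample] = []
    for pair in range(cfg.n_pairs):
        for sex_idx, sex in enumerate(("male", "female")):
            stream = _STREAM_SAMPLE_BASE + 2 * pair + sex_idx
            rng = _rng(cfg.seed, stream)
            sample_id = f"{sex}_{pair}"
            role = "reference" if pair == 0 else "additional"
            if sex == "male":
                auto2 = ref_auto_het if pair == 0 else mutate_sequence(
                    autosome, cfg.het_density, rng
                )
                haps = [x, y, autosome, auto2]
            else:
                x2 = mutate_sequence(x, cfg.het_density, rng)
                auto2 = mutate_sequence(autosome, cfg.het_density, rng)
                haps = [x, x2, autosome, auto2]
            fastq = outdir / f"{sample_id}.fastq.gz"
            n_reads = write_fastq_gz(
                fastq, simulate_reads(haps, cfg, rng, sample_id=sample_id)
            )
            samples.append(SimulatedSample(sample_id, sex, role, fastq, n_reads))

    truth.strata.to_csv(outdir / "truth_strata.tsv", sep="\t", index=False)
    truth.contigs.to_csv(outdir / "truth_contigs.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return SimulatedDataset(
        config=cfg,
        outdir=outdir,
        assembly_path=assembly_path,
        samples=samples,
        contigs=contigs,
        truth=truth,
    )


def evaluate_recovery(
    truth: GroundTruth,
    block_assignments: Sequence[Sequence[str]],
    y_hap_calls: Mapping[str, int] | None = None,
) -> dict:
    """Compare a segmentation against the planted truth.

    ``block_assignments`` lists contig ids per detected block, in density
    order (block 1 first). Returns block count, expected vs detected
    breakpoint positions (in contigs along the ordering) and their maximal
    offset, majority-vote block/stratum membership agreement, and — when
    ``y_hap_calls`` maps contig id to the called Y haplotype index —
    haplotype assignment accuracy over planted sex contigs.
    """
    if truth.contigs is None:
        raise ValueError("truth has no per-contig table; run emit_phased_contigs first")
    tc = truth.contigs.set_index("contig_id")
    stratum_names = list(truth.strata["name"])
    sel = [cid for blk in block_assignments for cid in blk if cid in tc.index]

    # expected breakpoints: cumulative per-stratum counts of assigned contigs
    per_stratum = [
        sum(tc.loc[c, "origin"] == name for c in sel) for name in stratum_names
    ]
    expected_bps = [
        int(b) for b in np.cumsum(per_stratum)[:-1] if 0 < b < len(sel)
    ]
    detected_bps: list[int] = []
    acc = 0
    for blk in block_assignments[:-1]:
        acc += len(blk)
        detected_bps.append(acc)
    if len(detected_bps) == len(expected_bps) and expected_bps:
        max_offset: float = max(abs(d - e) for d, e in zip(detected_bps, expected_bps))
    else:
        max_offset = 0 if not (detected_bps or expected_bps) else math.inf

    agree = total = 0
    for blk in block_assignments:
        origins = [tc.loc[c, "origin"] for c in blk if c in tc.index]
        if not origins:
            continue
        majority = max(set(origins), key=origins.count)
        agree += sum(o == majority for o in origins)
        total += len(origins)

    hap_correct = hap_total = 0
    if y_hap_calls:
        for cid, call in y_hap_calls.items():
            if cid in tc.index and tc.loc[cid, "y_hap"] in (1, 2):
                hap_total += 1
                hap_correct += int(call == tc.loc[cid, "y_hap"])
    return {
        "n_blocks": len(block_assignments),
        "n_true_strata": len(stratum_names),
        "expected_breakpoints": expected_bps,
        "detected_breakpoints": detected_bps,
        "max_breakpoint_offset": max_offset,
        "membership_agreement": agree / total if total else math.nan,
        "y_hap_accuracy": hap_correct / hap_total if hap_total else math.nan,
        "n_selected": len(sel),
    }


def evaluate_run_dir(run_dir: str | Path, truth: GroundTruth) -> dict:
    """:func:`evaluate_recovery` applied to a pipeline output directory
    (reads ``blocks.tsv`` and ``selected_contigs.tsv``)."""
    run_dir = Path(run_dir)
    blocks_df = pd.read_csv(run_dir / "blocks.tsv", sep="\t")
    assignments: list[list[str]] = []
    if len(blocks_df):
        for _, grp in blocks_df.groupby("block_index", sort=True):
            assignments.append(list(grp.sort_values("rank")["contig_id"]))
    sel_df = pd.read_csv(run_dir / "selected_contigs.tsv", sep="\t")
    calls = dict(zip(sel_df["contig_id"], sel_df["y_hap"].astype(int)))
    return evaluate_recovery(truth, assignments, y_hap_calls=calls)
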