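"""Pipeline orchestration: count -> filter -> score -> segment -> anchor.

Each stage writes a deterministic TSV artifact under the output directory
and the run ends with a ``manifest.json`` recording input checksums, the
full parameter set and per-stage record counts. The selection cascade counts
(contigs with matches >= ratio-passing >= density-passing) mirror the shape
of the published date-palm cascade. A failed stage leaves a ``.partial``
marker naming the stage so incomplete outputs are recognisable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import block_segmentation as seg
from . import synteny_anchors as syn
from .haplotype_density import (
    DEFAULT_HAP_REGEX,
    YSelectionConfig,
    load_phased_fasta,
    score_contig,
    score_unphased,
    select_y_contigs,
    stats_to_frame,
)
from .kmer_core import (
    DEFAULT_K,
    count_kmers_from_files,
    coverage_histogram,
)
from .male_filter import SampleThresholds, select_male_specific

logger = logging.getLogger("ystrata")


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class SampleSpec:
    sample_id: str
    path: str
    thresholds: SampleThresholds


@dataclass
class PipelineConfig:
    samples: list[SampleSpec]
    assembly_path: str
    k: int = DEFAULT_K
    hap_regex: str = DEFAULT_HAP_REGEX
    canonical: bool = True
    female_literal: bool = False
    selection: YSelectionConfig = field(default_factory=YSelectionConfig)
    window: int = seg.DEFAULT_WINDOW
    peak_min_ratio: float = seg.DEFAULT_PEAK_MIN_RATIO
    min_separation: int | None = None
    extra_contigs_path: str | None = None  # single-haplotype Y contigs (e.g. BACs)
    hits_path: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            samples = []
            for s in d["samples"]:
                thr = SampleThresholds(
                    sample_id=s["sample_id"],
                    sex=s["sex"],
                    role=s.get("role", "additional"),
                    male_min=s.get("male_min"),
                    female_max=s.get("female_max"),
                )
                samples.append(
                    SampleSpec(sample_id=s["sample_id"], path=s["path"], thresholds=thr)
                )
            sel = d.get("selection", {})
            return cls(
                samples=samples,
                assembly_path=d["assembly"]["path"],
                hap_regex=d["assembly"].get("hap_regex", DEFAULT_HAP_REGEX),
                k=d.get("k", DEFAULT_K),
                canonical=d.get("canonical", True),
                female_literal=d.get("female_literal", False),
                selection=YSelectionConfig(
                    min_ratio=sel.get("min_ratio", 2.5),
                    min_kmers=sel.get("min_kmers", 30),
                    max_bp_per_kmer=sel.get("max_bp_per_kmer", 2000.0),
                ),
                window=d.get("segmentation", {}).get("window", seg.DEFAULT_WINDOW),
                peak_min_ratio=d.get("segmentation", {}).get(
                    "peak_min_ratio", seg.DEFAULT_PEAK_MIN_RATIO
                ),
                min_separation=d.get("segmentation", {}).get("min_separation"),
                extra_contigs_path=d.get("extra_contigs"),
                hits_path=d.get("hits"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "canonical": self.canonical,
            "female_literal": self.female_literal,
            "samples": [
                {"sample_id": s.sample_id, "path": s.path, **_thr_dict(s.thresholds)}
                for s in self.samples
            ],
            "assembly": {"path": self.assembly_path, "hap_regex": self.hap_regex},
            "selection": asdict(self.selection),
            "segmentation": {
                "window": self.window,
                "peak_min_ratio": self.peak_min_ratio,
                "min_separation": self.min_separation,
            },
            "extra_contigs": self.extra_contigs_path,
            "hits": self.hits_path,
        }

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [
                *(s.path for s in self.samples),
                self.assembly_path,
                self.extra_contigs_path,
                self.hits_path,
            ]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise ConfigError(f"missing input files: {missing}")


def _thr_dict(t: SampleThresholds) -> dict:
    d = {"sex": t.sex, "role": t.role}
    if t.male_min is not None:
        d["male_min"] = t.male_min
    if t.female_max is not None:
        d["female_max"] = t.female_max
    return d


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial = outdir / ".partial"
    counts: dict[str, int] = {}
    stage = "setup"
    try:
        cfg.validate_paths()
        partial.write_text(stage + "\n")

        stage = "count"
        t0 = time.perf_counter()
        partial.write_text(stage + "\n")
        tables = []
        for s in cfg.samples:
            tbl = count_kmers_from_files(
                [s.path], k=cfg.k, canonical=cfg.canonical, sample_id=s.sample_id
            )
            coverage_histogram(tbl).to_tsv(outdir / f"hist_{s.sample_id}.tsv")
            tables.append((s.thresholds, tbl))
            logger.info("count: %s -> %d distinct k-mers", s.sample_id, len(tbl))
        counts["samples_counted"] = len(tables)
        logger.info("count stage: %.1fs", time.perf_counter() - t0)

        stage = "filter"
        t0 = time.perf_counter()
        partial.write_text(stage + "\n")
        male_set = select_male_specific(tables, female_literal=cfg.female_literal)
        male_set.to_tsv(outdir / "male_kmers.tsv")
        male_set.write_provenance(outdir / "male_kmers.provenance.json")
        counts["male_specific_kmers"] = len(male_set)
        logger.info(
            "filter stage: %d male-specific k-mers (%.1fs)",
            len(male_set), time.perf_counter() - t0,
        )

        stage = "score"
        t0 = time.perf_counter()
        partial.write_text(stage + "\n")
        contigs = load_phased_fasta(cfg.assembly_path, cfg.hap_regex)
        stats = [score_contig(c, male_set) for c in contigs]
        if cfg.extra_contigs_path:
            from Bio.SeqIO.FastaIO import SimpleFastaParser

            with open(cfg.extra_contigs_path) as fh:
                for title, s in SimpleFastaParser(fh):
                    stats.append(
                        score_unphased(title.split()[0], s, male_set, mask_aware=True)
                    )
        selected = select_y_contigs(stats, cfg.selection)
        sel_ids = {s.contig_id for s in selected}
        stats_to_frame(stats, sel_ids).to_csv(
            outdir / "contig_stats.tsv", sep="\t", index=False
        )
        stats_to_frame(selected, sel_ids).to_csv(
            outdir / "selected_contigs.tsv", sep="\t", index=False
        )
        counts["contigs_scored"] = len(stats)
        counts["contigs_with_matches"] = sum(1 for s in stats if max(s.kmers_hap) > 0)
        counts["contigs_ratio_pass"] = sum(
            1 for s in stats if s.y_hap and s.ratio >= cfg.selection.min_ratio
        )
        counts["contigs_selected"] = len(selected)
        logger.info(
            "score stage: %d scored, %d selected (%.1fs)",
            len(stats), len(selected), time.perf_counter() - t0,
        )

        stage = "segment"
        t0 = time.perf_counter()
        partial.write_text(stage + "\n")
        blocks: list[seg.KmerDensityBlock] = []
        breakpoints: list[int] = []
        if len(selected) >= 2 * cfg.window:
            scan = seg.ratio_scan(selected, window=cfg.window)
            scan.to_frame().to_csv(outdir / "scan.tsv", sep="\t", index=False)
            breakpoints = seg.call_breakpoints(
                scan, cfg.peak_min_ratio, cfg.min_separation
            )
            blocks = seg.assign_blocks(selected, breakpoints)
        elif selected:
            # too few contigs to scan: a single block
            blocks = seg.assign_blocks(selected, [])
        seg.blocks_to_frame(blocks).to_csv(outdir / "blocks.tsv", sep="\t", index=False)
        counts["breakpoints"] = len(breakpoints)
        counts["blocks"] = len(blocks)
        logger.info(
            "segment stage: %d breakpoints, %d blocks (%.1fs)",
            len(breakpoints), len(blocks), time.perf_counter() - t0,
        )

        if cfg.hits_path:
            stage = "anchor"
            t0 = time.perf_counter()
            partial.write_text(stage + "\n")
            hits = syn.read_blast_tabular(cfg.hits_path)
            best = syn.best_hits(hits)
            anchors = syn.anchors_from_best_hits(best, blocks)
            syn.anchors_to_frame(anchors).to_csv(
                outdir / "anchors.tsv", sep="\t", index=False
            )
            syn.collinearity_report(anchors, blocks).to_csv(
                outdir / "block_summary.tsv", sep="\t", index=False
            )
            counts["anchors"] = len(anchors)
            logger.info(
                "anchor stage: %d anchors (%.1fs)",
                len(anchors), time.perf_counter() - t0,
            )

        stage = "manifest"
        inputs = {
            str(p): _sha256(p)
            for p in [
                *(s.path for s in cfg.samples),
                cfg.assembly_path,
                cfg.extra_contigs_path,
                cfg.hits_path,
            ]
            if p is not None
        }
        manifest = {
            "parameters": cfg.to_dict(),
            "inputs": inputs,
            "counts": counts,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        partial.unlink(missing_ok=True)
        return manifest
    except ConfigError:
        raise
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 — map to a stage-tagged failure
        raise StageError(stage, type(exc).__name__, str(exc)) from exc
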