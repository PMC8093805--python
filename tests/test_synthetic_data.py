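import filecmp
import gzip
import math
from pathlib import Path

import numpy as np
import pytest
from scipy import stats as sps

from ystrata import synthetic_data as sd
from ystrata.kmer_core import window_codes


def tiny_config(seed=42, **overrides):
    defaults = dict(
        strata=[
            sd.StratumSpec("s1", 20_000, 0.01),
            sd.StratumSpec("s2", 20_000, 0.0033),
        ],
        contig_length=2_000,
        autosome_length=10_000,
        coverage=5,
        n_pairs=2,
    )
    defaults.update(overrides)
    return sd.default_config(seed, **defaults)


def to_str(codes):
    return "".join("ACGTN"[b] for b in codes)


class TestSexRegion:
    def test_zero_density_leaves_y_identical_to_x(self):
        cfg = tiny_config(strata=[sd.StratumSpec("s", 20_000, 0.0)])
        x, y, truth = sd.simulate_sex_region(cfg)
        np.testing.assert_array_equal(x, y)
        assert truth.variant_positions.size == 0

    def test_variant_count_is_seeded_poisson(self):
        cfg = sd.default_config(7, strata=[sd.StratumSpec("s", 10_000, 0.002)],
                                contig_length=10_000, autosome_length=10_000)
        x, y, truth = sd.simulate_sex_region(cfg)
        m = truth.variant_positions.size
        lo, hi = sps.poisson(20).ppf([0.005, 0.995])
        assert lo <= m <= hi
        # exact reproducibility under the seed
        _, _, truth2 = sd.simulate_sex_region(cfg)
        np.testing.assert_array_equal(truth.variant_positions, truth2.variant_positions)

    def test_substitutions_differ_from_original_and_keep_spacing(self):
        cfg = tiny_config()
        x, y, truth = sd.simulate_sex_region(cfg)
        pos = truth.variant_positions
        assert np.all(x[pos] != y[pos])
        changed = np.flatnonzero(x != y)
        np.testing.assert_array_equal(changed, np.sort(pos))
        for _, row in truth.strata.iterrows():
            inside = np.sort(pos[(pos >= row["start"]) & (pos < row["end"])])
            if inside.size >= 2:
                assert np.diff(inside).min() >= cfg.k

    def test_stratum_densities_in_planted_ratio(self):
        cfg = sd.default_config(
            3,
            strata=[
                sd.StratumSpec("hi", 150_000, 0.009),
                sd.StratumSpec("lo", 150_000, 0.003),
            ],
            contig_length=10_000,
            autosome_length=10_000,
        )
        x, y, truth = sd.simulate_sex_region(cfg)
        strata = truth.strata.set_index("name")
        ratio = strata.loc["hi", "n_variants"] / strata.loc["lo", "n_variants"]
        assert ratio == pytest.approx(3.0, rel=0.25)  # Poisson sampling noise

    def test_unplaceable_density_raises(self):
        cfg = tiny_config(strata=[sd.StratumSpec("s", 20_000, 0.1)], seed=1)
        with pytest.raises(ValueError, match="density"):
            sd.simulate_sex_region(cfg)


class TestContigs:
    def test_zero_density_contig_haplotypes_identical(self):
        cfg = tiny_config(strata=[sd.StratumSpec("s", 20_000, 0.0)], n_run_fraction=0.0)
        x, y, truth = sd.simulate_sex_region(cfg)
        contigs, truth = sd.emit_phased_contigs(x, y, truth, cfg)
        assert all(c.hap1 == c.hap2 for c in contigs)
        assert (truth.contigs["planted_kmer_count"] == 0).all()

    def test_y_haplotype_index_is_balanced(self):
        cfg = sd.default_config(9, strata=[sd.StratumSpec("s", 200_000, 0.001)],
                                contig_length=2_000, autosome_length=2_000)
        x, y, truth = sd.simulate_sex_region(cfg)
        _, truth = sd.emit_phased_contigs(x, y, truth, cfg)
        sex = truth.contigs[truth.contigs["origin"] != "autosome"]
        frac = (sex["y_hap"] == 1).mean()
        assert 0.35 <= frac <= 0.65  # Bernoulli(0.5) over 100 contigs

    def test_n_run_covers_ten_percent_of_length(self):
        from ystrata.haplotype_density import effective_length

        cfg = tiny_config(n_run_fraction=1.0)
        x, y, truth = sd.simulate_sex_region(cfg)
        contigs, truth = sd.emit_phased_contigs(x, y, truth, cfg)
        for c in contigs:
            assert effective_length(c.hap1) == int(0.9 * cfg.contig_length)

    def test_planted_kmer_count_tracks_variants(self):
        # with spacing >= k each variant creates about k Y-specific k-mers
        cfg = tiny_config(n_run_fraction=0.0)
        x, y, truth = sd.simulate_sex_region(cfg)
        _, truth = sd.emit_phased_contigs(x, y, truth, cfg)
        tc = truth.contigs
        sex = tc[tc["origin"] == "s1"]
        total_planted = sex["planted_kmer_count"].sum()
        n_var = sum(
            1 for p in truth.variant_positions if p < 20_000
        )
        assert total_planted == pytest.approx(n_var * cfg.k, rel=0.1)


class TestReads:
    def test_read_count_matches_expected_depth(self):
        cfg = tiny_config(coverage=20, read_length=100)
        rng = np.random.default_rng(0)
        hap = rng.integers(0, 4, size=100_000, dtype=np.uint8)
        reads = list(sd.simulate_reads([hap], cfg, np.random.default_rng(1)))
        assert len(reads) == 20_000

    def test_error_free_reads_are_substrings(self):
        cfg = tiny_config(error_rate=0.0, read_length=60)
        rng = np.random.default_rng(0)
        hap = rng.integers(0, 4, size=5_000, dtype=np.uint8)
        hap_str = to_str(hap)
        from helpers import naive_revcomp

        for _, seq in sd.simulate_reads([hap], cfg, np.random.default_rng(1)):
            assert seq in hap_str or naive_revcomp(seq) in hap_str

    def test_error_rate_realised_within_binomial_noise(self):
        cfg = tiny_config(error_rate=0.01, read_length=100, coverage=10)
        rng = np.random.default_rng(0)
        hap = rng.integers(0, 4, size=50_000, dtype=np.uint8)
        hap_str = to_str(hap)
        from helpers import naive_revcomp

        mismatches = bases = 0
        # reads are uniform over positions; align by regenerating without error
        gen_err = sd.simulate_reads([hap], cfg, np.random.default_rng(9))
        cfg0 = tiny_config(error_rate=0.0, read_length=100, coverage=10)
        gen_clean = sd.simulate_reads([hap], cfg0, np.random.default_rng(9))
        for (_, noisy), (_, clean) in zip(gen_err, gen_clean):
            mismatches += sum(a != b for a, b in zip(noisy, clean))
            bases += len(noisy)
        rate = mismatches / bases
        sigma = math.sqrt(0.01 * 0.99 / bases)
        assert abs(rate - 0.01) <= 3 * sigma


class TestDatasetDeterminism:
    def test_identical_config_gives_byte_identical_outputs(self, tmp_path):
        cfg = tiny_config(seed=77, coverage=3)
        a = sd.simulate_dataset(cfg, tmp_path / "a")
        b = sd.simulate_dataset(tiny_config(seed=77, coverage=3), tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in files:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_different_seed_changes_reads(self, tmp_path):
        a = sd.simulate_dataset(tiny_config(seed=1, coverage=2), tmp_path / "a")
        b = sd.simulate_dataset(tiny_config(seed=2, coverage=2), tmp_path / "b")
        fa = gzip.open(a.samples[0].fastq_path, "rb").read()
        fb = gzip.open(b.samples[0].fastq_path, "rb").read()
        assert fa != fb
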