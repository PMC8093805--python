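import numpy as np
import pytest

from helpers import random_dna
from ystrata import kmer_core as kc
from ystrata import male_filter as mf


def make_table(counts_by_code: dict[int, int], sample_id="s", k=16):
    codes = np.array(sorted(counts_by_code), dtype=np.uint64)
    counts = np.array([counts_by_code[int(c)] for c in codes], dtype=np.int64)
    return kc.KmerCountTable(sample_id, k, codes=codes, counts=counts)


class TestErrorTrough:
    def test_unique_interior_minimum(self):
        hist = kc.CoverageHistogram({1: 1000, 2: 300, 3: 50, 10: 20, 20: 400, 21: 380})
        assert mf.find_error_trough(hist) == 10

    def test_monotone_histogram_has_no_trough(self):
        hist = kc.CoverageHistogram({1: 100, 2: 50, 3: 10})
        with pytest.raises(mf.TroughNotFoundError):
            mf.find_error_trough(hist)

    def test_tie_breaks_toward_smaller_count(self):
        hist = kc.CoverageHistogram({1: 500, 3: 20, 7: 20, 15: 300})
        assert mf.find_error_trough(hist) == 3

    def test_simulated_sample_with_errors(self, rng):
        # 25x haploid sample at 1% error: the trough must sit strictly
        # between the error peak and a mode near the true coverage
        from ystrata import synthetic_data as sd

        cfg = sd.default_config(5, coverage=25, error_rate=0.01)
        hap = rng.integers(0, 4, size=60_000, dtype=np.uint8)
        reads = (
            seq for _, seq in sd.simulate_reads([hap], cfg, np.random.default_rng(5))
        )
        table = kc.count_kmers(reads, k=16)
        hist = kc.coverage_histogram(table)
        trough = mf.find_error_trough(hist)
        dense = np.zeros(max(hist.bins) + 1)
        for c, m in hist.bins.items():
            dense[c] = m
        mode = 2 + int(np.argmax(dense[2:]))
        assert 2 < trough < mode
        # k-mer coverage is read coverage scaled by window yield and the
        # chance a 16-mer is error-free: 25 * (85/100) * 0.99**16 ~ 18
        expected_mode = 25 * (100 - 16 + 1) / 100 * 0.99**16
        assert 0.8 * expected_mode <= mode <= 1.2 * expected_mode


PAIRS = [
    (mf.SampleThresholds("refM", "male", "reference", male_min=25), "refM"),
    (mf.SampleThresholds("refF", "female", "reference", female_max=21), "refF"),
    (mf.SampleThresholds("m2", "male", male_min=3), "m2"),
    (mf.SampleThresholds("f2", "female", female_max=9), "f2"),
    (mf.SampleThresholds("m3", "male", male_min=3), "m3"),
    (mf.SampleThresholds("f3", "female", female_max=8), "f3"),
]


def run_filter(counts: dict[str, dict[int, int]], **kwargs):
    tables = [(thr, make_table(counts.get(sid, {}), sid)) for thr, sid in PAIRS]
    return mf.select_male_specific(tables, **kwargs)


class TestSelectMaleSpecific:
    def test_passing_kmer_is_retained(self):
        result = run_filter(
            {"refM": {7: 30}, "m2": {7: 5}, "m3": {7: 5}, "f2": {7: 2}}
        )
        assert 7 in result

    def test_reference_male_bound_is_exclusive_of_24(self):
        kept = run_filter({"refM": {7: 25}, "m2": {7: 3}, "m3": {7: 3}})
        dropped = run_filter({"refM": {7: 24}, "m2": {7: 3}, "m3": {7: 3}})
        assert 7 in kept and 7 not in dropped

    def test_female_tolerance_bounds_inclusive(self):
        base = {"refM": {7: 30}, "m2": {7: 5}, "m3": {7: 5}}
        assert 7 in run_filter({**base, "refF": {7: 21}})
        assert 7 not in run_filter({**base, "refF": {7: 22}})
        assert 7 in run_filter({**base, "f3": {7: 8}})
        assert 7 not in run_filter({**base, "f3": {7: 9}})

    def test_absent_kmer_counts_as_zero_for_females(self):
        result = run_filter({"refM": {7: 30}, "m2": {7: 3}, "m3": {7: 3}})
        assert 7 in result

    def test_requires_both_sexes_and_shared_k(self):
        male = (PAIRS[0][0], make_table({1: 30}, "refM"))
        female = (PAIRS[1][0], make_table({1: 1}, "refF"))
        with pytest.raises(ValueError, match="female"):
            mf.select_male_specific([male])
        odd = (PAIRS[1][0], make_table({1: 1}, "refF", k=15))
        with pytest.raises(ValueError, match="mixed k"):
            mf.select_male_specific([male, odd])

    def test_agrees_with_direct_predicate_enumeration(self, rng):
        n = 10_000
        codes = np.arange(n, dtype=np.uint64)
        # random counts with mass piled on the published boundary values
        special = [0, 2, 3, 8, 9, 21, 22, 24, 25]
        def draw():
            vals = rng.integers(0, 40, size=n)
            swap = rng.random(n) < 0.3
            vals[swap] = rng.choice(special, size=int(swap.sum()))
            return vals

        per_sample = {sid: draw() for _, sid in PAIRS}
        tables = [
            (thr, kc.KmerCountTable(sid, 16, codes=codes, counts=per_sample[sid]))
            for thr, sid in PAIRS
        ]
        result = mf.select_male_specific(tables)
        expected = [
            int(c)
            for c in codes
            if per_sample["refM"][c] >= 25
            and per_sample["m2"][c] >= 3
            and per_sample["m3"][c] >= 3
            and per_sample["refF"][c] <= 21
            and per_sample["f2"][c] <= 9
            and per_sample["f3"][c] <= 8
        ]
        assert result.codes.tolist() == expected

    def test_order_invariance(self, rng):
        counts = {
            "refM": {1: 30, 2: 26, 3: 40},
            "m2": {1: 5, 2: 3, 3: 2},
            "m3": {1: 5, 2: 3, 3: 9},
            "refF": {2: 4},
        }
        tables = [(thr, make_table(counts.get(sid, {}), sid)) for thr, sid in PAIRS]
        forward = mf.select_male_specific(tables)
        backward = mf.select_male_specific(tables[::-1])
        np.testing.assert_array_equal(forward.codes, backward.codes)

    def test_threshold_monotonicity(self):
        counts = {
            "refM": {c: 25 + c for c in range(10)},
            "m2": {c: 3 for c in range(10)},
            "m3": {c: 3 for c in range(10)},
            "refF": {c: c * 3 for c in range(10)},
        }
        def sized(female_max, male_min):
            pairs = []
            for thr, sid in PAIRS:
                if sid == "refF":
                    thr = mf.SampleThresholds(sid, "female", "reference", female_max=female_max)
                if sid == "refM":
                    thr = mf.SampleThresholds(sid, "male", "reference", male_min=male_min)
                pairs.append((thr, make_table(counts.get(sid, {}), sid)))
            return len(mf.select_male_specific(pairs))

        assert sized(21, 25) <= sized(27, 25)  # looser female tolerance grows set
        assert sized(21, 30) <= sized(21, 25)  # stricter male bound shrinks it

    def test_literal_female_reading_flag(self):
        # the alternative reading keeps a k-mer only when the female count
        # EXCEEDS the cutoff — inconsistent with female absence, but exposed
        base = {"refM": {7: 30}, "m2": {7: 5}, "m3": {7: 5},
                "refF": {7: 0}, "f2": {7: 10}, "f3": {7: 9}}
        assert 7 not in run_filter(base)
        assert 7 not in run_filter(base, female_literal=True)  # refF count 0 fails '>21'


class TestPlantedRecovery:
    def test_planted_y_kmers_recovered_without_error(self, rng):
        # zero-error male/female counts from planted Y-only k-mers
        y_only = {int(c) for c in rng.integers(0, 4**16, size=200)}
        shared = {int(c) for c in rng.integers(0, 4**16, size=200)} - y_only
        male_counts = {c: 30 for c in y_only} | {c: 50 for c in shared}
        female_counts = {c: 48 for c in shared}
        counts = {
            "refM": male_counts,
            "m2": {c: max(3, v // 8) for c, v in male_counts.items()},
            "m3": {c: max(3, v // 8) for c, v in male_counts.items()},
            "refF": female_counts,
            "f2": {c: v // 3 for c, v in female_counts.items()},
            "f3": {c: v // 3 for c, v in female_counts.items()},
        }
        result = run_filter(counts)
        assert set(result.codes.tolist()) == y_only


def test_paper_thresholds_are_well_formed():
    sexes = [t.sex for t in mf.PAPER_THRESHOLDS]
    assert sexes.count("male") == 3 and sexes.count("female") == 3
    ref = [t for t in mf.PAPER_THRESHOLDS if t.role == "reference"]
    assert {t.male_min or t.female_max for t in ref} == {25, 21}
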