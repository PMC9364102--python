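import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snpruns.runs import (
    DEFAULT_L_AUTO_BP,
    MinSnpInputs,
    ROH,
    ROHET,
    Run,
    RunParams,
    classify_lengths,
    compute_froh,
    detect_roh,
    detect_rohet,
    min_snp_threshold,
    postfilter_runs,
)
from snpruns.genotypes import GenomicMap, GenotypeMatrix
import pandas as pd

import oracles
from conftest import make_matrix


class TestMinSnpThreshold:
    @pytest.mark.parametrize(
        "alpha,ns,ni,het,expected",
        [
            (0.05, 44_901, 193, 0.2, 85),  # panel-scale inputs
            (0.05, 100, 10, 0.5, 14),
        ],
    )
    def test_known_values(self, alpha, ns, ni, het, expected):
        assert min_snp_threshold(
            MinSnpInputs(alpha, ns, ni, het)) == expected

    def test_direct_evaluation_oracle(self, rng):
        for _ in range(50):
            alpha = rng.uniform(0.001, 0.2)
            ns = int(rng.integers(100, 100_000))
            ni = int(rng.integers(2, 1000))
            het = rng.uniform(0.05, 0.6)
            expect = max(1, math.floor(
                math.log(alpha / (ns * ni)) / math.log(1 - het)))
            assert min_snp_threshold(
                MinSnpInputs(alpha, ns, ni, het)) == expect

    def test_zero_het_is_domain_error(self):
        with pytest.raises(ValueError):
            MinSnpInputs(0.05, 100, 10, 0.0)

    @given(
        alpha=st.floats(0.001, 0.3),
        ns=st.integers(100, 100_000),
        ni=st.integers(2, 2000),
        het=st.floats(0.02, 0.7),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_formula_properties(self, alpha, ns, ni, het):
        """The bound is >= 1 and monotone in its arguments."""
        base = min_snp_threshold(MinSnpInputs(alpha, ns, ni, het))
        assert base >= 1
        higher_het = min(0.75, het + 0.1)
        assert min_snp_threshold(
            MinSnpInputs(alpha, ns, ni, higher_het)) <= base
        assert min_snp_threshold(
            MinSnpInputs(alpha, ns * 2, ni, het)) >= base

    def test_monotonicity(self):
        """Threshold shrinks with rising het, grows with more tests."""
        base = min_snp_threshold(MinSnpInputs(0.05, 10_000, 100, 0.3))
        for het in (0.35, 0.4, 0.5):
            assert min_snp_threshold(
                MinSnpInputs(0.05, 10_000, 100, het)) <= base
        for ns in (20_000, 50_000):
            assert min_snp_threshold(
                MinSnpInputs(0.05, ns, 100, 0.3)) >= base


class TestDetectRohet:
    def test_fully_homozygous_individual_empty(self):
        g = make_matrix(["0" * 30],
                        positions=[1 + 100_000 * j for j in range(30)])
        assert detect_rohet(g, RunParams(kind=ROHET)) == []

    def test_twenty_het_snps_single_run(self):
        pos = [1 + 75_000 * j for j in range(20)]  # spans 1.425 Mb + 1
        g = make_matrix(["1" * 20], positions=pos)
        runs = detect_rohet(g, RunParams(kind=ROHET))
        assert len(runs) == 1
        r = runs[0]
        assert (r.start_bp, r.end_bp, r.n_snps) == (pos[0], pos[-1], 20)

    def test_single_homozygote_splits_and_kills_run(self):
        pos = [1 + 75_000 * j for j in range(20)]
        row = "1" * 9 + "0" + "1" * 10  # stretches of 9 and 10 < 16 SNPs
        g = make_matrix([row], positions=pos)
        assert detect_rohet(g, RunParams(kind=ROHET)) == []

    def test_gap_above_500kb_breaks_run(self):
        pos = [1 + 75_000 * j for j in range(10)]
        pos += [pos[-1] + 600_000 + 75_000 * j for j in range(10)]
        g = make_matrix(["1" * 20], positions=pos)
        assert detect_rohet(g, RunParams(kind=ROHET)) == []


class TestDetectRoh:
    def test_fully_heterozygous_individual_empty(self):
        g = make_matrix(["1" * 120],
                        positions=[1 + 20_000 * j for j in range(120)])
        assert detect_roh(g, RunParams(kind=ROH, min_snps=85)) == []

    def test_long_homozygous_stretch_one_run(self):
        pos = [1 + 17_000 * j for j in range(120)]  # spans ~2 Mb
        g = make_matrix(["0" * 120], positions=pos)
        runs = detect_roh(g, RunParams(kind=ROH, min_snps=85))
        assert len(runs) == 1
        assert runs[0].n_snps == 120
        assert (runs[0].start_bp, runs[0].end_bp) == (pos[0], pos[-1])

    def test_short_stretch_below_min_snps_empty(self):
        pos = [1 + 20_000 * j for j in range(60)]
        g = make_matrix(["0" * 60], positions=pos)
        assert detect_roh(g, RunParams(kind=ROH, min_snps=85)) == []


@pytest.mark.parametrize("seed", range(6))
def test_detectors_match_brute_force(seed):
    """Both detectors agree exactly with naive enumeration on random data."""
    rng = np.random.default_rng(seed)
    rohet_params = RunParams(kind=ROHET, min_length_bp=400_000, min_snps=4,
                             max_gap_bp=300_000)
    roh_params = RunParams(kind=ROH, min_length_bp=400_000, min_snps=5,
                           max_gap_bp=300_000, window_snps=8,
                           min_density_snps_per_mb=2.0)
    for _ in range(25):
        calls, pos = oracles.random_instance(rng)
        g = GenotypeMatrix(
            [f"i{k}" for k in range(calls.shape[0])],
            ["B"] * calls.shape[0],
            GenomicMap(pd.DataFrame({
                "snp_id": [f"s{j}" for j in range(len(pos))],
                "chrom": "1", "pos": pos})),
            calls,
        )
        got_het = {(r.sample_id, r.start_bp, r.end_bp, r.n_snps)
                   for r in detect_rohet(g, rohet_params)}
        want_het = {
            (f"i{k}", a, b, c)
            for k in range(calls.shape[0])
            for a, b, c in oracles.brute_rohet(
                calls[k], pos, rohet_params.min_length_bp,
                rohet_params.min_snps, rohet_params.max_gap_bp)
        }
        assert got_het == want_het
        got_roh = {(r.sample_id, r.start_bp, r.end_bp, r.n_snps)
                   for r in detect_roh(g, roh_params)}
        want_roh = {
            (f"i{k}", a, b, c)
            for k in range(calls.shape[0])
            for a, b, c in oracles.brute_roh(
                calls[k], pos, roh_params.min_length_bp,
                roh_params.min_snps, roh_params.max_gap_bp,
                roh_params.window_snps, roh_params.max_opposite_calls,
                roh_params.max_missing_calls,
                roh_params.min_density_snps_per_mb,
                roh_params.window_hit_threshold)
        }
        assert got_roh == want_roh


def _mk_run(start, end, n_snps=30, sample="i0", kind=ROH, chrom="1"):
    return Run(sample, chrom, start, end, n_snps, kind)


class TestPostfilter:
    def test_few_snp_runs_removed(self):
        runs = [_mk_run(1, 1_500_000, n_snps=4)]
        assert postfilter_runs(runs, n_individuals=10) == []

    def test_rare_region_removed_common_kept(self):
        rare = [_mk_run(1, 1_500_000, sample=f"i{k}") for k in range(3)]
        common = [_mk_run(5_000_000, 6_500_000, sample=f"i{k}")
                  for k in range(20)]
        kept = postfilter_runs(rare + common, n_individuals=100)
        assert {r.start_bp for r in kept} == {5_000_000}
        assert len(kept) == 20


class TestClassifyLengths:
    def test_printed_two_class_percentages(self):
        runs = ([_mk_run(1, 1_500_000, sample=f"a{k}") for k in range(301)]
                + [_mk_run(1, 2_700_000, sample=f"b{k}") for k in range(52)])
        out = classify_lengths(runs).set_index("length_class")
        assert out.loc["1-2 Mb", "count"] == 301
        assert out.loc["1-2 Mb", "percentage"] == 85.27
        assert out.loc["2-4 Mb", "percentage"] == 14.73

    def test_upper_inclusive_boundary(self):
        out = classify_lengths([_mk_run(1, 2_000_000)])
        out = out.set_index("length_class")
        assert out.loc["1-2 Mb", "count"] == 1
        assert out.loc["2-4 Mb", "count"] == 0

    def test_one_run_per_class(self):
        lengths = [1.5e6, 3e6, 9e6, 20e6]
        runs = [_mk_run(1, int(l)) for l in lengths]
        out = classify_lengths(runs)
        assert list(out["count"]) == [1, 1, 0, 1, 1]

    def test_empty_input_gives_na_percentages(self):
        out = classify_lengths([])
        assert (out["count"] == 0).all()
        assert out["percentage"].isna().all()


class TestFroh:
    def test_no_runs_zero(self):
        res = compute_froh([], ["i0"], DEFAULT_L_AUTO_BP)
        assert res[0].f_roh == 0.0

    def test_exact_ratio(self):
        runs = [_mk_run(1, 245_200_000)]
        res = compute_froh(runs, ["i0"], 2_452_000_000)
        assert res[0].f_roh == pytest.approx(0.1, abs=1e-9)

    def test_two_runs_sum(self):
        runs = [_mk_run(1, 10_000_000), _mk_run(20_000_001, 40_000_000)]
        res = compute_froh(runs, ["i0"], 2_452_000_000)
        assert res[0].f_roh == pytest.approx(30_000_000 / 2_452_000_000)

    def test_rejects_rohet_and_bad_l_auto(self):
        with pytest.raises(ValueError):
            compute_froh([_mk_run(1, 2_000_000, kind=ROHET)], ["i0"])
        with pytest.raises(ValueError):
            compute_froh([], ["i0"], 0)


def test_detected_runs_satisfy_their_invariants(rng):
    """Every reported run honors its length/SNP-count/gap constraints."""
    from snpruns.simulate import PlantedSegment, SyntheticConfig, \
        simulate_genotypes

    cfg = SyntheticConfig(
        n_individuals={"A": 30}, n_snps=5000, seed=2,
        planted_segments=[
            PlantedSegment(tuple(range(10)), "1", 5_000_000, 9_000_000,
                           "heterozygous"),
            PlantedSegment(tuple(range(10, 25)), "2", 20_000_000,
                           26_000_000, "homozygous"),
        ],
    )
    g, _ = simulate_genotypes(cfg)
    het_params = RunParams(kind=ROHET)
    roh_params = RunParams(kind=ROH, min_snps=40)
    pos_by_chrom = {c: g.gmap.positions(c) for c in g.gmap.chromosomes}
    for params, runs in ((het_params, detect_rohet(g, het_params)),
                         (roh_params, detect_roh(g, roh_params))):
        assert runs, "expected planted runs to be found"
        for r in runs:
            assert r.length_bp >= params.min_length_bp
            assert r.n_snps >= params.min_snps
            pos = pos_by_chrom[r.chrom]
            inside = pos[(pos >= r.start_bp) & (pos <= r.end_bp)]
            assert np.all(np.diff(inside) <= params.max_gap_bp)
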