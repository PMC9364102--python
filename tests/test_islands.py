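import numpy as np
import pytest

from snpruns.islands import (
    call_islands,
    consensus_regions,
    empirical_fdr,
    snp_incidence,
)
from snpruns.runs import ROHET, Run, RunParams, detect_rohet
from snpruns.simulate import PlantedSegment, SyntheticConfig, \
    simulate_genotypes

import oracles
from conftest import make_matrix


def _runs_covering_all(g, samples):
    first = int(g.gmap.table["pos"].iloc[0])
    last = int(g.gmap.table["pos"].iloc[-1])
    return [Run(s, "1", first, last, g.n_snps, ROHET) for s in samples]


class TestSnpIncidence:
    def test_full_and_zero_coverage(self):
        g = make_matrix(["1" * 5] * 10, positions=[10, 20, 30, 40, 50])
        inc = snp_incidence(_runs_covering_all(g, g.samples), g)
        assert all(s.occurrence == 1.0 for s in inc)
        inc0 = snp_incidence([], g)
        assert all(s.occurrence == 0.0 for s in inc0)

    def test_planted_carrier_fraction_recovered(self):
        cfg = SyntheticConfig(
            n_individuals={"A": 100}, n_snps=6000, seed=21,
            planted_segments=[PlantedSegment(
                tuple(range(30)), "1", 10_000_000, 14_000_000,
                "heterozygous")],
        )
        g, _ = simulate_genotypes(cfg)
        runs = detect_rohet(g, RunParams(kind=ROHET))
        inc = snp_incidence(runs, g)
        in_seg = [s for s in inc
                  if s.chrom == "1" and 10_500_000 <= s.pos <= 13_500_000]
        assert in_seg
        occ = np.array([s.occurrence for s in in_seg])
        # every planted carrier's run covers the interior of the segment
        assert np.all(occ >= 0.30)
        assert np.median(occ) == pytest.approx(0.30, abs=0.02)


class TestEmpiricalFdr:
    def test_top_snp_rank_p(self):
        g = make_matrix(["0" * 100], positions=[10 * j + 10
                                                for j in range(100)])
        inc = snp_incidence([Run("ind0", "1", 10, 15, 1, ROHET)], g)
        out = empirical_fdr(inc)
        top = [s for s in out if s.occurrence > 0]
        assert len(top) == 1
        assert top[0].empirical_p == pytest.approx(0.01)

    def test_all_tied_share_one_p(self):
        g = make_matrix(["1" * 6], positions=[10, 20, 30, 40, 50, 60])
        out = empirical_fdr(snp_incidence(_runs_covering_all(g, ["ind0"]), g))
        ps = {s.empirical_p for s in out}
        fps = {s.fdr_p for s in out}
        assert len(ps) == 1 and len(fps) == 1

    def test_bh_matches_independent_oracle(self, rng):
        for _ in range(30):
            occ = rng.random(20)
            g = make_matrix(["0" * 20], positions=[100 * j + 10
                                                   for j in range(20)])
            inc = snp_incidence([], g)
            inc = [type(s)(s.snp_id, s.chrom, s.pos, float(o))
                   for s, o in zip(inc, occ)]
            out = empirical_fdr(inc)
            emp = np.array([s.empirical_p for s in out])
            np.testing.assert_allclose(
                [s.fdr_p for s in out], oracles.bh_adjust(emp), atol=1e-12)

    def test_ten_vector_hand_case(self):
        # occurrences 0.9 x3 and 0.1 x7: the top tie group shares minimum
        # rank 1 (p = 0.1), the rest share rank 4 (p = 0.4); BH adjusts the
        # top three to 0.1 * 10/3 = 1/3 and the rest to 0.4
        g = make_matrix(["0" * 10], positions=[100 * j + 10
                                               for j in range(10)])
        inc = snp_incidence([], g)
        occ = [0.9] * 3 + [0.1] * 7
        inc = [type(s)(s.snp_id, s.chrom, s.pos, o)
               for s, o in zip(inc, occ)]
        out = empirical_fdr(inc)
        emp = np.array([s.empirical_p for s in out])
        np.testing.assert_allclose(emp, [0.1] * 3 + [0.4] * 7)
        np.testing.assert_allclose(
            [s.fdr_p for s in out], [1 / 3] * 3 + [0.4] * 7)
        np.testing.assert_allclose(
            [s.fdr_p for s in out], oracles.bh_adjust(emp), atol=1e-12)


class TestCallIslands:
    def test_no_passing_snp_empty(self):
        g = make_matrix(["1" * 6] * 4, positions=[10, 20, 30, 40, 50, 60])
        inc = empirical_fdr(snp_incidence(_runs_covering_all(g, g.samples),
                                          g))
        # all tied: adjusted p = 1 everywhere, nothing passes
        assert call_islands(inc, _runs_covering_all(g, g.samples)) == []

    def test_passing_snps_outside_any_run_excluded(self):
        g = make_matrix(["0" * 300], positions=[1000 * j + 10
                                                for j in range(300)])
        inc = snp_incidence([], g)
        # a 150-SNP high-occurrence plateau but no covering run at all
        inc = [type(s)(s.snp_id, s.chrom, s.pos,
                       0.9 if j < 150 else 0.0)
               for j, s in enumerate(inc)]
        out = empirical_fdr(inc)
        assert out[0].fdr_p == pytest.approx(1 / 150)
        assert out[0].fdr_p < 0.01
        assert call_islands(out, []) == []

    def test_planted_island_within_one_snp(self):
        cfg = SyntheticConfig(
            n_individuals={"A": 80}, n_snps=8000, seed=31,
            planted_segments=[PlantedSegment(
                tuple(range(48)), "2", 30_000_000, 35_000_000,
                "heterozygous")],
        )
        g, _ = simulate_genotypes(cfg)
        runs = detect_rohet(g, RunParams(kind=ROHET))
        islands = call_islands(empirical_fdr(snp_incidence(runs, g)), runs)
        assert len(islands) == 1
        isl = islands[0]
        pos2 = g.gmap.positions("2")
        inside = pos2[(pos2 >= 30_000_000) & (pos2 <= 35_000_000)]
        # allow one SNP of slack at each planted boundary
        assert isl.chrom == "2"
        assert abs(int(np.searchsorted(pos2, isl.start_bp))
                   - int(np.searchsorted(pos2, inside[0]))) <= 1
        assert abs(int(np.searchsorted(pos2, isl.end_bp))
                   - int(np.searchsorted(pos2, inside[-1]))) <= 1


class TestConsensusRegions:
    def test_one_bp_overlap_across_breeds_is_shared(self):
        runs = [Run("a", "1", 1_000_000, 2_000_000, 20, ROHET, breed="X"),
                Run("b", "1", 2_000_000, 3_000_000, 20, ROHET, breed="Y")]
        regions = consensus_regions(runs)
        assert len(regions) == 1
        assert regions[0].shared
        assert (regions[0].start_bp, regions[0].end_bp) == (1_000_000,
                                                            3_000_000)

    def test_disjoint_runs_stay_separate_and_unique(self):
        runs = [Run("a", "1", 1_000_000, 2_000_000, 20, ROHET, breed="X"),
                Run("a", "1", 2_000_001, 3_000_000, 20, ROHET, breed="X")]
        regions = consensus_regions(runs)
        assert len(regions) == 2
        assert not any(r.shared for r in regions)

    def test_input_order_invariance(self, rng):
        runs = [Run(f"i{k}", "1",
                    int(rng.integers(1, 50_000_000)), 0, 20, ROHET,
                    breed=f"B{k % 3}") for k in range(40)]
        runs = [Run(r.sample_id, r.chrom, r.start_bp,
                    r.start_bp + int(rng.integers(1_000_000, 3_000_000)),
                    r.n_snps, r.kind, r.breed) for r in runs]
        a = consensus_regions(runs)
        shuffled = list(runs)
        rng.shuffle(shuffled)
        b = consensus_regions(shuffled)
        assert [(r.chrom, r.start_bp, r.end_bp, r.carriers) for r in a] \
            == [(r.chrom, r.start_bp, r.end_bp, r.carriers) for r in b]

    def test_three_breed_shared_unique_labels(self):
        """5 planted shared + 10 unique regions are labelled exactly."""
        runs = []
        # 5 shared regions: carried in breeds X and Y with overlap
        for k in range(5):
            base = 10_000_000 * (k + 1)
            runs.append(Run(f"x{k}", "1", base, base + 2_000_000, 30,
                            ROHET, breed="X"))
            runs.append(Run(f"y{k}", "1", base + 1_000_000,
                            base + 3_000_000, 30, ROHET, breed="Y"))
        # 10 unique regions spread over chromosome 2, one breed each
        for k in range(10):
            base = 5_000_000 * (k + 1)
            runs.append(Run(f"z{k}", "2", base, base + 1_500_000, 30,
                            ROHET, breed=["X", "Y", "Z"][k % 3]))
        regions = consensus_regions(runs)
        shared = [r for r in regions if r.shared]
        unique = [r for r in regions if not r.shared]
        assert len(shared) == 5 and len(unique) == 10
        assert all(r.chrom == "1" for r in shared)
        assert all(r.chrom == "2" for r in unique)

    def test_island_intervals_covered_by_member_runs(self):
        cfg = SyntheticConfig(
            n_individuals={"A": 40}, n_snps=5000, seed=41,
            planted_segments=[PlantedSegment(
                tuple(range(20)), "1", 20_000_000, 24_000_000,
                "heterozygous")],
        )
        g, _ = simulate_genotypes(cfg)
        runs = detect_rohet(g, RunParams(kind=ROHET))
        islands = call_islands(empirical_fdr(snp_incidence(runs, g)), runs)
        for isl in islands:
            assert isl.member_runs
            assert any(r.start_bp <= isl.start_bp and r.end_bp >= isl.end_bp
                       for r in isl.member_runs) or len(isl.member_runs) > 1
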