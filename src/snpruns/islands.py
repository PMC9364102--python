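"""Population-level run incidence, island calling, and consensus regions.

The island statistic ranks SNPs genome-wide by the fraction of individuals
whose runs cover them; the rank is converted to an empirical p-value
(rank / n, smallest for the most frequently covered SNP, minimum rank for
ties) and adjusted with Benjamini-Hochberg FDR.  SNPs with an adjusted
p-value below the cut-off that actually sit inside at least one run are
island SNPs; consecutive island SNPs merge into island intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from snpruns.genotypes import GenotypeMatrix
from snpruns.runs import Run


@dataclass(frozen=True)
class SnpIncidence:
    snp_id: str
    chrom: str
    pos: int
    occurrence: float  # fraction of individuals with a run covering the SNP
    empirical_p: float = float("nan")
    fdr_p: float = float("nan")


@dataclass(frozen=True)
class ConsensusRegion:
    """Merged interval of overlapping runs with its carriers per breed."""

    chrom: str
    start_bp: int
    end_bp: int
    member_runs: tuple[Run, ...]
    kind: str

    @property
    def carriers(self) -> frozenset[str]:
        return frozenset(r.sample_id for r in self.member_runs)

    @property
    def breeds(self) -> frozenset[str]:
        return frozenset(r.breed for r in self.member_runs)

    @property
    def shared(self) -> bool:
        """Carried in at least two breeds."""
        return len(self.breeds) >= 2

    @property
    def region_id(self) -> str:
        return f"{self.kind}_{self.chrom}:{self.start_bp}-{self.end_bp}"

    def carrier_fraction(self, n_individuals: int) -> float:
        return len(self.carriers) / n_individuals


def snp_incidence(runs: list[Run], g: GenotypeMatrix) -> list[SnpIncidence]:
    """Fraction of individuals whose runs cover each SNP.

    ``runs`` should come from one breed and one run kind; every sample of
    ``g`` counts in the denominator.
    """
    n = g.n_samples
    table = g.gmap.table
    cover = np.zeros(g.n_snps, dtype=np.int64)
    by_sample_chrom: dict[tuple[str, str], list[Run]] = {}
    for r in runs:
        by_sample_chrom.setdefault((r.sample_id, r.chrom), []).append(r)
    for chrom in g.gmap.chromosomes:
        idx = g.gmap.chrom_slice(chrom)
        pos = table["pos"].to_numpy()[idx]
        for sample in g.samples:
            covered = np.zeros(pos.size, dtype=bool)
            for r in by_sample_chrom.get((sample, chrom), ()):
                covered |= (pos >= r.start_bp) & (pos <= r.end_bp)
            cover[idx] += covered
    return [
        SnpIncidence(
            snp_id=table["snp_id"].iloc[j],
            chrom=table["chrom"].iloc[j],
            pos=int(table["pos"].iloc[j]),
            occurrence=cover[j] / n,
        )
        for j in range(g.n_snps)
    ]


def empirical_fdr(incidences: list[SnpIncidence]) -> list[SnpIncidence]:
    """Attach rank-based empirical p-values and BH-adjusted p-values.

    The empirical p-value of a SNP is the classical one-sided construction
    ``(number of SNPs with strictly higher occurrence + 1) / n``: the SNP
    with the highest occurrence gets p = 1/n, and tied SNPs share the
    minimum rank of their tie group.  Adjustment is Benjamini-Hochberg
    step-up over all SNPs.  With the minimum-rank convention a plateau of k
    tied top SNPs is adjusted to 1/k, so genuinely extended high-occurrence
    regions can clear a stringent FDR cut-off while isolated ranks cannot
    (average-rank ties would pin every adjusted value above 0.5 and make
    the cut-off unreachable).
    """
    if len(incidences) < 2:
        raise ValueError("need at least 2 SNPs for ranking")
    occ = np.array([s.occurrence for s in incidences])
    # descending occurrence -> ascending rank; min rank for ties
    ranks = rankdata(-occ, method="min")
    emp_p = ranks / occ.size
    _, fdr_p, _, _ = multipletests(emp_p, method="fdr_bh")
    return [
        SnpIncidence(s.snp_id, s.chrom, s.pos, s.occurrence,
                     float(emp_p[j]), float(fdr_p[j]))
        for j, s in enumerate(incidences)
    ]


def call_islands(
    incidences: list[SnpIncidence],
    runs: list[Run],
    alpha_fdr: float = 0.01,
    max_gap_bp: int = 500_000,
) -> list[ConsensusRegion]:
    """Call islands: intervals of significant SNPs located inside runs.

    A SNP is an island SNP when its FDR-adjusted empirical p-value is below
    ``alpha_fdr`` *and* at least one run covers its position.  Consecutive
    island SNPs on a chromosome with gaps at most ``max_gap_bp`` merge into
    one island interval; member runs are the runs overlapping the interval.
    """
    if not incidences:
        return []
    if any(np.isnan(s.fdr_p) for s in incidences):
        raise ValueError("run empirical_fdr first")
    kind = runs[0].kind if runs else "NA"
    runs_by_chrom: dict[str, list[Run]] = {}
    for r in runs:
        runs_by_chrom.setdefault(r.chrom, []).append(r)

    def covered(s: SnpIncidence) -> bool:
        return any(r.start_bp <= s.pos <= r.end_bp
                   for r in runs_by_chrom.get(s.chrom, ()))

    island_snps = [s for s in incidences
                   if s.fdr_p < alpha_fdr and covered(s)]
    regions: list[ConsensusRegion] = []
    by_chrom: dict[str, list[SnpIncidence]] = {}
    for s in island_snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, snps in by_chrom.items():
        snps.sort(key=lambda s: s.pos)
        block: list[SnpIncidence] = []
        for s in snps:
            if block and s.pos - block[-1].pos > max_gap_bp:
                regions.append(_close_island(chrom, block, runs_by_chrom, kind))
                block = []
            block.append(s)
        if block:
            regions.append(_close_island(chrom, block, runs_by_chrom, kind))
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return regions


def _close_island(chrom, block, runs_by_chrom, kind) -> ConsensusRegion:
    start, end = block[0].pos, block[-1].pos
    members = tuple(
        r for r in runs_by_chrom.get(chrom, ())
        if r.start_bp <= end and r.end_bp >= start
    )
    return ConsensusRegion(chrom, start, end, members, kind)


def consensus_regions(
    runs: list[Run],
    min_reciprocal_overlap: float = 0.0,
) -> list[ConsensusRegion]:
    """Merge overlapping runs across individuals/breeds into regions.

    Single-linkage merging: two runs belong to the same region when their
    intervals overlap (optionally requiring a minimum reciprocal overlap
    fraction).  A region is *shared* when its member runs come from at
    least two breeds.  Output order is (chrom, start) and independent of
    the input run order.
    """
    regions: list[ConsensusRegion] = []
    by_chrom: dict[str, list[Run]] = {}
    for r in runs:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom],
                    key=lambda r: (r.start_bp, r.end_bp, r.sample_id))
        cluster: list[Run] = []
        cluster_end = -1
        for r in rs:
            if cluster and not _overlaps(r, cluster_end,
                                         min_reciprocal_overlap, cluster):
                regions.append(_close_region(chrom, cluster))
                cluster = []
                cluster_end = -1
            cluster.append(r)
            cluster_end = max(cluster_end, r.end_bp)
        if cluster:
            regions.append(_close_region(chrom, cluster))
    return regions


def _overlaps(r: Run, cluster_end: int, min_recip: float,
              cluster: list[Run]) -> bool:
    if r.start_bp > cluster_end:
        return False
    if min_recip <= 0:
        return True
    # reciprocal overlap against any member of the current cluster
    for m in cluster:
        ov = min(r.end_bp, m.end_bp) - max(r.start_bp, m.start_bp) + 1
        if ov > 0 and (ov / r.length_bp >= min_recip
                       and ov / m.length_bp >= min_recip):
            return True
    return False


def _close_region(chrom: str, cluster: list[Run]) -> ConsensusRegion:
    start = min(r.start_bp for r in cluster)
    end = max(r.end_bp for r in cluster)
    kind = cluster[0].kind
    members = tuple(sorted(cluster,
                           key=lambda r: (r.start_bp, r.end_bp, r.sample_id)))
    return ConsensusRegion(chrom, start, end, members, kind)


def regions_to_frame(regions: list[ConsensusRegion],
                     n_individuals: int | None = None) -> pd.DataFrame:
    rows = []
    for reg in regions:
        row = {
            "region_id": reg.region_id, "chrom": reg.chrom,
            "start_bp": reg.start_bp, "end_bp": reg.end_bp,
            "kind": reg.kind, "n_carriers": len(reg.carriers),
            "n_breeds": len(reg.breeds),
            "shared": reg.shared,
            "breeds": ",".join(sorted(reg.breeds)),
        }
        if n_individuals:
            row["carrier_fraction"] = reg.carrier_fraction(n_individuals)
        rows.append(row)
    return pd.DataFrame(rows)
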