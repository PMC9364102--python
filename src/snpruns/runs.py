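"""Detection of runs of heterozygosity (ROHet) and homozygosity (ROH).

ROHet are called with a *consecutive* strategy: maximal stretches of
heterozygous calls uninterrupted by homozygous or missing genotypes, with a
cap on the physical gap between adjacent SNPs.  ROH are called with a
*sliding-window* strategy: a fixed-size SNP window slides along the
chromosome, each SNP is scored by the fraction of covering windows that are
fully homozygous, and stretches of eligible SNPs become candidate runs
subject to length, SNP-count and SNP-density thresholds.

The minimum number of SNPs for a ROH is derived from the false-positive
bound

    l = ln( alpha / (n_s * n_i) ) / ln(1 - het_bar)

where ``alpha`` is the accepted genome-wide false-positive rate, ``n_s`` the
number of SNPs per individual, ``n_i`` the number of individuals and
``het_bar`` the mean heterozygosity across SNPs.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from snpruns.genotypes import GenotypeMatrix, HET, MISSING

ROHET = "ROHet"
ROH = "ROH"

#: total autosomal length covered by a typical porcine 50K panel, in bp
DEFAULT_L_AUTO_BP = 2_452_000_000

#: length class edges in Mb; classes are (1-2], (2-4], (4-8], (8-16], >16
LENGTH_CLASS_EDGES_MB = (1.0, 2.0, 4.0, 8.0, 16.0)
LENGTH_CLASS_LABELS = ("1-2 Mb", "2-4 Mb", "4-8 Mb", "8-16 Mb", "> 16 Mb")


@dataclass(frozen=True)
class RunParams:
    """Parameters controlling run detection.

    ``min_snps`` for ROHet defaults to 16 (strictly more than 15 SNPs); for
    ROH it should be set from :func:`min_snp_threshold` or explicitly.
    ``window_snps``, ``window_hit_threshold`` and ``min_density_snps_per_mb``
    apply to the sliding-window ROH strategy only.
    """

    kind: str
    min_length_bp: int = 1_000_000
    min_snps: int = 16
    max_gap_bp: int = 500_000
    window_snps: int = 50
    max_opposite_calls: int = 0
    max_missing_calls: int = 0
    min_density_snps_per_mb: float = 2.0
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in (ROHET, ROH):
            raise ValueError(f"kind must be {ROHET!r} or {ROH!r}")
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        for name in ("min_snps", "max_gap_bp", "window_snps",
                     "max_opposite_calls", "max_missing_calls"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Run:
    """One detected run in one individual (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    kind: str
    breed: str = "NA"

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass(frozen=True)
class MinSnpInputs:
    """Inputs to the minimum-SNP false-positive bound."""

    alpha: float
    n_snps_per_individual: int
    n_individuals: int
    mean_het: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_snps_per_individual < 1 or self.n_individuals < 1:
            raise ValueError("counts must be >= 1")
        if not 0 < self.mean_het < 1:
            raise ValueError("mean_het must lie strictly in (0, 1)")


def min_snp_threshold(inp: MinSnpInputs, rounding: str = "floor") -> int:
    """Minimum number of homozygous SNPs for a ROH to be trusted.

    Evaluates ``ln(alpha / (n_s * n_i)) / ln(1 - het_bar)`` and rounds down
    (or to nearest, with ``rounding='round'``); the result is at least 1.
    """
    num = math.log(inp.alpha / (inp.n_snps_per_individual * inp.n_individuals))
    den = math.log(1.0 - inp.mean_het)
    l = num / den
    if rounding == "floor":
        value = math.floor(l)
    elif rounding == "round":
        value = round(l)
    else:
        raise ValueError("rounding must be 'floor' or 'round'")
    return max(1, int(value))


def _stretch_bounds(idx: np.ndarray, pos: np.ndarray, max_gap_bp: int):
    """Split sorted SNP indices into maximal blocks with gaps <= max_gap_bp.

    ``idx`` are indices into ``pos`` that must be consecutive integers to be
    part of one block (an excluded SNP between them breaks the block).
    """
    if idx.size == 0:
        return
    breaks = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(pos[idx]) > max_gap_bp)
    )
    start = 0
    for b in breaks:
        yield idx[start:b + 1]
        start = b + 1
    yield idx[start:]


def detect_rohet(g: GenotypeMatrix, params: RunParams) -> list[Run]:
    """Detect heterozygosity-rich runs with the consecutive strategy.

    Per individual and chromosome, maximal stretches of heterozygous calls
    containing no homozygous and no missing genotype, with inter-SNP gaps at
    most ``max_gap_bp``, are kept when they span at least ``min_length_bp``
    and contain at least ``min_snps`` SNPs.  Run boundaries are the first
    and last SNP positions of the stretch.
    """
    if params.kind != ROHET:
        raise ValueError("params.kind must be 'ROHet'")
    runs: list[Run] = []
    for chrom in g.gmap.chromosomes:
        snp_idx = g.gmap.chrom_slice(chrom)
        pos = g.gmap.table["pos"].to_numpy()[snp_idx]
        sub = g.calls[:, snp_idx]
        for i, sample in enumerate(g.samples):
            het_local = np.flatnonzero(sub[i] == HET)
            for block in _stretch_bounds(het_local, pos, params.max_gap_bp):
                start, end = int(pos[block[0]]), int(pos[block[-1]])
                if (end - start + 1 >= params.min_length_bp
                        and block.size >= params.min_snps):
                    runs.append(Run(sample, chrom, start, end,
                                    int(block.size), ROHET, g.breeds[i]))
    return runs


def _roh_eligible_snps(calls_row: np.ndarray, params: RunParams) -> np.ndarray:
    """Boolean eligibility per SNP from the sliding-window vote.

    Windows of ``window_snps`` consecutive SNPs (truncated to the chromosome
    when it holds fewer SNPs) are *compatible* when they contain at most
    ``max_opposite_calls`` heterozygotes and ``max_missing_calls`` missing
    calls.  A SNP is eligible when the fraction of covering windows that are
    compatible reaches ``window_hit_threshold``.
    """
    n = calls_row.size
    w = min(params.window_snps, n)
    het = (calls_row == HET).astype(np.int32)
    mis = (calls_row == MISSING).astype(np.int32)
    # rolling sums over all n-w+1 windows
    kern = np.ones(w, dtype=np.int32)
    het_in_win = np.convolve(het, kern, mode="valid")
    mis_in_win = np.convolve(mis, kern, mode="valid")
    compatible = ((het_in_win <= params.max_opposite_calls)
                  & (mis_in_win <= params.max_missing_calls)).astype(np.int32)
    # windows covering SNP j are those with start in [j-w+1, j]
    cover_hits = np.convolve(compatible, np.ones(w, dtype=np.int32),
                             mode="full")[:n]
    n_windows = compatible.size
    starts_lo = np.maximum(0, np.arange(n) - w + 1)
    starts_hi = np.minimum(n_windows - 1, np.arange(n))
    n_cover = starts_hi - starts_lo + 1
    frac = cover_hits / n_cover
    return frac >= params.window_hit_threshold


def detect_roh(g: GenotypeMatrix, params: RunParams) -> list[Run]:
    """Detect runs of homozygosity with the sliding-window strategy.

    See :func:`_roh_eligible_snps` for the window vote.  Maximal stretches
    of consecutive eligible SNPs with inter-SNP gaps at most ``max_gap_bp``
    become candidates; candidates are kept when they span at least
    ``min_length_bp``, contain at least ``min_snps`` SNPs and reach a SNP
    density of ``min_density_snps_per_mb``.
    """
    if params.kind != ROH:
        raise ValueError("params.kind must be 'ROH'")
    runs: list[Run] = []
    for chrom in g.gmap.chromosomes:
        snp_idx = g.gmap.chrom_slice(chrom)
        pos = g.gmap.table["pos"].to_numpy()[snp_idx]
        sub = g.calls[:, snp_idx]
        for i, sample in enumerate(g.samples):
            eligible = _roh_eligible_snps(sub[i], params)
            # missing calls can never sit inside a run when none are allowed
            if params.max_missing_calls == 0:
                eligible &= sub[i] != MISSING
            if params.max_opposite_calls == 0:
                eligible &= sub[i] != HET
            idx = np.flatnonzero(eligible)
            for block in _stretch_bounds(idx, pos, params.max_gap_bp):
                start, end = int(pos[block[0]]), int(pos[block[-1]])
                length = end - start + 1
                if length < params.min_length_bp:
                    continue
                if block.size < params.min_snps:
                    continue
                if block.size / (length / 1e6) < params.min_density_snps_per_mb:
                    continue
                runs.append(Run(sample, chrom, start, end,
                                int(block.size), ROH, g.breeds[i]))
    return runs


def postfilter_runs(
    runs: list[Run],
    n_individuals: int,
    min_snps_abs: int = 5,
    min_carrier_fraction: float = 0.05,
) -> list[Run]:
    """Drop runs with fewer than ``min_snps_abs`` SNPs or in rare regions.

    Runs are merged into population-level consensus regions (single-linkage
    interval overlap); a run is kept only when its region is carried by at
    least ``min_carrier_fraction`` of the ``n_individuals``.
    """
    from snpruns.islands import consensus_regions

    runs = [r for r in runs if r.n_snps >= min_snps_abs]
    if not runs:
        return []
    regions = consensus_regions(runs)
    kept: list[Run] = []
    for region in regions:
        carriers = {r.sample_id for r in region.member_runs}
        if len(carriers) / n_individuals >= min_carrier_fraction:
            kept.extend(region.member_runs)
    kept.sort(key=lambda r: (r.chrom, r.start_bp, r.sample_id))
    return kept


def classify_lengths(runs: list[Run]) -> pd.DataFrame:
    """Summarise runs into the five length classes.

    Classes partition [1 Mb, inf) with upper-inclusive bounds: (1-2], (2-4],
    (4-8], (8-16] and >16 Mb.  Returns a table with count, percentage
    (rounded to 2 decimals; NaN when there are no runs) and mean length in
    Mb per class.
    """
    lengths_mb = np.array([r.length_mb for r in runs])
    edges = LENGTH_CLASS_EDGES_MB
    rows = []
    total = len(runs)
    for k, label in enumerate(LENGTH_CLASS_LABELS):
        lo = edges[k]
        hi = edges[k + 1] if k + 1 < len(edges) else math.inf
        in_class = (lengths_mb > lo) & (lengths_mb <= hi)
        count = int(in_class.sum())
        pct = round(100.0 * count / total, 2) if total else math.nan
        mean_mb = float(lengths_mb[in_class].mean()) if count else math.nan
        rows.append({"length_class": label, "count": count,
                     "percentage": pct, "mean_length_mb": mean_mb})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FrohResult:
    """Genomic inbreeding of one individual: total ROH length over L_AUTO."""

    sample_id: str
    sum_roh_bp: int
    l_auto_bp: int

    @property
    def f_roh(self) -> float:
        return self.sum_roh_bp / self.l_auto_bp


def compute_froh(
    runs: list[Run],
    samples: list[str],
    l_auto_bp: int = DEFAULT_L_AUTO_BP,
) -> list[FrohResult]:
    """Per-individual F_ROH = sum of ROH lengths / autosomal length.

    Individuals in ``samples`` without any ROH get F_ROH = 0.
    """
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    totals: dict[str, int] = defaultdict(int)
    for r in runs:
        if r.kind != ROH:
            raise ValueError("compute_froh expects ROH runs")
        totals[r.sample_id] += r.length_bp
    return [FrohResult(s, totals.get(s, 0), l_auto_bp) for s in samples]


def runs_to_frame(runs: list[Run]) -> pd.DataFrame:
    """Runs as a tidy table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            {"sample_id": r.sample_id, "breed": r.breed, "chrom": r.chrom,
             "start_bp": r.start_bp, "end_bp": r.end_bp,
             "n_snps": r.n_snps, "length_bp": r.length_bp, "kind": r.kind}
            for r in runs
        ]
    )
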