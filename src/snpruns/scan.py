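"""Windowed nucleotide diversity, Weir-Cockerham F_ST and trait correlation.

Diversity per site uses the unbiased heterozygosity ``n/(n-1) * 2p(1-p)``
over ``n`` non-missing alleles; a window's theta-pi is the sum of site
values divided by the window span in bp.  F_ST uses the Weir & Cockerham
(1984) variance components a (among populations), b (among individuals
within populations) and c (within individuals), combined over a window as
the ratio of sums  sum(a) / sum(a + b + c)  — the "weighted" estimate.
Windows are 50 kb with a 10 kb step by default.

For selection-vs-trait analysis, the median log diversity ratio
``ln(pi_pop1 / pi_pop2)`` over the windows overlapping a region is
correlated (Pearson) with the difference in breed mean trait value across
breed pairs; pairs sharing a breed are not independent, so the t-test
p-value is a guide, and a permutation p-value is offered alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from snpruns.genotypes import GenotypeMatrix, HET, MISSING


@dataclass(frozen=True)
class WindowStat:
    chrom: str
    start_bp: int
    end_bp: int
    n_variants: int
    pi_pop1: float
    pi_pop2: float
    fst: float

    @property
    def log_pi_ratio(self) -> float:
        if (self.pi_pop1 is None or self.pi_pop2 is None
                or not self.pi_pop1 > 0 or not self.pi_pop2 > 0):
            return math.nan
        return math.log(self.pi_pop1 / self.pi_pop2)


def _site_stats(g: GenotypeMatrix):
    """Per-site allele counts: n alleles, alt dosage, het individuals."""
    calls = g.calls
    valid = calls != MISSING
    n_ind = valid.sum(axis=0)
    n_alleles = 2 * n_ind
    alt = np.where(valid, calls, 0).sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    return n_alleles, alt, n_het, n_ind


def _site_pi(g: GenotypeMatrix) -> np.ndarray:
    """Unbiased per-site diversity n/(n-1) * 2 p (1-p), NaN when n < 2."""
    n_alleles, alt, _, _ = _site_stats(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n_alleles
        pi = n_alleles / (n_alleles - 1.0) * 2.0 * p * (1.0 - p)
    pi[n_alleles < 2] = np.nan
    return pi


def _windows(chrom_len_pos: np.ndarray, window_bp: int, step_bp: int):
    """Window (start, end) pairs covering the observed positions, 1-based."""
    if chrom_len_pos.size == 0:
        return
    last = int(chrom_len_pos.max())
    start = 1
    while start <= last:
        yield start, start + window_bp - 1
        start += step_bp


def _wc_site_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) a, b, c for two populations at one site.

    ``n`` are diploid sample sizes, ``p`` alt-allele frequencies and ``h``
    observed heterozygote frequencies; vectorized over sites.
    """
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) \
            / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0)
            / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - (r - 1.0) / r * s2
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    return a, b, c


def _pair_site_arrays(pop1: GenotypeMatrix, pop2: GenotypeMatrix):
    if not pop1.gmap.table[["snp_id", "chrom", "pos"]].equals(
            pop2.gmap.table[["snp_id", "chrom", "pos"]]):
        raise ValueError("populations must share the same site set")
    n_all1, alt1, het1, n_ind1 = _site_stats(pop1)
    n_all2, alt2, het2, n_ind2 = _site_stats(pop2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt1 / n_all1
        p2 = alt2 / n_all2
        h1 = het1 / n_ind1
        h2 = het2 / n_ind2
    return n_ind1, p1, h1, n_ind2, p2, h2


def windowed_pi(
    g: GenotypeMatrix,
    window_bp: int = 50_000,
    step_bp: int = 10_000,
) -> pd.DataFrame:
    """Per-window nucleotide diversity: sum of site pi over the span in bp."""
    pi = _site_pi(g)
    table = g.gmap.table
    rows = []
    for chrom in g.gmap.chromosomes:
        idx = g.gmap.chrom_slice(chrom)
        pos = table["pos"].to_numpy()[idx]
        site_pi = pi[idx]
        for start, end in _windows(pos, window_bp, step_bp):
            in_win = (pos >= start) & (pos <= end)
            vals = site_pi[in_win]
            usable = vals[np.isfinite(vals)]
            n_var = int(in_win.sum())
            theta = (float(usable.sum()) / window_bp
                     if usable.size else math.nan)
            rows.append({"chrom": chrom, "start_bp": start, "end_bp": end,
                         "n_variants": n_var, "pi": theta})
    return pd.DataFrame(rows)


def windowed_fst(
    pop1: GenotypeMatrix,
    pop2: GenotypeMatrix,
    window_bp: int = 50_000,
    step_bp: int = 10_000,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham F_ST plus per-population diversity.

    Returns one row per window with n_variants, pi_pop1, pi_pop2, fst and
    log_pi_ratio; windows without usable sites (or where both populations
    are monomorphic, making the F_ST denominator zero) carry NaN.
    """
    n1, p1, h1, n2, p2, h2 = _pair_site_arrays(pop1, pop2)
    a, b, c = _wc_site_components(n1, p1, h1, n2, p2, h2)
    pi1 = _site_pi(pop1)
    pi2 = _site_pi(pop2)
    table = pop1.gmap.table
    rows = []
    for chrom in pop1.gmap.chromosomes:
        idx = pop1.gmap.chrom_slice(chrom)
        pos = table["pos"].to_numpy()[idx]
        for start, end in _windows(pos, window_bp, step_bp):
            in_win = np.flatnonzero((pos >= start) & (pos <= end))
            sites = idx[in_win]
            usable = sites[np.isfinite(a[sites] + b[sites] + c[sites])]
            num = float(a[usable].sum()) if usable.size else math.nan
            den = float((a[usable] + b[usable] + c[usable]).sum()) \
                if usable.size else math.nan
            fst = num / den if usable.size and den != 0.0 else math.nan
            v1 = pi1[sites]
            v2 = pi2[sites]
            t1 = (float(v1[np.isfinite(v1)].sum()) / window_bp
                  if np.isfinite(v1).any() else math.nan)
            t2 = (float(v2[np.isfinite(v2)].sum()) / window_bp
                  if np.isfinite(v2).any() else math.nan)
            log_ratio = (math.log(t1 / t2)
                         if t1 and t2 and t1 > 0 and t2 > 0 else math.nan)
            rows.append({"chrom": chrom, "start_bp": start, "end_bp": end,
                         "n_variants": int(in_win.size),
                         "pi_pop1": t1, "pi_pop2": t2, "fst": fst,
                         "log_pi_ratio": log_ratio})
    return pd.DataFrame(rows)


def genome_fst(pop1: GenotypeMatrix, pop2: GenotypeMatrix) -> float:
    """Genome-wide weighted Weir-Cockerham estimate over all usable sites."""
    n1, p1, h1, n2, p2, h2 = _pair_site_arrays(pop1, pop2)
    a, b, c = _wc_site_components(n1, p1, h1, n2, p2, h2)
    usable = np.isfinite(a + b + c)
    den = float((a[usable] + b[usable] + c[usable]).sum())
    if den == 0.0:
        return math.nan
    return float(a[usable].sum()) / den


def region_median_ratio(
    windows: pd.DataFrame,
    chrom: str,
    start_bp: int,
    end_bp: int,
) -> float:
    """Median log diversity ratio over windows overlapping the region.

    Overlap is any bp intersection; NaN windows are excluded from the
    median.  Raises when no usable window overlaps.
    """
    sel = windows.loc[
        (windows["chrom"] == chrom)
        & (windows["start_bp"] <= end_bp)
        & (windows["end_bp"] >= start_bp),
        "log_pi_ratio",
    ].dropna()
    if sel.empty:
        raise ValueError("no non-NA window overlaps the region")
    return float(sel.median())


def correlate_with_traits(
    median_ratios: np.ndarray,
    trait_differences: np.ndarray,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Pearson correlation between region diversity ratios and trait gaps.

    One value per breed pair on each axis; at least 3 pairs are required.
    Returns r, the two-sided t-test p-value, and (optionally) a permutation
    p-value from shuffling the trait differences.  Pairs sharing a breed
    are not independent; ``independent`` is flagged False in the output.
    """
    x = np.asarray(median_ratios, dtype=float)
    y = np.asarray(trait_differences, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 breed pairs with both values")
    tiny = 1e-12
    if (np.std(x) <= tiny * max(1.0, abs(float(np.mean(x))))
            or np.std(y) <= tiny * max(1.0, abs(float(np.mean(y))))):
        return {"r": math.nan, "p_value": math.nan,
                "p_permutation": math.nan, "n_pairs": int(x.size),
                "independent": False}
    r, p = stats.pearsonr(x, y)
    out = {"r": float(r), "p_value": float(p), "n_pairs": int(x.size),
           "independent": False, "p_permutation": math.nan}
    if n_permutations > 0:
        rng = rng or np.random.default_rng(0)
        count = 0
        for _ in range(n_permutations):
            rp, _ = stats.pearsonr(x, rng.permutation(y))
            if abs(rp) >= abs(r):
                count += 1
        out["p_permutation"] = (count + 1) / (n_permutations + 1)
    return out
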