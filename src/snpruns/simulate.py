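"""Synthetic genotypes, litter records and divergent population pairs.

The generator emulates the statistical structure the analysis assumes
without modelling linkage disequilibrium: background genotypes are
independent Hardy-Weinberg draws at per-SNP allele frequencies, and the run
structure is supplied by *planted* homozygous or heterozygous segments of
known coordinates which overwrite the background calls.  This keeps the
truth set unambiguous for recall/precision checks.

Phenotypes follow a repeatability model: repeated litter records per sow
with breed, farm-year-season (64 levels by default) and parity fixed
effects, an additive sow effect (optionally correlated through a genomic
relationship matrix), a permanent-environment sow effect, optional region
presence effects, and a per-sow residual whose standard deviation can be
made heterogeneous so that log-variance traits are recoverable.

Divergent population pairs are drawn from the Balding-Nichols model: each
SNP's two population frequencies are Beta draws around a shared ancestral
frequency with spread set by the target fixation index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from snpruns.genotypes import (
    GenomicMap,
    GenotypeMatrix,
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
)


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class PlantedSegment:
    """A genotype segment overwritten in a set of individuals.

    ``individuals`` are integer sample indices; ``kind`` is ``homozygous``
    (no heterozygous call inside) or ``heterozygous`` (every non-missing
    call heterozygous).  Coordinates are 1-based inclusive.
    """

    individuals: tuple[int, ...]
    chrom: str
    start_bp: int
    end_bp: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("homozygous", "heterozygous"):
            raise ConfigError("segment kind must be homozygous/heterozygous")
        if self.end_bp < self.start_bp:
            raise ConfigError("segment end before start")


def _default_chromosomes() -> dict[str, int]:
    # three autosomes totalling 300 Mb keep desk-scale runs fast while
    # leaving room for multi-Mb planted segments
    return {"1": 120_000_000, "2": 100_000_000, "3": 80_000_000}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; every draw is governed by ``seed``.

    Variances are on the scale of the litter traits (piglets per litter);
    ``sigma2_e`` defaults to 9 (residual SD of 3 piglets, a realistic
    figure for total number born).  ``mean_het`` is the target mean
    heterozygosity across SNPs; background allele frequencies are Beta
    draws whose expected heterozygosity equals the target.
    """

    n_individuals: dict[str, int] = field(
        default_factory=lambda: {"BreedA": 100})
    n_snps: int = 10_000
    chromosome_lengths_bp: dict[str, int] = field(
        default_factory=_default_chromosomes)
    mean_het: float = 0.20
    planted_segments: list[PlantedSegment] = field(default_factory=list)
    missing_rate: float = 0.01
    family_size: int = 1  # >1 groups individuals into full-sib families
    # phenotype model
    breed_effects: dict[str, float] | None = None
    n_fys: int = 64
    fys_sd: float = 1.0
    parity_effects: tuple[float, ...] = (0.0, 0.6, 0.9, 1.0, 0.9, 0.6, 0.2,
                                         -0.3)
    trait_mean: float = 12.0
    mortality: float = 0.08
    sigma2_b: float = 1.0
    sigma2_pe: float = 1.0
    sigma2_e: float = 9.0
    n_parities: int = 8
    records_per_parity: int = 1
    region_betas: dict[str, float] = field(default_factory=dict)
    # divergent pair
    fst_target: float = 0.1
    n_per_pop: int = 50
    low_diversity_window: tuple[str, int, int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_b", "sigma2_pe", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.mean_het < 0.5:
            raise ConfigError("mean_het must lie in (0, 0.5)")
        if not 0 <= self.fst_target < 1:
            raise ConfigError("fst_target must lie in [0, 1)")
        for seg in self.planted_segments:
            if seg.chrom not in self.chromosome_lengths_bp:
                raise ConfigError(f"segment on unknown chromosome {seg.chrom}")
            if seg.end_bp > self.chromosome_lengths_bp[seg.chrom]:
                raise ConfigError("segment exceeds chromosome length")
        self._check_contradictions()

    def _check_contradictions(self) -> None:
        segs = self.planted_segments
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                a, b = segs[i], segs[j]
                if (a.kind != b.kind and a.chrom == b.chrom
                        and a.start_bp <= b.end_bp and b.start_bp <= a.end_bp
                        and set(a.individuals) & set(b.individuals)):
                    raise ConfigError(
                        "contradictory overlapping planted segments for one "
                        f"individual on chromosome {a.chrom}"
                    )


@dataclass
class TruthTable:
    """Ground truth recorded alongside each simulated dataset."""

    planted_segments: list[PlantedSegment] = field(default_factory=list)
    segment_samples: list[tuple[str, ...]] = field(default_factory=list)
    snp_alt_freq: np.ndarray | None = None  # drawn background frequencies
    het_per_snp_count: np.ndarray | None = None  # realized het calls per SNP
    region_betas: dict[str, float] = field(default_factory=dict)
    sow_residual_sd: dict[str, float] = field(default_factory=dict)
    pop1_freq: np.ndarray | None = None
    pop2_freq: np.ndarray | None = None
    low_diversity_window: tuple[str, int, int, float] | None = None


def _beta_shape_for_het(target_het: float) -> float:
    # for p ~ Beta(a, a), E[2 p (1-p)] = a / (2a + 1); invert for a
    return target_het / (1.0 - 2.0 * target_het)


def _draw_map(cfg: SyntheticConfig, rng: np.random.Generator) -> GenomicMap:
    lens = cfg.chromosome_lengths_bp
    total = sum(lens.values())
    rows = []
    snp_no = 0
    remaining = cfg.n_snps
    items = list(lens.items())
    for k, (chrom, length) in enumerate(items):
        n_here = (remaining if k == len(items) - 1
                  else int(round(cfg.n_snps * length / total)))
        n_here = min(n_here, remaining)
        remaining -= n_here
        pos = np.sort(rng.choice(length, size=n_here, replace=False) + 1)
        for p in pos:
            rows.append({"snp_id": f"snp{snp_no}", "chrom": chrom,
                         "pos": int(p)})
            snp_no += 1
    return GenomicMap(pd.DataFrame(rows))


def _hwe_dosages(freq: np.ndarray, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, freq[None, :], size=(n, freq.size)).astype(np.int8)


def _family_dosages(freq: np.ndarray, n: int, family_size: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Full-sib families: two HWE parents per family, Mendelian children."""
    m = freq.size
    out = np.empty((n, m), dtype=np.int8)
    done = 0
    while done < n:
        k = min(family_size, n - done)
        sire = rng.binomial(2, freq)
        dam = rng.binomial(2, freq)
        for _ in range(k):
            child = (rng.binomial(1, sire / 2.0)
                     + rng.binomial(1, dam / 2.0))
            out[done] = child.astype(np.int8)
            done += 1
    return out


def simulate_genotypes(
    cfg: SyntheticConfig,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Background Hardy-Weinberg genotypes with planted run segments.

    Homozygous planted segments set every call in the interval homozygous;
    heterozygous segments set every call heterozygous.  Missing calls are
    injected uniformly at ``cfg.missing_rate`` outside planted segments so
    that planted truth stays unambiguous.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    gmap = _draw_map(cfg, rng)
    a = _beta_shape_for_het(cfg.mean_het)
    freq = rng.beta(a, a, size=cfg.n_snps)
    samples: list[str] = []
    breeds: list[str] = []
    blocks = []
    for breed, n in cfg.n_individuals.items():
        samples += [f"{breed}_{i}" for i in range(n)]
        breeds += [breed] * n
        if cfg.family_size > 1:
            blocks.append(_family_dosages(freq, n, cfg.family_size, rng))
        else:
            blocks.append(_hwe_dosages(freq, n, rng))
    calls = np.concatenate(blocks, axis=0)

    pos_all = gmap.table["pos"].to_numpy()
    chrom_all = gmap.table["chrom"].to_numpy()
    planted_mask = np.zeros(calls.shape, dtype=bool)
    seg_samples: list[tuple[str, ...]] = []
    for seg in cfg.planted_segments:
        snp_sel = ((chrom_all == seg.chrom) & (pos_all >= seg.start_bp)
                   & (pos_all <= seg.end_bp))
        cols = np.flatnonzero(snp_sel)
        for i in seg.individuals:
            if seg.kind == "heterozygous":
                calls[i, cols] = HET
            else:
                calls[i, cols] = np.where(freq[cols] > 0.5, HOM_MINOR,
                                          HOM_MAJOR)
            planted_mask[i, cols] = True
        seg_samples.append(tuple(samples[i] for i in seg.individuals))

    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        miss &= ~planted_mask
        calls[miss] = MISSING

    g = GenotypeMatrix(samples, breeds, gmap, calls).reorient_by_frequency()
    truth = TruthTable(
        planted_segments=list(cfg.planted_segments),
        segment_samples=seg_samples,
        snp_alt_freq=freq,
        het_per_snp_count=(g.calls == HET).sum(axis=0),
    )
    return g, truth


def simulate_litter_records(
    cfg: SyntheticConfig,
    presence: pd.DataFrame | None = None,
    grm: np.ndarray | None = None,
    residual_sd: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """Repeated litter records per sow under a repeatability model.

    ``presence`` is a sows x regions 0/1 frame (index = sow ids); region
    effect sizes come from ``cfg.region_betas`` (zero for regions not
    listed).  When ``grm`` is given, additive sow effects are drawn from
    N(0, G sigma2_b); otherwise sows are treated as unrelated.
    ``residual_sd`` (one value per sow, in presence/row order) overrides the
    homogeneous residual SD to plant log-variance differences.

    Records carry TNB (total number born, integer >= 1), NBA (born alive)
    and TND (born dead) with TNB = NBA + TND, plus the latent continuous
    phenotype ``y_latent`` used by calibration checks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    if presence is None:
        n_sows = sum(cfg.n_individuals.values())
        sow_ids = [f"{b}_{i}" for b, n in cfg.n_individuals.items()
                   for i in range(n)]
        presence = pd.DataFrame(index=sow_ids)
    else:
        sow_ids = list(presence.index)
        n_sows = len(sow_ids)
    sow_breed = {s: s.rsplit("_", 1)[0] for s in sow_ids}
    breed_eff = cfg.breed_effects or {
        b: i * 0.5 for i, b in enumerate(cfg.n_individuals)}
    fys_eff = rng.normal(0.0, cfg.fys_sd, size=cfg.n_fys)

    if grm is not None:
        if grm.shape != (n_sows, n_sows):
            raise ConfigError("grm shape does not match the sow set")
        l_chol = np.linalg.cholesky(grm + 1e-8 * np.eye(n_sows))
        b_add = math.sqrt(cfg.sigma2_b) * (l_chol @ rng.standard_normal(n_sows))
    else:
        b_add = rng.normal(0.0, math.sqrt(cfg.sigma2_b), size=n_sows)
    pe = rng.normal(0.0, math.sqrt(cfg.sigma2_pe), size=n_sows)
    if residual_sd is None:
        res_sd = np.full(n_sows, math.sqrt(cfg.sigma2_e))
    else:
        res_sd = np.asarray(residual_sd, dtype=float)
        if res_sd.size != n_sows:
            raise ConfigError("residual_sd length does not match sows")

    betas = np.array([cfg.region_betas.get(c, 0.0)
                      for c in presence.columns])
    region_term = (presence.to_numpy(dtype=float) @ betas
                   if len(presence.columns) else np.zeros(n_sows))

    rows = []
    for s_idx, sow in enumerate(sow_ids):
        for parity in range(1, cfg.n_parities + 1):
            for _ in range(cfg.records_per_parity):
                fys = int(rng.integers(cfg.n_fys))
                e = rng.normal(0.0, res_sd[s_idx])
                latent = (cfg.trait_mean
                          + breed_eff.get(sow_breed[sow], 0.0)
                          + fys_eff[fys]
                          + cfg.parity_effects[(parity - 1)
                                               % len(cfg.parity_effects)]
                          + b_add[s_idx] + pe[s_idx]
                          + region_term[s_idx] + e)
                tnb = max(1, int(round(latent)))
                tnd = int(rng.binomial(tnb, cfg.mortality))
                rows.append({
                    "sow_id": sow, "breed": sow_breed[sow],
                    "fys": f"fys{fys}", "parity": parity,
                    "tnb": tnb, "nba": tnb - tnd, "tnd": tnd,
                    "y_latent": latent,
                })
    records = pd.DataFrame(rows)
    truth = TruthTable(
        region_betas=dict(cfg.region_betas),
        sow_residual_sd={s: float(res_sd[i]) for i, s in enumerate(sow_ids)},
    )
    return records, truth


def _balding_nichols(p_anc: np.ndarray, fst: float,
                     rng: np.random.Generator) -> np.ndarray:
    if fst == 0:
        return p_anc.copy()
    scale = (1.0 - fst) / fst
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def _scale_heterozygosity(p: np.ndarray, factor: float) -> np.ndarray:
    """Move frequencies toward fixation so 2q(1-q) = factor * 2p(1-p)."""
    h = 2.0 * p * (1.0 - p) * factor
    q = (1.0 - np.sqrt(np.maximum(0.0, 1.0 - 2.0 * h))) / 2.0
    return np.where(p <= 0.5, q, 1.0 - q)


def simulate_divergent_pair(
    cfg: SyntheticConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, TruthTable]:
    """Two populations at a target fixation index (Balding-Nichols draws).

    Optionally plants a window of locally reduced diversity in population 2
    (``cfg.low_diversity_window`` = (chrom, start, end, het factor)) to
    create a nucleotide-diversity-ratio signal.  Genotypes are REF/ALT
    oriented (code 2 counts the ALT allele whose frequency is recorded).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    gmap = _draw_map(cfg, rng)
    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    p1 = _balding_nichols(p_anc, cfg.fst_target, rng)
    p2 = _balding_nichols(p_anc, cfg.fst_target, rng)
    if cfg.low_diversity_window is not None:
        chrom, start, end, factor = cfg.low_diversity_window
        sel = ((gmap.table["chrom"] == chrom)
               & (gmap.table["pos"] >= start)
               & (gmap.table["pos"] <= end)).to_numpy()
        p2 = np.where(sel, _scale_heterozygosity(p2, factor), p2)
    n = cfg.n_per_pop
    g1 = GenotypeMatrix([f"p1_{i}" for i in range(n)], ["pop1"] * n, gmap,
                        _hwe_dosages(p1, n, rng))
    g2 = GenotypeMatrix([f"p2_{i}" for i in range(n)], ["pop2"] * n, gmap,
                        _hwe_dosages(p2, n, rng))
    truth = TruthTable(pop1_freq=p1, pop2_freq=p2,
                       low_diversity_window=cfg.low_diversity_window)
    return g1, g2, truth
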