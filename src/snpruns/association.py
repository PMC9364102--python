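"""Region presence/absence association with litter traits.

Each consensus region becomes a two-level fixed effect (presence = 1,
absence = 0) in the linear model

    y = breed + farm-year-season + region + e

fitted by ordinary least squares, one region at a time, on per-parity
records or per-sow log-variance traits.  Repeated records of a sow enter as
independent rows — the model deliberately has no sow effect, so p-values
for record-level traits are anti-conservative when records repeat; callers
comparing across regions should keep that in mind.

Multiple testing uses a Bonferroni threshold over the N regions tested for
one run kind: significant when p <= 0.05/N, suggestive when
0.05/N < p <= 1/N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from snpruns.islands import ConsensusRegion
from snpruns.runs import Run

SIGNIFICANT = "significant"
SUGGESTIVE = "suggestive"
NOT_SIGNIFICANT = "ns"


@dataclass(frozen=True)
class RegionPredictorSet:
    """Presence/absence predictors for the phenotyped individuals."""

    regions: tuple[ConsensusRegion, ...]
    presence: pd.DataFrame  # individuals x regions, values in {0, 1}
    carrier_fraction: pd.Series

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class AssociationResult:
    region_id: str
    trait: str
    parity: str  # "1".."8" or "pooled"
    effect: float
    se: float
    p_value: float
    n_records: int
    tier: str = NOT_SIGNIFICANT
    note: str = ""


def build_predictors(
    regions: list[ConsensusRegion],
    phenotyped_samples: list[str],
    min_freq: float = 0.01,
) -> RegionPredictorSet:
    """Presence matrix over phenotyped individuals, rare regions dropped.

    An individual is a carrier when at least one of its runs overlaps the
    region (region carriers are the samples of the member runs).  Regions
    carried by at most ``min_freq`` of the phenotyped individuals are
    dropped; the retained count N sets the Bonferroni threshold.
    """
    kept = []
    cols = {}
    fracs = {}
    sample_set = set(phenotyped_samples)
    for reg in regions:
        carriers = reg.carriers & sample_set
        frac = len(carriers) / len(phenotyped_samples)
        if frac > min_freq:
            kept.append(reg)
            cols[reg.region_id] = [
                1 if s in carriers else 0 for s in phenotyped_samples]
            fracs[reg.region_id] = frac
    if not kept:
        warnings.warn("no region passes the carrier-frequency filter")
    presence = pd.DataFrame(cols, index=list(phenotyped_samples), dtype=int)
    return RegionPredictorSet(tuple(kept), presence, pd.Series(fracs))


def fit_region_model(
    y: np.ndarray,
    breed: np.ndarray,
    fys: np.ndarray,
    presence: np.ndarray,
    region_id: str = "region",
    trait: str = "trait",
    parity: str = "pooled",
) -> AssociationResult:
    """OLS fit of one region term with breed and farm-year-season effects.

    Returns the region coefficient, its standard error and the two-sided
    t-test p-value.  When the region has no contrast (all carriers or all
    non-carriers) or is confounded with a fixed-effect level, the result
    carries NA values and an explanatory note.
    """
    y = np.asarray(y, dtype=float)
    presence = np.asarray(presence, dtype=float)
    ok = np.isfinite(y)
    y, breed, fys, presence = y[ok], np.asarray(breed)[ok], \
        np.asarray(fys)[ok], presence[ok]
    n = y.size
    if presence.min() == presence.max():
        return AssociationResult(region_id, trait, parity, math.nan,
                                 math.nan, math.nan, n,
                                 note="no presence/absence contrast")
    parts = [np.ones((n, 1))]
    for values in (breed, fys):
        d = pd.get_dummies(pd.Categorical(values), drop_first=True)
        if d.shape[1]:
            parts.append(d.to_numpy(dtype=float))
    X = np.concatenate(parts + [presence[:, None]], axis=1)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # try again without the region column: if the rank recovers, the
        # region is confounded with breed/farm-year-season
        base_rank = np.linalg.matrix_rank(X[:, :-1])
        note = ("region confounded with fixed effects"
                if base_rank == rank else "singular fixed-effect design")
        return AssociationResult(region_id, trait, parity, math.nan,
                                 math.nan, math.nan, n, note=note)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    if dof <= 0:
        return AssociationResult(region_id, trait, parity, math.nan,
                                 math.nan, math.nan, n,
                                 note="no residual degrees of freedom")
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(s2 * XtX_inv[-1, -1])
    t = beta[-1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return AssociationResult(region_id, trait, parity, float(beta[-1]),
                             se, float(p), n)


def tier_results(results: list[AssociationResult],
                 n_regions: int) -> list[AssociationResult]:
    """Assign Bonferroni tiers given N regions tested for this run kind.

    significant: p <= 0.05/N; suggestive: 0.05/N < p <= 1/N.  The p = 1/N
    boundary is classified suggestive.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    sig = 0.05 / n_regions
    sug = 1.0 / n_regions
    out = []
    for r in results:
        if math.isnan(r.p_value):
            tier = NOT_SIGNIFICANT
        elif r.p_value <= sig:
            tier = SIGNIFICANT
        elif r.p_value <= sug:
            tier = SUGGESTIVE
        else:
            tier = NOT_SIGNIFICANT
        out.append(replace(r, tier=tier))
    return out


def associate_regions(
    predictors: RegionPredictorSet,
    records: pd.DataFrame,
    traits: tuple[str, ...] = ("tnb", "nba", "tnd"),
    per_parity: bool = True,
    pooled: bool = True,
) -> list[AssociationResult]:
    """Run the region model for every region x trait x parity group.

    ``records`` must carry sow_id, breed, fys, parity and the trait columns;
    the presence row for a record is looked up by sow_id.  Results come
    back tier-annotated with N = number of regions in ``predictors``.
    """
    if predictors.n_regions == 0:
        return []
    pres = predictors.presence
    results: list[AssociationResult] = []
    groups: list[tuple[str, pd.DataFrame]] = []
    if pooled:
        groups.append(("pooled", records))
    if per_parity:
        for par, grp in records.groupby("parity", sort=True):
            groups.append((str(par), grp))
    for trait in traits:
        for parity_label, grp in groups:
            pr = pres.loc[grp["sow_id"]].to_numpy()
            for k, reg in enumerate(predictors.regions):
                results.append(fit_region_model(
                    grp[trait].to_numpy(), grp["breed"].to_numpy(),
                    grp["fys"].to_numpy(), pr[:, k],
                    region_id=reg.region_id, trait=trait,
                    parity=parity_label))
    return tier_results(results, predictors.n_regions)


def association_degree(results: list[AssociationResult]) -> pd.DataFrame:
    """Rank regions by their hit count across traits and parity groups.

    The degree of a region is the number of significant-or-suggestive
    results across all traits and parity groups; ties are broken by the
    smallest p-value.  Also returns -log10(p) per (region, trait, parity)
    in long form via the ``minus_log10_p`` column.
    """
    rows = []
    for r in results:
        rows.append({
            "region_id": r.region_id, "trait": r.trait, "parity": r.parity,
            "p_value": r.p_value,
            "minus_log10_p": (-math.log10(r.p_value)
                              if r.p_value and not math.isnan(r.p_value)
                              else math.nan),
            "hit": r.tier in (SIGNIFICANT, SUGGESTIVE),
        })
    long = pd.DataFrame(rows)
    summary = (
        long.groupby("region_id")
        .agg(n_hits=("hit", "sum"), min_p=("p_value", "min"))
        .sort_values(["n_hits", "min_p"], ascending=[False, True])
        .reset_index()
    )
    return summary.merge(long, on="region_id", how="left")
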