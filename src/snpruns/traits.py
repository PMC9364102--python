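"""Litter-size variability traits from a genomic repeatability model.

Per-record residuals come from the mixed model

    y = W a + Z b + U pe + e

with fixed effects ``a`` (farm-year-season and parity), additive sow
effects ``b ~ N(0, G sigma2_b)`` correlated through a genomic relationship
matrix G, permanent-environment sow effects ``pe ~ N(0, I sigma2_pe)`` and
residuals ``e ~ N(0, I sigma2_e)``.  The per-sow natural log of the sample
variance of the residuals (LnVar) is the litter variability trait.

Variance components are estimated by EM-REML on Henderson's mixed-model
equations with Aitken extrapolation to accelerate the terminal geometric
phase; components may instead be supplied and held fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from snpruns.genotypes import GenotypeMatrix, MISSING


def prepare_records(records: pd.DataFrame,
                    trait: str = "tnb") -> pd.DataFrame:
    """Apply the record edits: drop TNB = 0 and single-record sows."""
    out = records.loc[records["tnb"] > 0].copy()
    counts = out["sow_id"].value_counts()
    keep = counts.index[counts >= 2]
    return out.loc[out["sow_id"].isin(keep)].reset_index(drop=True)


def grm(g: GenotypeMatrix, stabilizer: float = 1e-6) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    Centered minor-allele dosages scaled by ``2 * sum(p * (1 - p))``;
    missing calls are mean-imputed per SNP.  A small multiple of the
    identity is added so the result is safely positive definite.
    """
    calls = g.calls.astype(float)
    calls[calls == MISSING] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0  # per-SNP mean dosage / 2
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs; cannot build a GRM")
    calls = calls[:, poly]
    p = p[poly]
    col_mean = 2.0 * p
    nan_mask = np.isnan(calls)
    calls[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    z = calls - col_mean
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (z @ z.T) / denom
    G[np.diag_indices_from(G)] += stabilizer
    return G


@dataclass
class ModelFit:
    """Converged (or last-iterate) repeatability-model solution."""

    fixed_names: list[str]
    fixed_effects: np.ndarray
    additive: pd.Series  # indexed by sow id
    permanent_env: pd.Series
    residuals: pd.Series  # one per record, aligned with the input rows
    sigma2_b: float
    sigma2_pe: float
    sigma2_e: float
    converged: bool
    n_iter: int
    trace: list[tuple[float, float, float]] = field(default_factory=list)


def _design_matrices(records: pd.DataFrame, trait: str):
    y = records[trait].to_numpy(dtype=float)
    parts = [np.ones((len(records), 1))]
    names = ["intercept"]
    for col in ("fys", "parity"):
        levels = pd.Categorical(records[col])
        dummies = pd.get_dummies(levels, drop_first=True)
        parts.append(dummies.to_numpy(dtype=float))
        names += [f"{col}[{c}]" for c in dummies.columns]
    X = np.concatenate(parts, axis=1)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "singular fixed-effect design: farm-year-season and parity "
            "levels are confounded (rank %d < %d columns)" % (rank, X.shape[1])
        )
    sows = pd.Categorical(records["sow_id"])
    Z = pd.get_dummies(sows).to_numpy(dtype=float)
    sow_ids = list(pd.get_dummies(sows).columns)
    return y, X, names, Z, sow_ids


def fit_repeatability(
    records: pd.DataFrame,
    trait: str,
    G: np.ndarray | pd.DataFrame,
    components: tuple[float, float, float] | None = None,
    estimate: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ModelFit:
    """Fit the repeatability model for one trait.

    ``G`` must cover every sow in ``records`` (a DataFrame indexed by sow id,
    or an ndarray ordered like the sows' first appearance).  When
    ``estimate`` is true, variance components start from ``components`` (or
    an equal split of the phenotypic variance) and are updated by EM-REML
    until successive changes fall below ``tol`` or ``max_iter`` is reached;
    otherwise the supplied components are used as-is.  Effects are solved
    from the mixed-model equations at the final components.

    A component estimated (or supplied) as zero removes its random term:
    with both sow terms at zero the model collapses to fixed-effects least
    squares and the residuals are the OLS residuals.
    """
    records = records.reset_index(drop=True)
    counts = records["sow_id"].value_counts()
    if (counts < 2).any():
        raise ValueError("every sow needs at least 2 records; "
                         "run prepare_records first")
    y, X, names, Z, sow_ids = _design_matrices(records, trait)
    n, p = X.shape
    q = Z.shape[1]

    if isinstance(G, pd.DataFrame):
        missing = set(sow_ids) - set(G.index)
        if missing:
            raise ValueError(f"G does not cover sows: {sorted(missing)[:3]}")
        Gm = G.loc[sow_ids, sow_ids].to_numpy(dtype=float)
    else:
        Gm = np.asarray(G, dtype=float)
        if Gm.shape != (q, q):
            raise ValueError("G shape does not match the number of sows")
    Ginv = np.linalg.inv(Gm)

    var_y = float(np.var(y, ddof=1))
    if components is not None:
        s2b, s2pe, s2e = (float(c) for c in components)
    else:
        s2b = s2pe = var_y / 4.0
        s2e = var_y / 2.0

    floor = 1e-10 * max(var_y, 1.0)

    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    Xty, Zty, yty = X.T @ y, Z.T @ y, float(y @ y)

    def solve(s2b, s2pe, s2e, need_cinv):
        """Solve the MME; returns solutions and (optionally) C-inverse blocks."""
        use_b = s2b > floor
        use_pe = s2pe > floor
        blocks, rhs_parts = [[XtX]], [Xty]
        if use_b:
            blocks[0].append(XtZ)
            rhs_parts.append(Zty)
        if use_pe:
            blocks[0].append(XtZ)
            rhs_parts.append(Zty)
        rows = [np.concatenate(blocks[0], axis=1)]
        if use_b:
            row = [XtZ.T, ZtZ + Ginv * (s2e / s2b)]
            if use_pe:
                row.append(ZtZ)
            rows.append(np.concatenate(row, axis=1))
        if use_pe:
            row = [XtZ.T]
            if use_b:
                row.append(ZtZ)
            row.append(ZtZ + np.eye(q) * (s2e / s2pe))
            rows.append(np.concatenate(row, axis=1))
        C = np.concatenate(rows, axis=0)
        rhs = np.concatenate(rhs_parts)
        if need_cinv:
            Cinv = np.linalg.inv(C)
            sol = Cinv @ rhs
        else:
            Cinv = None
            sol = np.linalg.solve(C, rhs)
        beta = sol[:p]
        off = p
        if use_b:
            b = sol[off:off + q]
            off += q
        else:
            b = np.zeros(q)
        pe = sol[off:off + q] if use_pe else np.zeros(q)
        return beta, b, pe, sol, rhs, Cinv, use_b, use_pe

    trace = []
    converged = not estimate
    it = 0
    if estimate:
        prev_delta = None
        for it in range(1, max_iter + 1):
            beta, b, pe, sol, rhs, Cinv, use_b, use_pe = solve(
                s2b, s2pe, s2e, need_cinv=True)
            new_e = (yty - float(sol @ rhs)) / (n - p)
            off = p
            if use_b:
                Cbb = Cinv[off:off + q, off:off + q]
                new_b = (float(b @ (Ginv @ b))
                         + new_e * float(np.sum(Ginv * Cbb))) / q
                off += q
            else:
                new_b = 0.0
            if use_pe:
                Cpp = Cinv[off:off + q, off:off + q]
                new_pe = (float(pe @ pe) + new_e * float(np.trace(Cpp))) / q
            else:
                new_pe = 0.0
            delta = np.array([new_b - s2b, new_pe - s2pe, new_e - s2e])
            s2b, s2pe, s2e = max(new_b, 0.0), max(new_pe, 0.0), new_e
            trace.append((s2b, s2pe, s2e))
            if np.max(np.abs(delta)) < tol:
                converged = True
                break
            # Aitken extrapolation of the geometric EM tail
            if prev_delta is not None and it % 4 == 0:
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = delta / prev_delta
                if np.all((r > 0.1) & (r < 0.999)):
                    extra = delta * r / (1.0 - r)
                    s2b = max(s2b + extra[0], floor / 10)
                    s2pe = max(s2pe + extra[1], floor / 10)
                    s2e = max(s2e + extra[2], 1e-8 * var_y)
                    trace.append((s2b, s2pe, s2e))
            prev_delta = delta
        if not converged:
            warnings.warn("EM-REML did not converge; returning last iterate")

    beta, b, pe, sol, rhs, _, use_b, use_pe = solve(
        s2b, s2pe, s2e, need_cinv=False)
    fitted = X @ beta + Z @ b + Z @ pe
    resid = y - fitted
    return ModelFit(
        fixed_names=names,
        fixed_effects=beta,
        additive=pd.Series(b, index=sow_ids),
        permanent_env=pd.Series(pe, index=sow_ids),
        residuals=pd.Series(resid, index=records.index),
        sigma2_b=float(s2b),
        sigma2_pe=float(s2pe),
        sigma2_e=float(s2e),
        converged=converged,
        n_iter=it,
        trace=trace,
    )


def lnvar(fit: ModelFit, records: pd.DataFrame,
          trait_label: str = "trait") -> pd.DataFrame:
    """Per-sow natural log of the sample variance of the model residuals.

    Uses the n-1 denominator; sows whose residuals are all equal (zero
    variance, log undefined) get NA with a warning.
    """
    records = records.reset_index(drop=True)
    df = pd.DataFrame({"sow_id": records["sow_id"],
                       "resid": fit.residuals.to_numpy()})
    rows = []
    n_degenerate = 0
    for sow, grp in df.groupby("sow_id", sort=True):
        if len(grp) < 2:
            raise ValueError(f"sow {sow} has fewer than 2 residuals")
        v = float(np.var(grp["resid"].to_numpy(), ddof=1))
        if v <= 0.0:
            n_degenerate += 1
            val = math.nan
        else:
            val = math.log(v)
        rows.append({"sow_id": sow, f"lnvar_{trait_label}": val})
    if n_degenerate:
        warnings.warn(f"{n_degenerate} sows with zero residual variance; "
                      "LnVar set to NA")
    return pd.DataFrame(rows)
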