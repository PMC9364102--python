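"""Independent reference implementations used only as test oracles.

These are deliberately naive (explicit loops, pairwise enumeration) and
share no code with the package internals they check.
"""

from __future__ import annotations

import numpy as np

HET = 1
MISSING = -1


def brute_rohet(calls_row, pos, min_length_bp, min_snps, max_gap_bp):
    """All maximal heterozygous stretches passing the thresholds.

    Enumerates every candidate [i, j] index span, checks validity (all
    calls heterozygous, adjacent gaps within bound) and keeps spans that
    no valid span strictly contains.
    """
    n = len(pos)
    valid = []
    for i in range(n):
        for j in range(i, n):
            seg = calls_row[i:j + 1]
            if any(c != HET for c in seg):
                continue
            if any(pos[k + 1] - pos[k] > max_gap_bp for k in range(i, j)):
                continue
            valid.append((i, j))
    maximal = [
        (i, j) for (i, j) in valid
        if not any((a <= i and j <= b and (a, b) != (i, j))
                   for (a, b) in valid)
    ]
    out = []
    for i, j in maximal:
        length = pos[j] - pos[i] + 1
        count = j - i + 1
        if length >= min_length_bp and count >= min_snps:
            out.append((int(pos[i]), int(pos[j]), count))
    return sorted(out)


def brute_roh(calls_row, pos, min_length_bp, min_snps, max_gap_bp,
              window_snps, max_het, max_missing, min_density,
              hit_threshold):
    """Sliding-window ROH by direct enumeration of windows and stretches."""
    n = len(pos)
    w = min(window_snps, n)
    compatible = []
    for s in range(n - w + 1):
        win = calls_row[s:s + w]
        n_het = sum(1 for c in win if c == HET)
        n_mis = sum(1 for c in win if c == MISSING)
        compatible.append(n_het <= max_het and n_mis <= max_missing)
    eligible = []
    for j in range(n):
        covering = [s for s in range(n - w + 1) if s <= j <= s + w - 1]
        hits = sum(1 for s in covering if compatible[s])
        frac = hits / len(covering)
        ok = frac >= hit_threshold
        if max_het == 0 and calls_row[j] == HET:
            ok = False
        if max_missing == 0 and calls_row[j] == MISSING:
            ok = False
        eligible.append(ok)
    # maximal stretches of consecutive eligible SNPs with bounded gaps
    blocks = []
    cur: list[int] = []
    for j in range(n):
        if eligible[j]:
            if cur and pos[j] - pos[j - 1] > max_gap_bp:
                blocks.append(cur)
                cur = []
            cur.append(j)
        elif cur:
            blocks.append(cur)
            cur = []
    if cur:
        blocks.append(cur)
    out = []
    for block in blocks:
        i, k = block[0], block[-1]
        length = pos[k] - pos[i] + 1
        count = len(block)
        if (length >= min_length_bp and count >= min_snps
                and count / (length / 1e6) >= min_density):
            out.append((int(pos[i]), int(pos[k]), count))
    return sorted(out)


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up, written independently."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end  # 1-based rank of this p-value
        running_min = min(running_min, p[idx] * n / rank)
        adj[idx] = running_min
    return adj


def ols_via_normal_equations(X, y):
    """Solve beta, residuals, and region-coefficient SE / t-test p-value."""
    from scipy import stats

    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, resid, se, p


def wc_fst_single_site(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) theta-hat for one site, two populations."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def random_instance(rng, n_snps_max=60, n_ind=5, chrom_span=4_000_000):
    """A random small genotype panel for detector-vs-oracle checks."""
    n_snps = int(rng.integers(5, n_snps_max + 1))
    pos = np.sort(rng.choice(chrom_span, size=n_snps, replace=False) + 1)
    calls = rng.choice(
        [0, 1, 2, -1], size=(n_ind, n_snps), p=[0.42, 0.28, 0.25, 0.05]
    ).astype(np.int8)
    # occasionally plant long pure stretches so runs actually occur
    for i in range(n_ind):
        if rng.random() < 0.6:
            j0 = int(rng.integers(0, max(1, n_snps - 10)))
            j1 = min(n_snps, j0 + int(rng.integers(5, 30)))
            calls[i, j0:j1] = rng.choice([0, 1])
    return calls, pos
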