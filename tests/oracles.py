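"""Independent brute-force oracles used to cross-check the implementation.

Each function here deliberately re-derives a quantity by the most direct
method available (all-pairs scans, exhaustive enumeration, generic numeric
optimisation) and shares no code with the package internals it checks.
"""
import itertools

import numpy as np
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def brute_r2(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 0.0
    return float(((xc * yc).sum() / denom) ** 2)


def brute_clump_indices(stats_df, panel, p_threshold, p_window_low,
                        exclude_dist, exclude_r2, tier="supra",
                        supra_indices=None):
    """From-scratch re-scan clumping: at every step the full exclusion set is
    recomputed over all chosen indices; returns index SNP ids in pick order."""
    df = stats_df.copy()
    if tier == "supra":
        cand = df[df["pvalue"] <= p_threshold]
    else:
        cand = df[(df["pvalue"] > p_threshold) & (df["pvalue"] < p_window_low)]
    cand = cand[cand["snp_id"].isin(list(panel.snp_ids))]
    cand = cand.sort_values(["pvalue", "chrom", "pos"], kind="mergesort")

    def excluded_by(row, index_id):
        j = panel.index_of(index_id)
        if str(row.chrom) != str(panel.chrom[j]):
            return False
        if abs(int(row.pos) - int(panel.pos[j])) < exclude_dist:
            return True
        a = panel.column(index_id).astype(float)
        b = panel.column(row.snp_id).astype(float)
        if a.var() == 0 or b.var() == 0:
            return False
        return brute_r2(a, b) >= exclude_r2

    chosen = list(supra_indices or []) if tier == "sub" else []
    picked = []
    while True:
        remaining = [
            r for r in cand.itertuples(index=False)
            if r.snp_id not in picked
            and not any(excluded_by(r, c) for c in chosen + picked)
        ]
        if not remaining:
            return picked
        picked.append(remaining[0].snp_id)


# ---------------------------------------------------------------------------
# interval counting
# ---------------------------------------------------------------------------

def allpairs_locus_overlap(loci, peak_rows, mode="snp", window=0):
    """Loci with >= 1 (padded) peak hit, by scanning every locus x peak pair."""
    n = 0
    for locus in loci:
        chrom, s, e = locus.span
        hit = False
        for (pc, ps, pe) in peak_rows:
            if pc != chrom:
                continue
            lo, hi = max(ps - window, 0), pe + window
            if mode == "snp":
                if any(lo <= p < hi for p in locus.member_pos):
                    hit = True
            else:
                if s < hi and lo < e:
                    hit = True
        n += hit
    return n


def allpairs_peak_overlap(loci, peak_rows):
    n = 0
    for (pc, ps, pe) in peak_rows:
        if any(
            locus.chrom == pc and any(ps <= p < pe for p in locus.member_pos)
            for locus in loci
        ):
            n += 1
    return n


def allpairs_consensus(rows, min_datasets):
    """Single-linkage >=1-bp-overlap clustering via union-find over all
    pairs; returns sorted (chrom, start, end) union spans of supported
    clusters."""
    parent = list(range(len(rows)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(rows)), 2):
        ci, si, ei, _ = rows[i]
        cj, sj, ej, _ = rows[j]
        if ci == cj and si < ej and sj < ei:
            parent[find(i)] = find(j)
    clusters = {}
    for i in range(len(rows)):
        clusters.setdefault(find(i), []).append(rows[i])
    out = []
    for members in clusters.values():
        if len({m[3] for m in members}) >= min_datasets:
            out.append(
                (members[0][0], min(m[1] for m in members),
                 max(m[2] for m in members))
            )
    return sorted(out)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def brute_es(pi_sorted_desc, hit_mask, weight=1.0):
    """Running sum enumerated by an explicit loop."""
    pi = list(pi_sorted_desc)
    hits = list(hit_mask)
    nh = sum(hits)
    denom = sum(abs(p) ** weight for p, h in zip(pi, hits) if h)
    total = 0.0
    best = 0.0
    n = len(pi)
    for p, h in zip(pi, hits):
        if h:
            total += (abs(p) ** weight / denom) if denom > 0 else 1.0 / nh
        else:
            total -= 1.0 / (n - nh)
        if abs(total) > abs(best):
            best = total
    return best


def classic_ks_es(pi_sorted_desc, hit_mask):
    """Unweighted (Kolmogorov-Smirnov-style) enrichment statistic."""
    nh = sum(hit_mask)
    n = len(hit_mask)
    total, best = 0.0, 0.0
    for h in hit_mask:
        total += 1.0 / nh if h else -1.0 / (n - nh)
        if abs(total) > abs(best):
            best = total
    return best


# ---------------------------------------------------------------------------
# NB GLM
# ---------------------------------------------------------------------------

def direct_ml_nb(y, x=None, offsets=None):
    """Generic numeric ML fit of the NB2 GLM via Nelder-Mead on
    (beta, log alpha); returns (coef, alpha, loglik)."""
    y = np.asarray(y, float)
    n = len(y)
    offsets = np.zeros(n) if offsets is None else np.asarray(offsets, float)
    X = np.ones((n, 1)) if x is None else np.column_stack(
        [np.ones(n), np.asarray(x, float)]
    )
    k = X.shape[1]

    def nll(params):
        beta, log_alpha = params[:k], params[k]
        alpha = np.exp(log_alpha)
        mu = np.exp(offsets + X @ beta)
        r = 1.0 / alpha
        return -stats.nbinom.logpmf(y, r, r / (r + mu)).sum()

    start = np.concatenate(
        [np.linalg.lstsq(X, np.log(y + 0.5) - offsets, rcond=None)[0], [-1.0]]
    )
    best = None
    for s in (start, start + 0.3):
        res = optimize.minimize(nll, s, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 20_000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:k], float(np.exp(best.x[k])), -float(best.fun)


# ---------------------------------------------------------------------------
# paired sign test
# ---------------------------------------------------------------------------

def exhaustive_signed_rank_p(a, b):
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n sign
    assignments of the ranked |differences| (assumes no zeros, no ties)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.asarray(w_all)
    w_min = min(w_plus, n * (n + 1) / 2 - w_plus)
    p = np.mean(
        np.minimum(w_all, n * (n + 1) / 2 - w_all) <= w_min
    )
    return float(p)
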