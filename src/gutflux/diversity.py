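"""Alpha/beta diversity indices and the two group-comparison tests.

All index arithmetic is implemented here directly (scipy supplies only
probability distributions); external ecology packages serve as independent
cross-checks in the test suite, never in this module.

Alpha diversity works on integer count vectors: richness S (observed taxa),
the Chao1 richness estimator ``S + F1^2 / (2 F2)`` built from singleton and
doubleton counts, Shannon entropy ``-sum p ln p``, Simpson concentration
``D = sum p^2`` and Simpson evenness ``(1/D)/S``.  Relative-abundance input
is converted to counts by scaling with a documented pseudo-depth (default
10,000 reads) and rounding — Chao1 needs singletons, which proportions alone
cannot supply.

Beta diversity: Bray-Curtis dissimilarity ``BC_ij = 1 - 2 C_ij / (S_i + S_j)``
where ``C_ij`` sums the lesser count over shared taxa and ``S_i`` is the
sample's total count; and both UniFrac variants over a rooted phylogeny —
unweighted (fraction of observed branch length unique to one sample) and
weighted-normalized (abundance-weighted branch-length difference, in [0,1]).

Group comparisons: a two-sided Mann-Whitney U test (exact null distribution
for small tie-free problems, tie-corrected normal approximation with
continuity correction otherwise) and a two-sided variance-ratio F test.
"""

from __future__ import annotations

import math
from itertools import combinations

import dendropy
import numpy as np
from scipy import stats

DEFAULT_PSEUDO_DEPTH = 10_000


def to_counts(abundances, depth: int = DEFAULT_PSEUDO_DEPTH) -> np.ndarray:
    """Convert relative abundances to integer counts at a pseudo-depth."""
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    return np.rint(a * depth).astype(int)


# ------------------------------------------------------------------- alpha
def alpha_indices(counts) -> dict[str, float]:
    """Richness, Chao1, Shannon, Simpson concentration and Simpson evenness."""
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    observed = c[c > 0]
    S = int(observed.size)
    f1 = int(np.sum(observed == 1))
    f2 = int(np.sum(observed == 2))
    if f2 > 0:
        chao1 = S + f1 * f1 / (2.0 * f2)
    else:
        # bias-corrected form when no doubletons exist
        chao1 = S + f1 * (f1 - 1) / 2.0
    p = observed / total
    shannon = float(-np.sum(p * np.log(p)))
    simpson_d = float(np.sum(p * p))
    evenness = (1.0 / simpson_d) / S
    return {
        "richness": S,
        "chao1": float(chao1),
        "shannon": shannon,
        "simpson_D": simpson_d,
        "evenness": float(evenness),
    }


# -------------------------------------------------------------------- beta
def bray_curtis(counts_i, counts_j) -> float:
    """Bray-Curtis dissimilarity between two count vectors on one taxon universe."""
    x = np.asarray(counts_i, dtype=float)
    y = np.asarray(counts_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must share the taxon universe")
    s_i, s_j = x.sum(), y.sum()
    if s_i == 0 and s_j == 0:
        raise ValueError("both samples are empty")
    shared = (x > 0) & (y > 0)
    c_ij = np.minimum(x[shared], y[shared]).sum()
    return float(1.0 - 2.0 * c_ij / (s_i + s_j))


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)


def unifrac(counts_i, counts_j, taxa: list[str], tree, weighted: bool = False) -> float:
    """UniFrac distance between two samples over a phylogeny.

    ``taxa`` aligns the count vectors with tree leaf labels.  Unweighted:
    unique observed branch length over total observed branch length.
    Weighted: normalized abundance-weighted branch-length difference (both
    variants lie in [0, 1], are symmetric, and vanish on identical samples).
    """
    x = np.asarray(counts_i, dtype=float)
    y = np.asarray(counts_j, dtype=float)
    if not (len(x) == len(y) == len(taxa)):
        raise ValueError("counts and taxa must have equal length")
    t = _as_tree(tree)
    leaf_names = {lf.taxon.label for lf in t.leaf_node_iter()}
    missing = [tx for tx, cx, cy in zip(taxa, x, y) if (cx > 0 or cy > 0) and tx not in leaf_names]
    if missing:
        raise ValueError(f"taxa missing from the tree: {missing}")
    tx_index = {tx: k for k, tx in enumerate(taxa)}
    tot_x, tot_y = x.sum(), y.sum()
    if tot_x == 0 or tot_y == 0:
        raise ValueError("empty sample")

    num = 0.0
    den = 0.0
    for node in t.postorder_node_iter():
        if node.parent_node is None:
            continue  # the root edge carries no comparative signal
        length = node.edge.length or 0.0
        cx = cy = 0.0
        for leaf in node.leaf_iter():
            k = tx_index.get(leaf.taxon.label)
            if k is not None:
                cx += x[k]
                cy += y[k]
        if weighted:
            px, py = cx / tot_x, cy / tot_y
            num += length * abs(px - py)
            den += length * (px + py)
        else:
            in_x, in_y = cx > 0, cy > 0
            if in_x or in_y:
                den += length
                if in_x != in_y:
                    num += length
    if den == 0:
        return 0.0
    return float(num / den)


# -------------------------------------------------------------------- tests
def _exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U for tie-free samples (counts per U value).

    Classic lattice recursion, conditioning on which group holds the largest
    pooled value: ``f(u; m, n) = f(u - n; m - 1, n) + f(u; m, n - 1)``.  The
    result is the Gaussian-binomial coefficient expansion with total
    ``C(n1 + n2, n1)``.
    """
    max_u = n1 * n2
    # prev[n] = distribution for (m - 1, n); start at m = 0 where U = 0
    prev = np.zeros((n2 + 1, max_u + 1))
    prev[:, 0] = 1.0
    for _ in range(1, n1 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for n in range(1, n2 + 1):
            cur[n, n:] = prev[n, : max_u + 1 - n]
            cur[n] += cur[n - 1]
        prev = cur
    return prev[n2]


def mann_whitney_u(group_a, group_b) -> dict[str, float]:
    """Two-sided Mann-Whitney U test.

    Exact p for tie-free problems with ``n_a * n_b <= 400`` (dynamic-
    programming null distribution; explicit enumeration for small tied
    pools), tie-corrected continuity-corrected normal approximation
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size

    if n1 * n2 <= 400 and not has_ties:
        dist = _exact_u_distribution(n1, n2)
        total = dist.sum()
        u_int = int(round(u1))
        p_le = dist[: u_int + 1].sum() / total
        p_ge = dist[u_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return {"U": float(u1), "p": float(p), "method": "exact"}

    if has_ties and math.comb(n1 + n2, n1) <= 200_000:
        # small tied pools: enumerate the permutation distribution directly
        us = []
        idx = range(n1 + n2)
        for combo in combinations(idx, n1):
            r = ranks[list(combo)].sum()
            us.append(r - n1 * (n1 + 1) / 2.0)
        us = np.asarray(us)
        eps = 1e-9
        p_le = np.mean(us <= u1 + eps)
        p_ge = np.mean(us >= u1 - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return {"U": float(u1), "p": float(p), "method": "exact-permutation"}

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie_term = 0.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return {"U": float(u1), "p": 1.0, "method": "normal"}
    z = (u1 - mean_u - math.copysign(0.5, u1 - mean_u)) / math.sqrt(var_u)
    if u1 == mean_u:
        z = 0.0
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return {"U": float(u1), "p": float(p), "method": "normal"}


def f_test_variance(group_a, group_b) -> dict[str, float]:
    """Two-sided F test comparing the variances of two samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("degenerate (zero) variance")
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return {"F": float(f), "p": float(min(1.0, p))}
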