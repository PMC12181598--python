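"""First-principles oracles kept independent of the implementation paths
they check: per-gene scipy correlations with explicit sorting for the
ranking, exhaustive pair counting for the AUC, and membership enumeration
for the Venn regions."""

import numpy as np
from scipy import stats


def oracle_rank(expr, y, k, score_mode="min"):
    """Brute-force top-k ranking: scipy per gene, conflict-zeroing, explicit sort.

    Returns a list of (gene_id, combined, pearson, spearman).
    """
    rows = []
    yv = np.asarray(y, dtype=float)
    for gene in expr.index:
        x = expr.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(yv) == 0:
            continue
        p = stats.pearsonr(x, yv).statistic
        s = stats.spearmanr(x, yv).statistic
        if np.isnan(p) or np.isnan(s) or p * s <= 0:
            continue
        sign = 1.0 if p > 0 else -1.0
        if score_mode == "min":
            c = sign * min(abs(p), abs(s))
        elif score_mode == "mean":
            c = sign * (abs(p) + abs(s)) / 2.0
        else:
            c = p
        rows.append((str(gene), c, p, s))
    rows.sort(key=lambda r: (-abs(r[1]), -abs(r[2]), r[0]))
    return rows[:k]


def oracle_auc(scores, labels):
    """AUC by exhaustive positive/negative pair counting with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = concordant = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                concordant += 1
            elif sp == sn:
                concordant += 0.5
    return concordant / total


def oracle_venn_regions(a, b, c):
    """Region counts by per-gene membership enumeration."""
    a, b, c = set(a), set(b), set(c)
    counts = dict.fromkeys(
        ["a_only", "b_only", "c_only", "ab_only", "ac_only", "bc_only", "abc"], 0
    )
    for g in a | b | c:
        key = "".join(
            ch for ch, present in zip("abc", (g in a, g in b, g in c)) if present
        )
        name = {"a": "a_only", "b": "b_only", "c": "c_only",
                "ab": "ab_only", "ac": "ac_only", "bc": "bc_only", "abc": "abc"}[key]
        counts[name] += 1
    return counts
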