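"""Cross-test and cross-sex structure of the top-k candidate lists.

Venn region counts across the three function tests, per-sex unique-candidate
unions, per-test cross-sex intersections, the fraction of candidates whose
correlation direction disagrees between the sexes, and export of the
clustered combined-score matrix that underlies the study-style heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage


@dataclass(frozen=True)
class VennCounts3:
    """Region sizes of a three-set Venn partition."""

    a_only: int
    b_only: int
    c_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    @property
    def union_size(self) -> int:
        return (
            self.a_only + self.b_only + self.c_only
            + self.ab_only + self.ac_only + self.bc_only + self.abc
        )

    def as_dict(self) -> dict:
        return {
            "a_only": self.a_only, "b_only": self.b_only, "c_only": self.c_only,
            "ab_only": self.ab_only, "ac_only": self.ac_only, "bc_only": self.bc_only,
            "abc": self.abc, "union_size": self.union_size,
        }


@dataclass
class DirectionComparison:
    """Per-candidate sign agreement between the sexes and the summary fraction."""

    table: pd.DataFrame  # columns: gene_id, test, sign_F, sign_M, consistent
    n_evaluated: int
    n_inconsistent: int
    excluded: list = field(default_factory=list)

    @property
    def inconsistent_fraction(self) -> float:
        if self.n_evaluated == 0:
            return float("nan")
        return self.n_inconsistent / self.n_evaluated


def venn3(list_a, list_b, list_c) -> VennCounts3:
    """Exact region counts for three finite sets."""
    a, b, c = set(list_a), set(list_b), set(list_c)
    return VennCounts3(
        a_only=len(a - b - c),
        b_only=len(b - a - c),
        c_only=len(c - a - b),
        ab_only=len((a & b) - c),
        ac_only=len((a & c) - b),
        bc_only=len((b & c) - a),
        abc=len(a & b & c),
    )


def unique_union(lists) -> set:
    """Union of gene sets (the per-sex 'unique candidates' count)."""
    out: set = set()
    for l in lists:
        out |= set(l)
    return out


def cross_sex_overlap(f_list, m_list) -> set:
    """Genes shared between the female and male top-k lists of one test."""
    return set(f_list) & set(m_list)


def direction_consistency(
    correlations: pd.DataFrame, candidates: list[tuple[str, str]]
) -> DirectionComparison:
    """Sign agreement between the sexes for each (gene, originating test) pair.

    ``correlations`` is the long-format table (gene_id, sex, test,
    combined_score, ...); ``candidates`` lists (gene_id, test) pairs — the
    union of both sexes' top-k entries, each evaluated at the test that
    nominated it.  Pairs with a zero or missing score in either sex are
    excluded from the denominator; inconsistent iff the sign product is
    negative.
    """
    idx = correlations.set_index(["gene_id", "test", "sex"])["combined_score"]
    rows, excluded = [], []
    for gene, test in sorted(set(candidates)):
        try:
            sf = float(idx.loc[(gene, test, "F")])
            sm = float(idx.loc[(gene, test, "M")])
        except KeyError:
            excluded.append((gene, test, "absent"))
            continue
        sign_f = int(np.sign(sf)) if np.isfinite(sf) else 0
        sign_m = int(np.sign(sm)) if np.isfinite(sm) else 0
        if sign_f == 0 or sign_m == 0:
            excluded.append((gene, test, "zero_or_undefined"))
            continue
        rows.append(
            {
                "gene_id": gene, "test": test,
                "sign_F": sign_f, "sign_M": sign_m,
                "consistent": sign_f * sign_m > 0,
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "test", "sign_F", "sign_M", "consistent"])
    n_eval = len(table)
    n_incons = int((~table["consistent"]).sum()) if n_eval else 0
    return DirectionComparison(
        table=table, n_evaluated=n_eval, n_inconsistent=n_incons, excluded=excluded
    )


def export_heatmap_matrix(
    correlations: pd.DataFrame,
    genes,
    tests,
    sex: str | None = None,
    cluster: bool = True,
) -> pd.DataFrame:
    """Genes x tests matrix of combined scores, optionally row-clustered.

    Row order follows average-linkage hierarchical clustering on Euclidean
    distance (leaf order); rows with any missing (gene, test) value are kept
    as NaN, excluded from clustering and appended at the bottom.  With
    ``sex=None`` the columns are (sex, test) pairs for the paired female/male
    view.
    """
    sub = correlations if sex is None else correlations[correlations["sex"] == sex]
    if sex is None:
        mat = sub.pivot_table(
            index="gene_id", columns=["sex", "test"], values="combined_score", aggfunc="first"
        )
        cols = [(s, t) for s in ("F", "M") for t in tests if (s, t) in mat.columns]
        mat = mat.reindex(columns=pd.MultiIndex.from_tuples(cols))
        mat.columns = [f"{s}_{t}" for s, t in cols]
    else:
        mat = sub.pivot_table(
            index="gene_id", columns="test", values="combined_score", aggfunc="first"
        )
        mat = mat.reindex(columns=[t for t in tests if t in mat.columns])
    mat = mat.reindex(index=[g for g in genes if g in mat.index])
    if not cluster or len(mat) < 3:
        return mat
    complete = mat.dropna()
    incomplete = mat.index.difference(complete.index, sort=False)
    if len(complete) >= 3:
        Z = linkage(complete.to_numpy(), method="average", metric="euclidean")
        order = leaves_list(Z)
        ordered = list(complete.index[order]) + list(incomplete)
    else:
        ordered = list(complete.index) + list(incomplete)
    return mat.loc[ordered]
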