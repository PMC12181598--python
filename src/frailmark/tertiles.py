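"""Serum-marker validation by sex-specific performance tertiles.

Participants of each sex are split into tertiles of a timed test (T1 =
fastest); marker concentrations in T2 and T3 are compared against T1 with a
normality-gated path: Shapiro–Wilk per group at alpha = 0.05, then either
one-way ANOVA with one-sided Dunnett contrasts against T1, or
Kruskal–Wallis with one-sided Mann–Whitney U comparisons.  Post-hoc
contrasts are computed unconditionally — the omnibus statistic is reported
but not used as a gate, so the per-contrast error rate is interpretable on
its own.  Old-vs-young comparisons use a two-sided t-test or Mann–Whitney U
under the same gate; marker–marker associations use pairwise-complete
Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SHAPIRO_ALPHA = 0.05
TERTILE_LABELS = ("T1", "T2", "T3")


@dataclass
class TertileAssignment:
    sex: str | None
    test: str | None
    labels: pd.Series  # sample_id -> {T1, T2, T3}

    def group(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    def sizes(self) -> tuple[int, int, int]:
        return tuple(int((self.labels == t).sum()) for t in TERTILE_LABELS)


@dataclass
class GroupComparisonResult:
    marker: str | None
    sex: str | None
    groups: tuple
    normality_p: dict
    path: str  # anova_dunnett | kw_mwu | ttest | mwu | degenerate
    statistic: float
    omnibus_p: float
    p_values: dict  # contrast name -> one-sided (tertile) or two-sided (age) p
    alternative: str
    flags: list = field(default_factory=list)


def assign_tertiles(times: pd.Series, sex: str | None = None, test: str | None = None) -> TertileAssignment:
    """Tertiles of one sex's test times, fastest first.

    Sizes follow a ceil(n/3)-first allocation: remainder participants land
    in the faster tertiles (n=24 -> 8/8/8, n=28 -> 10/9/9).  Ties are broken
    by stable sample-id order.
    """
    times = times.dropna()
    n = len(times)
    if n < 3:
        raise ValueError(f"assign_tertiles needs >=3 participants, got {n}")
    order = times.to_frame("t").reset_index()
    id_col = order.columns[0]
    order = order.sort_values(["t", id_col], kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.repeat(TERTILE_LABELS, sizes)
    assignment = pd.Series(labels, index=order[id_col].to_numpy(), name="tertile")
    return TertileAssignment(sex=sex, test=test, labels=assignment.loc[times.index])


def _normality(groups: dict) -> tuple[dict, bool]:
    """Shapiro-Wilk p per group; groups with n < 3 are treated as normal."""
    ps, all_normal = {}, True
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3 or np.ptp(vals) == 0:
            ps[name] = np.nan
            continue
        p = float(stats.shapiro(vals).pvalue)
        ps[name] = p
        if p < SHAPIRO_ALPHA:
            all_normal = False
    return ps, all_normal


def compare_tertiles(
    values: pd.Series,
    assignment: TertileAssignment,
    alternative: str = "greater",
    marker: str | None = None,
) -> GroupComparisonResult:
    """Compare T2 and T3 against T1 (one-sided) with the normality-gated path.

    ``alternative`` is the expected direction of the slower tertiles
    relative to T1: 'greater' means the marker is expected higher in T2/T3.
    """
    if alternative not in {"greater", "less"}:
        raise ValueError("alternative must be 'greater' or 'less'")
    groups = {t: values.reindex(assignment.group(t)).dropna().to_numpy() for t in TERTILE_LABELS}
    for t, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"tertile {t} has fewer than 2 marker values")
    if all(np.ptp(v) == 0 for v in groups.values()):
        return GroupComparisonResult(
            marker=marker, sex=assignment.sex, groups=TERTILE_LABELS,
            normality_p={t: np.nan for t in TERTILE_LABELS}, path="degenerate",
            statistic=np.nan, omnibus_p=np.nan,
            p_values={"T2_vs_T1": np.nan, "T3_vs_T1": np.nan},
            alternative=alternative, flags=["zero_variance"],
        )
    normality_p, all_normal = _normality(groups)
    flags = []
    if all_normal:
        stat, omnibus_p = stats.f_oneway(*groups.values())
        # multivariate-t quadrature inside dunnett() is randomized; a fixed
        # rng makes p-values reproducible run-to-run
        dres = stats.dunnett(
            groups["T2"], groups["T3"], control=groups["T1"], alternative=alternative,
            rng=np.random.default_rng(0),
        )
        p_values = {"T2_vs_T1": float(dres.pvalue[0]), "T3_vs_T1": float(dres.pvalue[1])}
        path = "anova_dunnett"
    else:
        stat, omnibus_p = stats.kruskal(*groups.values())
        p_values = {}
        for t in ("T2", "T3"):
            _, p = stats.mannwhitneyu(groups[t], groups["T1"], alternative=alternative)
            p_values[f"{t}_vs_T1"] = float(p)
        path = "kw_mwu"
    return GroupComparisonResult(
        marker=marker, sex=assignment.sex, groups=TERTILE_LABELS,
        normality_p=normality_p, path=path, statistic=float(stat),
        omnibus_p=float(omnibus_p), p_values=p_values,
        alternative=alternative, flags=flags,
    )


def compare_age_groups(
    old_values, young_values, marker: str | None = None, sex: str | None = None
) -> GroupComparisonResult:
    """Two-sided old-vs-young comparison: t-test, or Mann-Whitney U when non-normal."""
    old = pd.Series(old_values).dropna().to_numpy(dtype=float)
    young = pd.Series(young_values).dropna().to_numpy(dtype=float)
    if len(old) < 2 or len(young) < 2:
        raise ValueError("compare_age_groups needs >=2 values per group")
    groups = {"old": old, "young": young}
    if np.ptp(old) == 0 and np.ptp(young) == 0:
        return GroupComparisonResult(
            marker=marker, sex=sex, groups=("old", "young"),
            normality_p={g: np.nan for g in groups}, path="degenerate",
            statistic=np.nan, omnibus_p=np.nan, p_values={"old_vs_young": np.nan},
            alternative="two-sided", flags=["zero_variance"],
        )
    normality_p, all_normal = _normality(groups)
    if all_normal:
        stat, p = stats.ttest_ind(old, young)
        path = "ttest"
    else:
        stat, p = stats.mannwhitneyu(old, young, alternative="two-sided")
        path = "mwu"
    return GroupComparisonResult(
        marker=marker, sex=sex, groups=("old", "young"),
        normality_p=normality_p, path=path, statistic=float(stat), omnibus_p=float(p),
        p_values={"old_vs_young": float(p)}, alternative="two-sided",
    )


def serum_pairwise_correlations(serum: pd.DataFrame, samples=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r and two-sided p between serum markers.

    Returns ``(r, p)`` DataFrames (markers x markers); entries with fewer
    than 3 complete pairs or a constant marker are NaN.
    """
    if samples is not None:
        serum = serum.loc[serum.index.intersection(samples)]
    markers = list(serum.columns)
    r = pd.DataFrame(np.nan, index=markers, columns=markers)
    p = pd.DataFrame(np.nan, index=markers, columns=markers)
    for i, a in enumerate(markers):
        vals = serum[a].dropna()
        if len(vals) >= 3 and np.ptp(vals) > 0:
            r.loc[a, a] = 1.0
            p.loc[a, a] = 0.0
        for b in markers[i + 1:]:
            pair = serum[[a, b]].dropna()
            if len(pair) < 3:
                continue
            if np.ptp(pair[a]) == 0 or np.ptp(pair[b]) == 0:
                continue
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p
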