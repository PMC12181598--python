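"""Sex-stratified dual-correlation ranking of candidate genes.

For each sex and each timed function test, every candidate gene's
expression is correlated with the test *time* (higher = worse function)
using both Pearson's r and Spearman's rho.  The two coefficients are
combined into a consensus score that is zeroed whenever they disagree in
sign (or either is undefined/zero); candidates are ranked by absolute
consensus score and the top k retained.

The estimator :class:`CorrelationRanker` exposes this as a scikit-learn
style fit/score object over a samples x genes matrix; the module-level
functions (`correlate`, `combined_score`, `rank_candidates`, `run_all`)
are the pipeline surface and delegate to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .simulate import SEXES, TEST_NAMES

SCORE_MODES = ("min", "mean", "pearson")


@dataclass(frozen=True)
class CorrelationResult:
    gene_id: str
    sex: str | None
    test: str | None
    pearson_r: float  # NaN when undefined
    spearman_rho: float
    combined_score: float
    n: int
    flag: str  # ok | constant_gene | insufficient_n


@dataclass
class RankedList:
    sex: str | None
    test: str | None
    k: int
    entries: list = field(default_factory=list)

    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def gene_set(self) -> set:
        return set(self.gene_ids())

    def __len__(self) -> int:
        return len(self.entries)


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X against y; NaN for constant rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[(sx == 0) | ~np.isfinite(r)] = np.nan
    if sy == 0:
        r[:] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlate(x, y) -> tuple[float, float, int, str]:
    """Pearson r and Spearman rho for two vectors after pairwise deletion.

    Returns ``(pearson_r, spearman_rho, n, flag)`` with NaN coefficients and
    flag ``insufficient_n`` when fewer than 3 complete pairs remain, or
    ``constant_gene`` when either vector is constant.  Spearman is Pearson
    on average-ranked data (ties receive average ranks).
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        return np.nan, np.nan, n, "insufficient_n"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n, "constant_gene"
    r = float(_pearson_rows(x[None, :], y)[0])
    rho = float(_pearson_rows(stats.rankdata(x)[None, :], stats.rankdata(y))[0])
    return r, rho, n, "ok"


def combined_score(pearson_r: float, spearman_rho: float, mode: str = "min") -> float:
    """Consensus of the two correlation coefficients.

    Zero whenever either coefficient is undefined (NaN), either is exactly
    zero, or the signs disagree.  Otherwise: ``min`` (default) takes the
    sign and the smaller magnitude, ``mean`` averages, ``pearson`` passes
    Pearson's r through.
    """
    if mode not in SCORE_MODES:
        raise ValueError(f"score mode must be one of {SCORE_MODES}, got {mode!r}")
    p, s = float(pearson_r), float(spearman_rho)
    if np.isnan(p) or np.isnan(s) or p * s <= 0:
        return 0.0
    sign = 1.0 if p > 0 else -1.0
    if mode == "min":
        return sign * min(abs(p), abs(s))
    if mode == "mean":
        return sign * (abs(p) + abs(s)) / 2.0
    return p


class CorrelationRanker(BaseEstimator):
    """Rank features (genes) by Pearson/Spearman consensus against a phenotype.

    A scikit-learn style selector: ``fit(X, y)`` with ``X`` of shape
    (n_samples, n_features) and ``y`` the phenotype (test time) computes,
    per feature, Pearson's r, Spearman's rho and the sign-consensus
    combined score, then ranks by absolute score (ties broken by absolute
    Pearson r, then feature name).

    Parameters
    ----------
    k : int, default 40
        Number of top features retained by :meth:`top_k` / :meth:`get_support`.
    score_mode : {'min', 'mean', 'pearson'}, default 'min'
        How agreeing coefficients are combined.

    Attributes
    ----------
    feature_names_in_ : ndarray of feature names
    pearson_r_, spearman_rho_, combined_score_ : ndarray, per feature
    n_used_ : ndarray of complete-pair counts per feature
    flags_ : ndarray of {'ok', 'constant_gene', 'insufficient_n'}
    ranking_ : ndarray of feature indices, best first (zero scores excluded)
    """

    def __init__(self, k: int = 40, score_mode: str = "min"):
        self.k = k
        self.score_mode = score_mode

    def fit(self, X, y):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.score_mode not in SCORE_MODES:
            raise ValueError(f"score_mode must be one of {SCORE_MODES}")
        if isinstance(X, pd.DataFrame):
            names = np.asarray(X.columns, dtype=object)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            names = np.asarray([f"x{i}" for i in range(Xv.shape[1])], dtype=object)
        yv = np.asarray(pd.Series(y).to_numpy(), dtype=float)
        if Xv.shape[0] != yv.shape[0]:
            raise ValueError("X and y have different numbers of samples")

        n_feat = Xv.shape[1]
        pearson = np.full(n_feat, np.nan)
        spearman = np.full(n_feat, np.nan)
        n_used = np.zeros(n_feat, dtype=int)
        flags = np.full(n_feat, "ok", dtype=object)

        complete_y = ~np.isnan(yv)
        G = Xv.T  # features x samples
        has_nan_rows = np.isnan(G).any(axis=1)
        # fast path: features fully observed on the y-complete samples
        fast = ~has_nan_rows
        ys = yv[complete_y]
        if complete_y.sum() >= 3 and fast.any():
            sub = G[np.ix_(fast, complete_y)]
            p = _pearson_rows(sub, ys)
            ranks = stats.rankdata(sub, axis=1)
            rho = _pearson_rows(ranks, stats.rankdata(ys))
            const = np.ptp(sub, axis=1) == 0
            if np.ptp(ys) == 0:
                const[:] = True
            p[const] = np.nan
            rho[const] = np.nan
            idx = np.where(fast)[0]
            pearson[idx] = p
            spearman[idx] = rho
            n_used[idx] = complete_y.sum()
            flags[idx[const]] = "constant_gene"
        else:
            fast = np.zeros(n_feat, dtype=bool)
        for j in np.where(~fast)[0]:
            pearson[j], spearman[j], n_used[j], flags[j] = correlate(G[j], yv)

        combined = np.array(
            [combined_score(p, s, self.score_mode) for p, s in zip(pearson, spearman)]
        )
        nonzero = np.where(combined != 0)[0]
        order = sorted(
            nonzero,
            key=lambda j: (-abs(combined[j]), -abs(pearson[j]), str(names[j])),
        )
        self.feature_names_in_ = names
        self.n_features_in_ = n_feat
        self.pearson_r_ = pearson
        self.spearman_rho_ = spearman
        self.combined_score_ = combined
        self.n_used_ = n_used
        self.flags_ = flags
        self.ranking_ = np.asarray(order, dtype=int)
        return self

    def top_k(self) -> list[int]:
        check_is_fitted(self, "ranking_")
        return list(self.ranking_[: self.k])

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "ranking_")
        top = self.top_k()
        if indices:
            return np.asarray(top, dtype=int)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[top] = True
        return mask

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        top = self.top_k()
        if isinstance(X, pd.DataFrame):
            return X.iloc[:, top]
        return np.asarray(X)[:, top]

    def results_frame(self, sex: str | None = None, test: str | None = None) -> pd.DataFrame:
        """All per-feature correlation results as a tidy DataFrame."""
        check_is_fitted(self, "ranking_")
        return pd.DataFrame(
            {
                "gene_id": self.feature_names_in_,
                "sex": sex,
                "test": test,
                "pearson_r": self.pearson_r_,
                "spearman_rho": self.spearman_rho_,
                "combined_score": self.combined_score_,
                "n": self.n_used_,
                "flag": self.flags_,
            }
        )


def rank_candidates(
    expr: pd.DataFrame,
    cohort: pd.DataFrame,
    sex: str,
    test: str,
    candidates,
    k: int = 40,
    score_mode: str = "min",
) -> RankedList:
    """Top-k candidates for one (sex, test) stratum.

    Scores are computed on the old participants of ``sex`` only, against the
    test time (missing phenotype values are dropped pairwise).  Zero-score
    genes are excluded; entries are sorted by |combined| desc, |pearson|
    desc, then gene id.
    """
    candidates = sorted(set(candidates))
    missing = [g for g in candidates if g not in expr.index]
    if missing:
        raise KeyError(f"candidate genes missing from expression matrix: {missing[:10]}")
    mask = (cohort["sex"] == sex) & (cohort["age_group"] == "old") & cohort[test].notna()
    samples = cohort.index[mask]
    if len(samples) < 3:
        raise ValueError(f"need >=3 old {sex} participants with {test} values, have {len(samples)}")
    X = expr.loc[candidates, samples].T  # samples x genes
    y = cohort.loc[samples, test]
    ranker = CorrelationRanker(k=k, score_mode=score_mode).fit(X, y)
    entries = [
        CorrelationResult(
            gene_id=str(ranker.feature_names_in_[j]),
            sex=sex,
            test=test,
            pearson_r=float(ranker.pearson_r_[j]),
            spearman_rho=float(ranker.spearman_rho_[j]),
            combined_score=float(ranker.combined_score_[j]),
            n=int(ranker.n_used_[j]),
            flag=str(ranker.flags_[j]),
        )
        for j in ranker.top_k()
    ]
    return RankedList(sex=sex, test=test, k=k, entries=entries)


def all_correlations(
    expr: pd.DataFrame,
    cohort: pd.DataFrame,
    candidates,
    k: int = 40,
    score_mode: str = "min",
    sexes=SEXES,
    tests=TEST_NAMES,
) -> pd.DataFrame:
    """Long-format correlation table over every (sex, test) stratum present."""
    frames = []
    candidates = sorted(set(candidates))
    for sex in sexes:
        for test in tests:
            mask = (cohort["sex"] == sex) & (cohort["age_group"] == "old") & cohort[test].notna()
            samples = cohort.index[mask]
            if len(samples) < 3:
                continue
            X = expr.loc[candidates, samples].T
            y = cohort.loc[samples, test]
            ranker = CorrelationRanker(k=k, score_mode=score_mode).fit(X, y)
            frames.append(ranker.results_frame(sex=sex, test=test))
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "sex", "test", "pearson_r", "spearman_rho",
                     "combined_score", "n", "flag"]
        )
    return pd.concat(frames, ignore_index=True)


def run_all(
    expr: pd.DataFrame,
    cohort: pd.DataFrame,
    candidates,
    k: int = 40,
    score_mode: str = "min",
    sexes=SEXES,
    tests=TEST_NAMES,
) -> tuple[dict, list]:
    """One RankedList per (sex, test) stratum.

    Returns ``(lists, skipped)`` where ``lists`` maps (sex, test) to a
    RankedList and ``skipped`` names strata with fewer than 3 usable
    participants.
    """
    lists: dict = {}
    skipped: list = []
    for sex in sexes:
        for test in tests:
            mask = (cohort["sex"] == sex) & (cohort["age_group"] == "old") & cohort[test].notna()
            if mask.sum() < 3:
                skipped.append((sex, test))
                continue
            lists[(sex, test)] = rank_candidates(
                expr, cohort, sex, test, candidates, k=k, score_mode=score_mode
            )
    return lists, skipped


def ranked_list_frame(rl: RankedList) -> pd.DataFrame:
    rows = [
        {
            "rank": i + 1,
            "gene_id": e.gene_id,
            "sex": e.sex,
            "test": e.test,
            "pearson_r": e.pearson_r,
            "spearman_rho": e.spearman_rho,
            "combined_score": e.combined_score,
            "n": e.n,
        }
        for i, e in enumerate(rl.entries)
    ]
    return pd.DataFrame(
        rows,
        columns=["rank", "gene_id", "sex", "test", "pearson_r", "spearman_rho",
                 "combined_score", "n"],
    )
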