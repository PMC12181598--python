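"""Fittest/weakest classification and biomarker-panel ROC comparison.

Older adults of one sex are split into the fittest and weakest halves of
their group by the average of their per-test ascending ranks over two named
function tests.  Logistic regression on standardized features then scores
each panel (age+BMI, sex-matched markers, cross-sex markers, combined), and
each panel's in-sample ROC/AUC is tested against chance with the normal
approximation to the Mann–Whitney statistic (tie-corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

import statsmodels.api as sm

# weak L2 fallback applied only when the unpenalized ML fit separates
_RIDGE_C = 1000.0


@dataclass
class HalfSplit:
    sex: str | None
    tests: tuple
    labels: pd.Series  # sample_id -> {'fittest', 'weakest'}
    composite_rank: pd.Series
    excluded: list = field(default_factory=list)

    def binary(self) -> pd.Series:
        """1 = weakest (the positive class to detect), 0 = fittest."""
        return (self.labels == "weakest").astype(int)


@dataclass
class FittedLogistic:
    feature_names: list
    coef: np.ndarray  # on standardized scale, intercept last
    probabilities: pd.Series
    separation_flag: bool
    converged: bool


@dataclass
class RocResult:
    name: str
    features: list
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    p_vs_chance: float
    n_pos: int
    n_neg: int
    flags: list = field(default_factory=list)


def split_half(cohort: pd.DataFrame, sex: str, test_pair: tuple) -> HalfSplit:
    """Median split of one sex's old participants on two-test composite rank.

    Per-test ascending ranks (fastest = lowest, ties averaged) are averaged;
    the faster half is 'fittest'.  With odd n the median participant joins
    the fittest half.  Composite ties break by the first test's time, then
    sample id.  Participants missing either test are excluded and listed.
    """
    t1, t2 = test_pair
    old = cohort[(cohort["sex"] == sex) & (cohort["age_group"] == "old")]
    usable = old[[t1, t2]].dropna()
    excluded = sorted(old.index.difference(usable.index))
    n = len(usable)
    if n < 4:
        raise ValueError(f"split_half needs >=4 old {sex} participants with both tests, have {n}")
    ranks = pd.DataFrame(
        {t: stats.rankdata(usable[t]) for t in (t1, t2)}, index=usable.index
    )
    composite = ranks.mean(axis=1)
    order = pd.DataFrame({"comp": composite, "t1": usable[t1]})
    order = order.reset_index()
    id_col = order.columns[0]
    order = order.sort_values(["comp", "t1", id_col], kind="stable")
    n_fit = (n + 1) // 2  # odd n: median participant goes to fittest
    labels = pd.Series("weakest", index=order[id_col].to_numpy(), name="half")
    labels.iloc[:n_fit] = "fittest"
    return HalfSplit(
        sex=sex, tests=(t1, t2), labels=labels.loc[usable.index],
        composite_rank=composite, excluded=excluded,
    )


def fit_logistic(features: pd.DataFrame, labels: pd.Series) -> FittedLogistic:
    """Maximum-likelihood logistic regression on internally standardized features.

    Constant features raise a ValueError naming them.  If the unpenalized
    fit shows (quasi-)separation — non-convergence or runaway coefficients —
    the model is refit with a weak L2 penalty and flagged.
    """
    X = features.astype(float)
    y = np.asarray(labels, dtype=float)
    if len(X) < X.shape[1] + 1:
        raise ValueError(f"need n >= n_features+1, have n={len(X)} for {X.shape[1]} features")
    const = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if const:
        raise ValueError(f"constant feature(s): {const}")
    Xs = (X - X.mean()) / X.std(ddof=0)
    design = sm.add_constant(Xs.to_numpy(), has_constant="add")

    separated, converged = False, True
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            params = fit.params
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            converged = False
    if params is None or not converged or np.max(np.abs(params)) > 15:
        separated = True
        clf = LogisticRegression(C=_RIDGE_C, solver="lbfgs", max_iter=2000)
        clf.fit(Xs.to_numpy(), y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        lin = params[0] + Xs.to_numpy() @ params[1:]
    else:
        lin = design @ params
        params = np.concatenate([[params[0]], params[1:]])
    probs = 1.0 / (1.0 + np.exp(-lin))
    return FittedLogistic(
        feature_names=list(X.columns),
        coef=np.asarray(params, dtype=float),
        probabilities=pd.Series(probs, index=X.index, name="p_weakest"),
        separation_flag=separated,
        converged=converged or separated,
    )


def _mwu_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC as tie-corrected U/(n1·n0) and its two-sided p against 0.5."""
    n1 = int(labels.sum())
    n0 = int(len(labels) - n1)
    ranks = stats.rankdata(scores)
    u1 = float(ranks[labels == 1].sum() - n1 * (n1 + 1) / 2)
    auc = u1 / (n1 * n0)
    n = n1 + n0
    _, counts = np.unique(scores, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n0 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return auc, 1.0
    z = (u1 - n1 * n0 / 2.0) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc, float(min(p, 1.0))


def roc_auc(scores, labels, name: str = "model", features=None) -> RocResult:
    """ROC points and trapezoidal AUC with significance against chance.

    AUC equals the tie-corrected Mann–Whitney U divided by n_pos·n_neg
    (ties get half credit); ``p_vs_chance`` is the two-sided normal
    approximation to the U statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc, p = _mwu_auc(scores, labels)
    return RocResult(
        name=name, features=list(features or []), fpr=fpr, tpr=tpr,
        auc=float(auc), p_vs_chance=p, n_pos=n_pos, n_neg=n_neg,
    )


def compare_models(
    cohort: pd.DataFrame,
    serum: pd.DataFrame,
    sex: str,
    test_pair: tuple,
    panels: dict,
) -> tuple[list, HalfSplit]:
    """One ROC result per feature panel on a shared fittest/weakest split.

    ``panels`` maps panel name -> feature list; features are 'age', 'bmi'
    or serum marker columns.  The positive class is the weakest half.
    """
    split = split_half(cohort, sex, test_pair)
    samples = split.labels.index
    y = split.binary()
    table = pd.concat([cohort.loc[samples, ["age", "bmi"]], serum.reindex(samples)], axis=1)
    results = []
    for name, feats in panels.items():
        missing = [f for f in feats if f not in table.columns]
        if missing:
            raise KeyError(f"panel {name!r} references unknown features: {missing}")
        model = fit_logistic(table[list(feats)], y)
        res = roc_auc(model.probabilities.to_numpy(), y.to_numpy(), name=name, features=list(feats))
        if model.separation_flag:
            res.flags.append("separation_ridge")
        res.flags.append("in_sample")
        results.append(res)
    return results, split
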