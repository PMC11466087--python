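"""The predictor-selection funnel.

Candidate Pfam domains pass four stages: (1) a universality filter keeps
domains present in every training genome (guards against overfitting to
rare domains), (2) an abundance filter keeps domains with mean occurrence
per genome strictly greater than a threshold (2 by default), (3) Boruta
shadow-feature selection keeps domains whose random-forest importance
repeatedly beats the best permuted copy, and (4) stepwise pruning removes
the least important survivor while cross-validated accuracy does not
drop, yielding the most parsimonious predictor set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from tolrad._importance import oob_mda
from tolrad.annotations_io import FrequencyTable, PfamAnnotationSet

__all__ = [
    "BorutaResult",
    "filter_universal",
    "filter_abundant",
    "boruta_select",
    "stepwise_prune",
]


def filter_universal(sets: list[PfamAnnotationSet]) -> list[str]:
    """Domains with at least one instance in *every* input genome (sorted)."""
    if not sets:
        raise ValueError("need at least one annotation set")
    universal = set(sets[0].domain_counts())
    for s in sets[1:]:
        universal &= set(s.domain_counts())
    return sorted(universal)


def filter_abundant(
    sets: list[PfamAnnotationSet], domains: list[str], min_mean: float = 2.0
) -> list[str]:
    """Domains whose mean occurrence per genome is strictly greater than ``min_mean``."""
    n = len(sets)
    totals: dict[str, int] = {d: 0 for d in domains}
    for s in sets:
        counts = s.domain_counts()
        for d in totals:
            totals[d] += counts.get(d, 0)
    return sorted(d for d, c in totals.items() if c / n > min_mean)


@dataclass
class BorutaResult:
    """Outcome of a Boruta run: confirmed/rejected/tentative partition the input."""

    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    n_iterations: int
    hit_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confirmed": self.confirmed,
            "rejected": self.rejected,
            "tentative": self.tentative,
            "n_iterations": self.n_iterations,
            "hit_counts": self.hit_counts,
        }


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, FrequencyTable):
        return X.frequencies
    return pd.DataFrame(X)


def boruta_select(
    X,
    y,
    max_runs: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    forest_params: dict | None = None,
) -> BorutaResult:
    """Boruta all-relevant feature selection with shadow features.

    Each iteration appends an independently permuted "shadow" copy of
    every undecided feature, fits a random forest on real+shadow columns,
    and scores per-feature importance as out-of-bag mean decrease in
    accuracy.  A real feature scores a *hit* when its importance exceeds
    the maximum shadow importance.  After each iteration a two-sided
    binomial test of the hit count against Binomial(n_iterations, 1/2),
    Bonferroni-corrected across the currently undecided features,
    confirms (significantly more hits) or rejects (significantly fewer)
    features.  Features still undecided after ``max_runs`` iterations are
    tentative and are treated as not selected downstream.
    """
    df = _as_frame(X)
    y = np.asarray(y)
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("boruta_select needs at least two classes in y")
    if class_counts.min() < 2:
        raise ValueError("each class needs at least 2 genomes")
    if df.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    params = {"n_estimators": 100, "max_features": "sqrt"}
    params.update(forest_params or {})

    features = list(df.columns)
    rejected: list[str] = []
    variances = df.var(axis=0, ddof=0)
    for feat in features:
        if variances[feat] == 0:
            warnings.warn(f"zero-variance feature {feat!r} auto-rejected")
            rejected.append(feat)
    undecided = [f for f in features if f not in rejected]
    confirmed: list[str] = []
    hits: dict[str, int] = {f: 0 for f in features}
    rng = np.random.default_rng(seed)
    n = df.shape[0]

    n_iter = 0
    while undecided and n_iter < max_runs:
        n_iter += 1
        real_cols = confirmed + undecided
        X_real = df[real_cols].to_numpy(dtype=np.float64)
        shadows = df[undecided].to_numpy(dtype=np.float64).copy()
        for j in range(shadows.shape[1]):
            shadows[:, j] = shadows[rng.permutation(n), j]
        X_iter = np.hstack([X_real, shadows])
        forest = RandomForestClassifier(
            random_state=int(rng.integers(2**31 - 1)), bootstrap=True, **params
        )
        forest.fit(X_iter, y)
        imp = oob_mda(forest, X_iter, y, rng, n_repeats=1)
        shadow_max = imp[len(real_cols):].max()
        for j, feat in enumerate(undecided):
            if imp[len(confirmed) + j] > shadow_max:
                hits[feat] += 1
        # binomial decisions, Bonferroni across currently undecided features
        m = len(undecided)
        thr = alpha / (2 * m)
        still: list[str] = []
        for feat in undecided:
            h = hits[feat]
            p_greater = float(binom.sf(h - 1, n_iter, 0.5))
            p_less = float(binom.cdf(h, n_iter, 0.5))
            if p_greater < thr:
                confirmed.append(feat)
            elif p_less < thr:
                rejected.append(feat)
            else:
                still.append(feat)
        undecided = still

    return BorutaResult(
        confirmed=sorted(confirmed),
        rejected=sorted(rejected),
        tentative=sorted(undecided),
        n_iterations=n_iter,
        hit_counts=dict(hits),
    )


def _cv_accuracy(
    df: pd.DataFrame, y: np.ndarray, cv_folds: int, n_trees: int, seed: int
) -> float:
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed
    )
    scores = cross_val_score(forest, df.to_numpy(dtype=np.float64), y, cv=cv)
    return float(np.mean(scores))


def stepwise_prune(
    X,
    y,
    features: list[str],
    cv_folds: int = 10,
    seed: int = 0,
    n_trees: int = 300,
    mda_repeats: int = 10,
    mda_threshold: float = 2.5,
) -> tuple[list[str], list[dict]]:
    """Stepwise removal of the lowest-importance predictor.

    Starting from ``features``, the candidate with the lowest permutation
    mean decrease in accuracy (ties broken lexicographically) is removed
    when (a) the cross-validated accuracy of the reduced set is at least
    that of the current set and (b) the candidate's mean decrease in
    accuracy is at most ``mda_threshold`` percentage points, i.e. its
    measured importance is indistinguishable from permutation noise;
    otherwise the loop stops.  Condition (b) keeps sets of mutually
    redundant informative predictors from collapsing to one: on cleanly
    separable data every subset scores the same CV accuracy, so an
    accuracy comparison alone cannot see that a removed predictor
    carried signal.  Never returns an empty set.  The audit trail
    records each candidate removal, both accuracies, the candidate's
    importance, and the decision.
    """
    df = _as_frame(X)
    y = np.asarray(y)
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("stepwise_prune needs both classes present")
    if len(features) < 2:
        raise ValueError("stepwise_prune needs at least 2 features")
    if cv_folds > class_counts.min():
        raise ValueError(
            f"cv_folds={cv_folds} exceeds the smallest class count "
            f"({class_counts.min()}); use fewer folds"
        )
    rng = np.random.default_rng(seed)
    current = list(features)
    audit: list[dict] = []
    acc_current: float | None = None
    while len(current) > 1:
        if acc_current is None:  # after an accepted removal, reuse the reduced-set CV
            acc_current = _cv_accuracy(df[current], y, cv_folds, n_trees, seed)
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed
        )
        forest.fit(df[current].to_numpy(dtype=np.float64), y)
        mda = oob_mda(
            forest, df[current].to_numpy(dtype=np.float64), y, rng, n_repeats=mda_repeats
        )
        order = sorted(range(len(current)), key=lambda i: (mda[i], current[i]))
        candidate = current[order[0]]
        candidate_mda_pct = float(100.0 * mda[order[0]])
        reduced = [f for f in current if f != candidate]
        acc_reduced = _cv_accuracy(df[reduced], y, cv_folds, n_trees, seed)
        accept = acc_reduced >= acc_current and candidate_mda_pct <= mda_threshold
        audit.append(
            {
                "removed_candidate": candidate,
                "mda_percent": candidate_mda_pct,
                "accuracy_current": acc_current,
                "accuracy_reduced": acc_reduced,
                "accepted": bool(accept),
            }
        )
        if not accept:
            break
        current = reduced
        acc_current = acc_reduced
    return current, audit
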