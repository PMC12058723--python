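"""Scoring of inferred state sequences and factorial statistics.

Inferred state labels are aligned to ground truth with the Hungarian
(Munkres) assignment on indicator correlations; recovery is summarized
as the mean per-state Pearson correlation between matched binary
indicator time courses.  Condition effects are tested with one-way
Welch's heteroscedastic ANOVA and Games-Howell post-hoc pairwise
comparisons at alpha = 0.01 with 99% confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy.optimize import linear_sum_assignment
from scipy.stats import studentized_range

from .hmm_inference import StateTimeCourse
from .markov_states import StateSequence

__all__ = [
    "EvaluationResult",
    "match_states",
    "matched_correlation",
    "welch_anova",
    "games_howell",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    permutation: np.ndarray     # permutation[m] = truth state assigned to inferred state m
    per_state_r: np.ndarray     # (K,) correlations indexed by truth state
    mean_r: float
    condition: dict = field(default_factory=dict)
    repetition: int = 0


def _indicators(labels: np.ndarray, K: int) -> np.ndarray:
    ind = np.zeros((K, labels.size))
    ind[labels, np.arange(labels.size)] = 1.0
    return ind


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _aligned_truth(inferred: StateTimeCourse, truth: StateSequence) -> np.ndarray:
    T = inferred.path.size
    start = inferred.offset
    if start + T > truth.n_samples:
        raise ValueError("inferred path longer than the cropped truth span")
    return truth.labels[start:start + T]


def match_states(inferred: StateTimeCourse, truth: StateSequence) -> np.ndarray:
    """Hungarian alignment of inferred to true state labels.

    Cost(k, m) = -corr(truth indicator k, inferred indicator m); returns
    `perm` with perm[m] = matched truth state for inferred state m.
    linear_sum_assignment's deterministic scan breaks ties toward lower
    indices.
    """
    K = truth.n_states
    if inferred.posteriors.shape[0] != K:
        raise ValueError("state count mismatch between model and ground truth")
    t_labels = _aligned_truth(inferred, truth)
    ti = _indicators(t_labels, K)
    ii = _indicators(inferred.path, K)
    cost = np.empty((K, K))
    for k in range(K):
        for m in range(K):
            cost[k, m] = -_safe_corr(ti[k], ii[m])
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=np.int64)
    perm[cols] = rows
    return perm


def matched_correlation(inferred: StateTimeCourse, truth: StateSequence,
                        permutation: np.ndarray,
                        condition: dict | None = None,
                        repetition: int = 0,
                        use_posteriors: bool = False) -> EvaluationResult:
    """Per-state Pearson correlation of matched indicator time courses.

    With `use_posteriors` the inferred side is the soft posterior
    probability course instead of the hard Viterbi indicator.  States
    never visited by one of the sequences have a constant indicator;
    they contribute r = 0 (logged) so mean_r stays comparable across
    runs.
    """
    K = truth.n_states
    t_labels = _aligned_truth(inferred, truth)
    if t_labels.size != inferred.path.size:
        raise ValueError("length mismatch")
    ti = _indicators(t_labels, K)
    ii = inferred.posteriors if use_posteriors else _indicators(inferred.path, K)
    per_state = np.zeros(K)
    for m in range(K):
        k = permutation[m]
        r = _safe_corr(ti[k], ii[m])
        if ti[k].std() == 0 or ii[m].std() == 0:
            logger.warning("constant indicator for matched pair (truth=%d, inferred=%d); r := 0", k, m)
        per_state[k] = r
    return EvaluationResult(permutation=np.asarray(permutation),
                            per_state_r=per_state, mean_r=float(per_state.mean()),
                            condition=condition or {}, repetition=repetition)


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least two values")
        if g.var(ddof=1) == 0:
            raise ValueError("degenerate group with zero variance")
    return groups


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """One-way Welch heteroscedastic ANOVA; returns (F, df1, df2, p)."""
    groups = _check_groups(groups)
    values = np.concatenate(groups)
    labels = np.concatenate([np.full(g.size, i) for i, g in enumerate(groups)])
    df = pd.DataFrame({"y": values, "g": labels})
    res = pg.welch_anova(data=df, dv="y", between="g")
    return (float(res["F"].iloc[0]), float(res["ddof1"].iloc[0]),
            float(res["ddof2"].iloc[0]), float(res["p_unc"].iloc[0]))


def games_howell(groups: list[np.ndarray], alpha: float = 0.01,
                 labels: list | None = None) -> pd.DataFrame:
    """Games-Howell pairwise comparisons with (1 - alpha) confidence intervals.

    Per pair: mean difference, SE = sqrt(s1^2/n1 + s2^2/n2),
    Welch-Satterthwaite df, p from the studentized-range distribution
    with k groups, and a CI of half-width q_crit/sqrt(2) * SE.
    """
    groups = _check_groups(groups)
    k = len(groups)
    labels = labels if labels is not None else list(range(k))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            na, nb = a.size, b.size
            va, vb = a.var(ddof=1), b.var(ddof=1)
            diff = a.mean() - b.mean()
            se = np.sqrt(va / na + vb / nb)
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            q_stat = np.abs(diff) / se * np.sqrt(2)
            p = float(studentized_range.sf(q_stat, k, df))
            q_crit = studentized_range.ppf(1 - alpha, k, df)
            half = q_crit / np.sqrt(2) * se
            rows.append(dict(A=labels[i], B=labels[j], mean_diff=diff, se=se,
                             df=df, p=p, ci_lower=diff - half, ci_upper=diff + half))
    return pd.DataFrame(rows)
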