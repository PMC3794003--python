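"""ANOVA F-score feature ranking and incremental feature selection (IFS).

Each of the 400 g-gap dipeptide frequencies is scored by the one-way ANOVA
F statistic across the two classes,

    F = MSB / MSW,   MSB = SSB / (K - 1),   MSW = SSW / (M - K),

where SSB is the between-group and SSW the within-group sum of squares,
K the number of groups (2) and M the total sample count.  A feature whose
between-class variation dwarfs its within-class variation gets a large F
and is more discriminative; with no class difference F sits near 1.

IFS then evaluates the nested subsets S_1 c S_2 c ... c S_400 formed by
adding features in descending F order, measuring leave-one-out (jackknife)
accuracy of an RBF SVM for each subset size t, and keeps the size at the
accuracy peak.  Scanning gaps g = 0..g_max and taking the globally best
peak yields the operating point (g0, t0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ggap_features import DIPEPTIDES, N_FEATURES, GGapFeatureMatrix
from .sequence_io import CLASS_NAMES


def f_score(groups: Sequence[Sequence[float]]) -> float:
    """One-way ANOVA F statistic for K groups of values.

    Returns ``inf`` when the within-group variation is exactly zero while
    groups differ (the feature separates the sample perfectly) and ``0.0``
    when all values are identical.

    Raises
    ------
    ValueError
        With fewer than two groups, an empty group, or M <= K.
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    K = len(arrays)
    if K < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    M = sum(a.size for a in arrays)
    if M <= K:
        raise ValueError(f"need more samples ({M}) than groups ({K})")
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0:
        return float("inf") if ssb > 0.0 else 0.0
    msb = ssb / (K - 1)
    msw = ssw / (M - K)
    return float(msb / msw)


def f_pvalue(f_value: float, df_between: int, df_within: int) -> float:
    """Upper-tail probability of the F(df_between, df_within) distribution."""
    if f_value < 0:
        raise ValueError("F value must be non-negative")
    if df_between < 1 or df_within < 1:
        raise ValueError("degrees of freedom must be positive")
    if np.isinf(f_value):
        return 0.0
    return float(stats.f.sf(f_value, df_between, df_within))


@dataclass
class FScoreRanking:
    """Per-feature F values, p-values and the descending rank order.

    ``order[k]`` is the (0-based) column index of the k-th ranked feature.
    Ties are broken by ascending canonical dipeptide index so the ranking
    is deterministic; infinite F values rank before all finite ones.
    """

    f_values: np.ndarray
    p_values: np.ndarray
    order: np.ndarray
    gap: int | None = None

    def top(self, t: int) -> np.ndarray:
        """Column indices of the top-``t`` ranked features."""
        if not 1 <= t <= len(self.order):
            raise ValueError(f"subset size must be in 1..{len(self.order)}")
        return self.order[:t]

    def to_frame(self) -> pd.DataFrame:
        dipeptide = [DIPEPTIDES[i] for i in self.order]
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "dipeptide": dipeptide,
                "gap": self.gap,
                "F": self.f_values[self.order],
                "p_value": self.p_values[self.order],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _column_f_scores(values: np.ndarray, group_masks: list[np.ndarray]) -> np.ndarray:
    """Vectorised one-way ANOVA F over matrix columns (same formula as f_score)."""
    M = values.shape[0]
    K = len(group_masks)
    grand = values.mean(axis=0)
    ssb = np.zeros(values.shape[1])
    ssw = np.zeros(values.shape[1])
    for mask in group_masks:
        sub = values[mask]
        mean_i = sub.mean(axis=0)
        ssb += mask.sum() * (mean_i - grand) ** 2
        ssw += ((sub - mean_i) ** 2).sum(axis=0)
    msb = ssb / (K - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb * (M - K) / ssw
    f[ssw == 0.0] = np.inf
    f[(ssw == 0.0) & (ssb == 0.0)] = 0.0
    return f


def rank_features(matrix: GGapFeatureMatrix) -> FScoreRanking:
    """Score every column by ANOVA F across the two classes and rank descending.

    Raises
    ------
    ValueError
        If the matrix is unlabelled, has fewer than two classes, or a class
        has fewer than two samples.
    """
    if matrix.labels is None:
        raise ValueError("feature matrix has no labels")
    labels = np.asarray(matrix.labels)
    present = [c for c in CLASS_NAMES if (labels == c).any()]
    if len(present) < 2:
        raise ValueError("need samples from both classes to rank features")
    masks = [labels == c for c in present]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each class needs at least two samples")
    f = _column_f_scores(matrix.values, masks)
    M, K = matrix.n_samples, len(masks)
    p = np.array([f_pvalue(v, K - 1, M - K) for v in f])
    # descending F, ties by ascending canonical index; inf first
    order = np.lexsort((np.arange(len(f)), -f))
    return FScoreRanking(f_values=f, p_values=p, order=order, gap=matrix.gap)


@dataclass(frozen=True)
class FeatureSubset:
    """The top-``size`` features of a ranking at one gap."""

    gap: int
    size: int
    member_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.size <= N_FEATURES:
            raise ValueError("subset size must be in 1..400")
        if len(set(self.member_indices)) != self.size:
            raise ValueError("member_indices must be distinct and match size")


def ifs_subsets(ranking: FScoreRanking, t_max: int = N_FEATURES):
    """Yield the nested IFS subsets S_1 c S_2 c ... c S_t_max."""
    gap = ranking.gap if ranking.gap is not None else -1
    for t in range(1, t_max + 1):
        yield FeatureSubset(gap=gap, size=t, member_indices=tuple(ranking.order[:t]))


def count_candidate_subsets(gap_min: int, gap_max: int, t_max: int = N_FEATURES) -> int:
    """Number of candidate feature subsets in a full IFS scan over a gap range."""
    if gap_max < gap_min or gap_min < 0:
        raise ValueError("invalid gap range")
    return (gap_max - gap_min + 1) * t_max


@dataclass
class IFSResult:
    """Jackknife accuracy for every IFS subset size at one gap, with its peak."""

    gap: int
    accuracies: np.ndarray  # one entry per subset size t = 1..t_max
    peak_t: int  # smallest t attaining the maximum (1-based)
    peak_accuracy: float
    c_value: float | None = None
    gamma_value: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": np.arange(1, len(self.accuracies) + 1), "accuracy": self.accuracies}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def ifs_scan(
    matrix: GGapFeatureMatrix,
    ranking: FScoreRanking,
    grid_spec=None,
    mode: str = "fast",
    t_max: int = N_FEATURES,
) -> IFSResult:
    """Run the IFS scan at one gap: jackknife accuracy for t = 1..t_max.

    ``mode='fast'`` optimises the SVM grid once on the full feature matrix
    and reuses that (C, gamma) across all subset sizes; ``mode='regrid'``
    re-runs the grid search for every subset (exhaustive, far slower).
    Returns the full accuracy curve and its peak (smallest t on ties).
    """
    from .svm_engine import SVMGridSpec, grid_search, jackknife_evaluate

    if mode not in ("fast", "regrid"):
        raise ValueError("mode must be 'fast' or 'regrid'")
    spec = grid_spec if grid_spec is not None else SVMGridSpec()
    labels = np.asarray(matrix.labels)
    if mode == "fast":
        c_value, gamma_value, _ = grid_search(matrix.values, labels, spec)
    accuracies = np.empty(t_max, dtype=np.float64)
    for t in range(1, t_max + 1):
        sub = matrix.values[:, ranking.order[:t]]
        if mode == "regrid":
            c_value, gamma_value, _ = grid_search(sub, labels, spec)
        counts = jackknife_evaluate(sub, labels, c_value, gamma_value)
        accuracies[t - 1] = counts.accuracy
    peak_t = int(np.argmax(accuracies)) + 1  # argmax takes the first (smallest t)
    return IFSResult(
        gap=matrix.gap,
        accuracies=accuracies,
        peak_t=peak_t,
        peak_accuracy=float(accuracies[peak_t - 1]),
        c_value=c_value if mode == "fast" else None,
        gamma_value=gamma_value if mode == "fast" else None,
    )


def select_optimal(results: Sequence[IFSResult]) -> tuple[int, int, float]:
    """Pick the (gap g0, size t0) with the globally maximal peak accuracy.

    Ties are broken by smaller gap, then smaller subset size.
    """
    if not results:
        raise ValueError("no IFS results to select from")
    best = min(results, key=lambda r: (-r.peak_accuracy, r.gap, r.peak_t))
    return best.gap, best.peak_t, best.peak_accuracy
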