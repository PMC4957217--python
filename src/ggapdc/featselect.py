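"""ANOVA F-score feature ranking and signed min-max normalization.

For each of the 400 dipeptide features, the discriminative power between
the two classes is measured with the classical two-group one-way ANOVA F
statistic,

    F(x) = MS_between / MS_within,

where MS_between = m_p (xbar_p - xbar)^2 + m_n (xbar_n - xbar)^2 (K - 1 = 1
degrees of freedom with K = 2 groups) and MS_within is the pooled
within-group sum of squares divided by m_p + m_n - 2. For two groups F is
exactly the square of the pooled-variance two-sample t statistic.

For the preference heat map, F is min-max scaled to [0, 1] and given the
sign of (mean frequency in positives - mean frequency in negatives), so the
top-ranked feature maps to +1 or -1 depending on which class it is
enriched in, and the lowest-F feature maps to 0.

Degenerate features: zero variance both between and within groups gives
F = 0 (uninformative); positive between-group but zero within-group
variance separates the classes perfectly and gets F = +inf, ranked above
every finite value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ContractError, DataError, DegenerateScoreError
from .features import PAIR_NAMES, FeatureMatrix

__all__ = [
    "FScoreTable",
    "fscore",
    "signed_normalized_fscore",
    "rank_features",
    "score_features",
    "fscore_table_to_tsv",
    "fscore_table_from_tsv",
]


@dataclass
class FScoreTable:
    """Per-feature F-scores, class means, signed normalized scores and ranks."""

    names: tuple[str, ...]
    F: np.ndarray
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    grand_mean: np.ndarray
    m_pos: int
    m_neg: int
    signed_norm: np.ndarray | None = field(default=None)
    #: rank[i] is the 1-based position of feature i after descending-F sort.
    rank: np.ndarray | None = field(default=None)
    #: feature indices in rank order (order[0] is the top feature).
    order: np.ndarray | None = field(default=None)

    @property
    def n_features(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        if self.signed_norm is None or self.rank is None:
            raise ContractError("table incomplete: compute signed scores and ranks first")
        return pd.DataFrame(
            {
                "dipeptide": list(self.names),
                "F": self.F,
                "signed_norm": self.signed_norm,
                "rank": self.rank,
                "mean_pos": self.mean_pos,
                "mean_neg": self.mean_neg,
            }
        )


def fscore(matrix: FeatureMatrix) -> FScoreTable:
    """Two-group one-way ANOVA F for every feature of a labelled matrix.

    Requires at least two samples in each class (the within-group variance
    is undefined otherwise).
    """
    y = matrix.y
    m_p, m_n = matrix.m_pos, matrix.m_neg
    if m_p == 0 or m_n == 0:
        raise DataError("both classes must be present to compute F-scores")
    if m_p < 2 or m_n < 2:
        raise DataError(
            f"need >= 2 samples per class (got {m_p} positive, {m_n} negative); "
            "within-group variance is undefined otherwise"
        )
    Xp = matrix.X[y == 1]
    Xn = matrix.X[y == 0]
    mean_pos = Xp.mean(axis=0)
    mean_neg = Xn.mean(axis=0)
    grand = matrix.X.mean(axis=0)

    ss_between = m_p * (mean_pos - grand) ** 2 + m_n * (mean_neg - grand) ** 2
    ms_between = ss_between  # K - 1 = 1
    ss_within = ((Xp - mean_pos) ** 2).sum(axis=0) + ((Xn - mean_neg) ** 2).sum(axis=0)
    ms_within = ss_within / (m_p + m_n - 2)

    F = np.zeros_like(ms_between)
    ok = ms_within > 0
    F[ok] = ms_between[ok] / ms_within[ok]
    # zero within-group variance: perfect separation -> +inf; flat feature -> 0
    F[~ok & (ms_between > 0)] = np.inf
    return FScoreTable(
        names=PAIR_NAMES if matrix.X.shape[1] == len(PAIR_NAMES)
        else tuple(f"x{i}" for i in range(matrix.X.shape[1])),
        F=F,
        mean_pos=mean_pos,
        mean_neg=mean_neg,
        grand_mean=grand,
        m_pos=m_p,
        m_neg=m_n,
    )


def signed_normalized_fscore(table: FScoreTable) -> np.ndarray:
    """Min-max scale F to [0, 1] and apply the enrichment sign.

    signed_norm(x) = sgn(mean_pos - mean_neg) * (F - F_min) / (F_max - F_min),
    with F_min/F_max taken over the finite scores. Perfect-separation
    sentinel features (F = +inf) map to sign * 1. Stores the result on the
    table and returns it.
    """
    F = table.F
    finite = np.isfinite(F)
    sign = np.sign(table.mean_pos - table.mean_neg)
    if not finite.any():
        table.signed_norm = sign.copy()
        return table.signed_norm
    f_min = float(F[finite].min())
    f_max = float(F[finite].max())
    if f_max == f_min and finite.all():
        raise DegenerateScoreError(
            "all features have identical F-scores; min-max normalization is "
            "undefined (check that the dataset carries any class signal)"
        )
    norm = np.zeros_like(F)
    if f_max > f_min:
        norm[finite] = (F[finite] - f_min) / (f_max - f_min)
    norm[~finite] = 1.0
    table.signed_norm = sign * norm
    return table.signed_norm


def rank_features(table: FScoreTable) -> np.ndarray:
    """Feature indices sorted by descending F, deterministically.

    Perfect-separation sentinels (F = +inf) come first, ordered by
    |mean_pos - mean_neg| descending then name; finite ties are broken by
    ascending dipeptide name. Stores ``order`` and 1-based ``rank`` on the
    table and returns the order.
    """
    F = table.F
    absdiff = np.abs(table.mean_pos - table.mean_neg)

    def key(i: int):
        if np.isinf(F[i]):
            return (0, -absdiff[i], 0.0, table.names[i])
        return (1, 0.0, -F[i], table.names[i])

    order = np.array(sorted(range(table.n_features), key=key), dtype=int)
    rank = np.empty_like(order)
    rank[order] = np.arange(1, table.n_features + 1)
    table.order = order
    table.rank = rank
    return order


def score_features(matrix: FeatureMatrix) -> FScoreTable:
    """Convenience: F-scores, signed normalized scores and ranks in one call."""
    table = fscore(matrix)
    signed_normalized_fscore(table)
    rank_features(table)
    return table


def fscore_table_to_tsv(table: FScoreTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def fscore_table_from_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
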