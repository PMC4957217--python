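"""Incremental feature selection (IFS) over the F-score ranking.

Features are sorted by descending F-score and evaluated as growing
prefixes: the top-1 feature alone, then the top 2, and so on until all 400
features are included, computing the cross-validated overall accuracy at
each size. The optimal subset is the smallest prefix attaining the maximal
OA. Sweeping the gap parameter g produces one such curve per g; the global
optimum across the sweep identifies the gap at which residue correlations
are most informative.

The fold split is fixed once per (g, seed) and reused for every prefix so
the curve reflects feature-set changes only, not fold-resampling noise.
Hyperparameters are either re-optimized per step on a coarse grid
(``hyper="grid"``, the default) or fixed at the full-feature-set optimum
(``hyper="fixed"``, much faster).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, DataError, GgapdcError
from .features import PAIR_NAMES, FeatureMatrix, build_feature_matrix
from .featselect import score_features
from .seqio import ProteinRecord
from .svm_eval import SVMConfig, evaluate_subset, grid_search_svm, stratified_folds

logger = logging.getLogger(__name__)

__all__ = [
    "IFSCurve",
    "incremental_feature_selection",
    "select_optimal_subset",
    "sweep_g",
    "ifs_curve_to_tsv",
    "sweep_summary",
    "plot_ifs_curves",
]


@dataclass
class IFSCurve:
    """Cross-validated OA (plus Sn/Sp) at every prefix size of a ranking."""

    g: int
    sizes: np.ndarray
    oa: np.ndarray
    sn: np.ndarray
    sp: np.ndarray
    ranking: np.ndarray

    def __post_init__(self):
        d = len(self.ranking)
        if not (len(self.sizes) == len(self.oa) == d):
            raise ContractError("curve arrays must have one point per ranked feature")
        if not np.array_equal(self.sizes, np.arange(1, d + 1)):
            raise ContractError("prefix sizes must be exactly 1..D")

    @property
    def best_oa(self) -> float:
        return float(self.oa.max())

    @property
    def best_size(self) -> int:
        """Smallest prefix size attaining the maximal OA."""
        return int(self.sizes[int(np.argmax(self.oa))])


def incremental_feature_selection(
    matrix: FeatureMatrix,
    ranking: Sequence[int],
    config: SVMConfig,
    hyper: str = "grid",
) -> IFSCurve:
    """Evaluate every prefix of *ranking* by cross-validated OA.

    *ranking* must be a permutation of all feature indices. With
    ``hyper="fixed"`` and no (C, gamma) on the config, a full grid search on
    the complete feature set picks the operating point first.
    """
    ranking = np.asarray(ranking, dtype=int)
    d = matrix.X.shape[1]
    if sorted(ranking.tolist()) != list(range(d)):
        raise ContractError(
            f"ranking must be a permutation of all {d} feature indices"
        )
    folds = stratified_folds(matrix.y, config.folds, config.seed)
    if hyper == "fixed" and (config.C is None or config.gamma is None):
        C, gamma = grid_search_svm(matrix, config, folds=folds)
        config = config.with_params(C, gamma)
        logger.info("IFS g=%d: fixed hyperparameters C=%g gamma=%g", matrix.g, C, gamma)

    n = len(ranking)
    oa = np.empty(n)
    sn = np.empty(n)
    sp = np.empty(n)
    for size in range(1, n + 1):
        try:
            report = evaluate_subset(matrix, ranking[:size], config, folds, hyper)
        except GgapdcError as err:
            raise type(err)(f"IFS failed at subset size {size}: {err}") from err
        oa[size - 1] = report.oa
        sn[size - 1] = report.sn
        sp[size - 1] = report.sp
    return IFSCurve(
        g=matrix.g, sizes=np.arange(1, n + 1), oa=oa, sn=sn, sp=sp, ranking=ranking
    )


def select_optimal_subset(curve: IFSCurve) -> tuple[int, list[str]]:
    """The smallest prefix size attaining the maximal OA, with feature names."""
    if len(curve.sizes) == 0:
        raise ContractError("cannot select from an empty IFS curve")
    best = curve.best_size
    names = [PAIR_NAMES[i] for i in curve.ranking[:best]]
    return best, names


def sweep_g(
    records: Sequence[ProteinRecord],
    labels: Sequence[int],
    g_values: Sequence[int],
    config: SVMConfig,
    hyper: str = "grid",
    denominator: str = "positions",
) -> list[IFSCurve]:
    """One IFS curve per gap value; sequences too short for a g are skipped.

    A g for which too few sequences (or only one class) remain is skipped
    with a warning; if every g is skipped a :class:`DataError` is raised.
    """
    records = list(records)
    labels = np.asarray(labels, dtype=int)
    if len(records) != len(labels):
        raise DataError(f"{len(records)} records but {len(labels)} labels")
    curves: list[IFSCurve] = []
    for g in g_values:
        keep = [i for i, r in enumerate(records) if r.length >= g + 2]
        n_dropped = len(records) - len(keep)
        if n_dropped:
            logger.warning(
                "g=%d: skipping %d sequence(s) shorter than %d", g, n_dropped, g + 2
            )
        y = labels[keep]
        if len(keep) == 0 or min(np.sum(y == 1), np.sum(y == 0)) < config.folds:
            logger.warning("g=%d: too few usable sequences per class; skipping g", g)
            continue
        matrix = build_feature_matrix(
            [records[i] for i in keep], y, g, denominator=denominator
        )
        table = score_features(matrix)
        curves.append(
            incremental_feature_selection(matrix, table.order, config, hyper)
        )
    if not curves:
        raise DataError("every requested g value was skipped; no curve computed")
    return curves


def sweep_summary(curves: Sequence[IFSCurve]) -> dict:
    """The globally best (g, subset size, OA) across a sweep.

    Ties in best OA are broken toward smaller g, then smaller subset size.
    """
    if not curves:
        raise ContractError("empty sweep")
    best = min(curves, key=lambda c: (-c.best_oa, c.g, c.best_size))
    size, names = select_optimal_subset(best)
    return {
        "g": best.g,
        "best_size": size,
        "best_OA": best.best_oa,
        "features": names,
        "per_g": {str(c.g): {"best_size": c.best_size, "best_OA": c.best_oa}
                  for c in curves},
    }


def ifs_curve_to_tsv(curve: IFSCurve, path: str | Path) -> None:
    """Export columns size, OA, Sn, Sp for one curve."""
    pd.DataFrame(
        {"size": curve.sizes, "OA": curve.oa, "Sn": curve.sn, "Sp": curve.sp}
    ).to_csv(path, sep="\t", index=False)


def write_sweep_summary(curves: Sequence[IFSCurve], path: str | Path) -> None:
    Path(path).write_text(json.dumps(sweep_summary(curves), indent=2) + "\n")


def plot_ifs_curves(curves: Sequence[IFSCurve], path: str | Path) -> None:
    """Subset size vs OA, one line per g."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for curve in curves:
        ax.plot(curve.sizes, curve.oa, label=f"g={curve.g}", linewidth=1)
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("cross-validated overall accuracy")
    ax.legend(ncol=2, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
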