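"""Residue-preference outputs: the 20x20 signed-score matrix and summaries.

The signed normalized F-scores of the 400 dipeptides, arranged with the
first residue of each pair along the rows and the second along the columns,
form a preference matrix: positive cells mark pairs enriched in the
positive class, negative cells pairs enriched in the negative class, and
magnitude tracks discriminative power. Marginal means over each residue's
row and column summarize which single residues drive the signal.

Numeric exports are sign-convention-explicit (+ means positive-class
enriched); the optional heat-map plot takes a ``flip_colors`` switch since
display conventions vary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError
from .features import N_RESIDUES, FeatureMatrix
from .featselect import FScoreTable
from .seqio import ALPHABET
from .svm_eval import MetricsReport, SVMConfig, evaluate_subset, stratified_folds

__all__ = [
    "PreferenceMatrix",
    "preference_matrix",
    "residue_enrichment_summary",
    "top_k_model",
    "preference_matrix_to_tsv",
    "preference_matrix_from_tsv",
    "plot_preference_heatmap",
]

#: Fixed decimal formatting for TSV round-trips.
_TSV_FORMAT = "%.6g"


@dataclass
class PreferenceMatrix:
    """20x20 signed scores; cell (a, b) is the pair with first residue a."""

    g: int
    values: np.ndarray
    residues: str = ALPHABET

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_RESIDUES, N_RESIDUES):
            raise ContractError(
                f"preference matrix must be 20x20, got {self.values.shape}"
            )


def preference_matrix(table: FScoreTable, g: int) -> PreferenceMatrix:
    """Reshape the table's signed scores into the 20x20 pair layout.

    Flattening the result row-major reproduces the signed_norm column in
    feature-index order.
    """
    if table.signed_norm is None:
        raise ContractError(
            "signed normalized scores missing; run signed_normalized_fscore first"
        )
    if len(table.signed_norm) != N_RESIDUES * N_RESIDUES:
        raise ContractError("table does not cover all 400 dipeptides")
    return PreferenceMatrix(
        g=g, values=table.signed_norm.reshape(N_RESIDUES, N_RESIDUES)
    )


def residue_enrichment_summary(matrix: PreferenceMatrix) -> pd.Series:
    """Mean signed score of each residue over its row plus its column.

    A residue's row collects the pairs where it comes first, its column the
    pairs where it comes second; the mean over both (40 cells) scores its
    overall enrichment. Returned sorted descending (positive-class-enriched
    residues first).
    """
    v = matrix.values
    marginals = (v.sum(axis=1) + v.sum(axis=0)) / (2 * N_RESIDUES)
    return pd.Series(marginals, index=list(matrix.residues)).sort_values(
        ascending=False
    )


def top_k_model(
    matrix: FeatureMatrix,
    table: FScoreTable,
    k: int,
    config: SVMConfig,
    hyper: str = "grid",
) -> MetricsReport:
    """Cross-validated metrics using only the k top-F-ranked features.

    Uses the same fold construction and hyperparameter policy as the IFS
    loop, so the result equals the IFS curve point at size k under a shared
    seed.
    """
    if table.order is None:
        raise ContractError("feature ranking missing; run rank_features first")
    if not 1 <= k <= len(table.order):
        raise ContractError(f"k must be in 1..{len(table.order)}, got {k}")
    folds = stratified_folds(matrix.y, config.folds, config.seed)
    return evaluate_subset(matrix, table.order[:k], config, folds, hyper)


def preference_matrix_to_tsv(matrix: PreferenceMatrix, path: str | Path) -> None:
    """21x21 TSV with residue headers; values at 6 significant digits."""
    df = pd.DataFrame(
        matrix.values, index=list(matrix.residues), columns=list(matrix.residues)
    )
    df.to_csv(path, sep="\t", float_format=_TSV_FORMAT, index_label=f"g{matrix.g}")


def preference_matrix_from_tsv(path: str | Path) -> PreferenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    g = int(str(df.index.name).lstrip("g"))
    if "".join(df.index) != ALPHABET or "".join(df.columns) != ALPHABET:
        raise ContractError(f"{path}: residue headers must be {ALPHABET}")
    return PreferenceMatrix(g=g, values=df.to_numpy(float))


def write_enrichment_summary(
    matrix: PreferenceMatrix, path: str | Path, top: int = 4
) -> None:
    """Summary JSON naming the most positive- and negative-enriched residues."""
    summary = residue_enrichment_summary(matrix)
    payload = {
        "g": matrix.g,
        "positive_enriched": summary.index[:top].tolist(),
        "negative_enriched": summary.index[-top:][::-1].tolist(),
        "marginal_scores": {r: float(s) for r, s in summary.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def plot_preference_heatmap(
    matrix: PreferenceMatrix, path: str | Path, flip_colors: bool = False
) -> None:
    """Render the 20x20 signed-score matrix as a diverging heat map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = "bwr_r" if flip_colors else "bwr"
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im = ax.imshow(matrix.values, cmap=cmap, vmin=-1, vmax=1)
    ax.set_xticks(range(N_RESIDUES), list(matrix.residues), fontsize=7)
    ax.set_yticks(range(N_RESIDUES), list(matrix.residues), fontsize=7)
    ax.set_xlabel("second residue")
    ax.set_ylabel("first residue")
    ax.set_title(f"signed normalized F-score, g={matrix.g}")
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
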