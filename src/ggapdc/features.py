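"""g-gap dipeptide composition features.

A g-gap dipeptide is an ordered residue pair at sequence positions
(i, i+g+1), i.e. separated by g intervening residues. A protein of length L
contains L - g - 1 such pairs, and its composition is the 400-dimensional
vector of pair frequencies over the 20x20 ordered pairs. With g = 0 this is
the classical adjoining dipeptide composition.

Feature index convention: feature eps = 20*i + j corresponds to the ordered
pair (ALPHABET[i], ALPHABET[j]) with the alphabet in alphabetical order, so
the vector enumerates AA, AC, AD, ..., YY row-major. This map is fixed so
feature ranks are comparable across runs and exports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, DataError, SequenceLengthError
from .seqio import ALPHABET, ProteinRecord

logger = logging.getLogger(__name__)

N_RESIDUES = 20
N_FEATURES = N_RESIDUES * N_RESIDUES  # 400 ordered pairs

#: Dipeptide names in feature-index order (AA, AC, ..., YY).
PAIR_NAMES: tuple[str, ...] = tuple(a + b for a in ALPHABET for b in ALPHABET)

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _a in enumerate(ALPHABET):
    _CODE[ord(_a)] = _i

#: g values above this trigger a warning (they are unusual, not invalid).
DEFAULT_MAX_G = 9

Denominator = Literal["positions", "length"]


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a validated sequence to integer residue codes 0..19."""
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sequence[int(np.argmax(codes < 0))]
        raise ValueError(f"unencodable character {bad!r}; validate the sequence first")
    return codes


def _check_g(g: int) -> int:
    g = int(g)
    if g < 0:
        raise ValueError(f"gap size g must be >= 0, got {g}")
    if g > DEFAULT_MAX_G:
        warnings.warn(
            f"g={g} is beyond the usual sweep range 0..{DEFAULT_MAX_G}",
            stacklevel=3,
        )
    return g


def ggap_dipeptide_counts(record: ProteinRecord | str, g: int) -> np.ndarray:
    """Count every g-gap dipeptide in the sequence.

    Returns a length-400 integer vector; entry for pair (a, b) is the number
    of positions i with residue a at i and residue b at i+g+1. The entries
    sum to L - g - 1.

    Raises :class:`~ggapdc.exceptions.SequenceLengthError` when L < g + 2.
    """
    g = _check_g(g)
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    rid = record.id if isinstance(record, ProteinRecord) else None
    L = len(seq)
    if L < g + 2:
        raise SequenceLengthError(
            f"sequence{' ' + repr(rid) if rid else ''} of length {L} is too short "
            f"for g={g} (needs L >= {g + 2})",
            record_id=rid, length=L, g=g,
        )
    codes = encode_sequence(seq)
    idx = codes[: L - g - 1] * N_RESIDUES + codes[g + 1 :]
    return np.bincount(idx, minlength=N_FEATURES)


def ggap_dipeptide_composition(
    record: ProteinRecord | str,
    g: int,
    denominator: Denominator = "positions",
) -> np.ndarray:
    """The 400-dimensional g-gap dipeptide frequency vector.

    ``denominator="positions"`` (default) divides counts by L - g - 1, the
    number of g-gap dipeptides present, so the vector sums to exactly 1.
    ``denominator="length"`` divides by the protein length L instead.
    """
    counts = ggap_dipeptide_counts(record, g)
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    L = len(seq)
    denom = (L - g - 1) if denominator == "positions" else L
    if denominator not in ("positions", "length"):
        raise ValueError(f"unknown denominator {denominator!r}")
    return counts / denom


@dataclass
class FeatureMatrix:
    """Samples x 400 g-gap dipeptide frequencies with class labels.

    ``y`` holds 1 for the positive class and 0 for the negative class; row
    order matches the input record order.
    """

    X: np.ndarray
    y: np.ndarray
    g: int
    ids: list[str] = field(default_factory=list)
    denominator: Denominator = "positions"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES:
            raise ContractError(
                f"feature matrix must be (n, {N_FEATURES}), got {self.X.shape}"
            )
        if self.X.shape[0] != self.y.shape[0]:
            raise DataError(
                f"{self.X.shape[0]} feature rows but {self.y.shape[0]} labels"
            )
        if not set(np.unique(self.y)) <= {0, 1}:
            raise DataError("labels must be 0 (negative) or 1 (positive)")
        if self.ids and len(self.ids) != self.X.shape[0]:
            raise DataError("ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def m_pos(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def m_neg(self) -> int:
        return int(np.sum(self.y == 0))

    @property
    def feature_names(self) -> tuple[str, ...]:
        return PAIR_NAMES


def build_feature_matrix(
    records: Sequence[ProteinRecord],
    labels: Sequence[int],
    g: int,
    denominator: Denominator = "positions",
) -> FeatureMatrix:
    """Assemble the composition vectors of a labelled dataset.

    Row order matches input order. All too-short records are reported
    together in a single error.
    """
    records = list(records)
    if not records:
        raise DataError("cannot build a feature matrix from zero records")
    if len(labels) != len(records):
        raise DataError(
            f"{len(records)} records but {len(labels)} labels"
        )
    g = _check_g(g)
    too_short = [r.id for r in records if r.length < g + 2]
    if too_short:
        raise SequenceLengthError(
            f"{len(too_short)} record(s) shorter than g+2={g + 2} for g={g}: "
            + ", ".join(too_short),
            g=g,
        )
    X = np.empty((len(records), N_FEATURES))
    for i, rec in enumerate(records):
        X[i] = ggap_dipeptide_composition(rec, g, denominator=denominator)
    return FeatureMatrix(
        X=X, y=np.asarray(labels, dtype=int), g=g,
        ids=[r.id for r in records], denominator=denominator,
    )


def feature_matrix_to_tsv(matrix: FeatureMatrix, path: str | Path) -> None:
    """Export as TSV: id column, 400 columns named like ``AA.g3``, label last."""
    cols = [f"{name}.g{matrix.g}" for name in PAIR_NAMES]
    df = pd.DataFrame(matrix.X, columns=cols)
    df.insert(0, "id", matrix.ids or [f"s{i}" for i in range(matrix.n_samples)])
    df["label"] = matrix.y
    df.to_csv(path, sep="\t", index=False)


def feature_matrix_from_tsv(path: str | Path) -> FeatureMatrix:
    """Read back a matrix written by :func:`feature_matrix_to_tsv`."""
    df = pd.read_csv(path, sep="\t")
    feat_cols = [c for c in df.columns if c not in ("id", "label")]
    if len(feat_cols) != N_FEATURES:
        raise DataError(
            f"{path}: expected {N_FEATURES} feature columns, found {len(feat_cols)}"
        )
    gs = {c.rsplit(".g", 1)[1] for c in feat_cols}
    if len(gs) != 1:
        raise DataError(f"{path}: mixed g values in feature columns: {sorted(gs)}")
    return FeatureMatrix(
        X=df[feat_cols].to_numpy(float),
        y=df["label"].to_numpy(int),
        g=int(gs.pop()),
        ids=df["id"].astype(str).tolist(),
    )
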