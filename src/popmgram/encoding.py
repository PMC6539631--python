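"""Tri-gram feature extraction from the protein overlapping property matrix.

For an ordered triple of property indices ``(x, y, z)`` the tri-gram
feature is the average, over all length-3 windows of the sequence, of the
product ``M[i, x] * M[i+1, y] * M[i+2, z]``:

    gram(x, y, z) = 1/(L-2) * sum_{i=1}^{L-2} M[i,x] M[i+1,y] M[i+2,z]

With ten overlapping property groups this yields a 1000-dimensional
feature vector per protein, capturing local physicochemical co-occurrence
without any alignment or database search.  Because every product term is
0 or 1 and there are ``L-2`` windows, each feature lies in ``[0, 1]``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .properties import (
    N_PROPERTIES,
    POPM,
    PropertyTable,
    build_popm,
    default_property_table,
)

N_FEATURES = N_PROPERTIES**3
MIN_LENGTH = 3


def flat_index(x: int, y: int, z: int) -> int:
    """Flat position of property triple ``(x, y, z)`` (1-based indices).

    Triples are ordered lexicographically:
    ``(1,1,1) -> 0`` ... ``(10,10,10) -> 999``.
    """
    for v in (x, y, z):
        if not 1 <= v <= N_PROPERTIES:
            raise ValueError(f"property index {v} outside [1, {N_PROPERTIES}]")
    return (x - 1) * 100 + (y - 1) * 10 + (z - 1)


def triple_from_flat(index: int) -> tuple[int, int, int]:
    """Inverse of :func:`flat_index`."""
    if not 0 <= index < N_FEATURES:
        raise ValueError(f"flat index {index} outside [0, {N_FEATURES})")
    x, rest = divmod(index, 100)
    y, z = divmod(rest, 10)
    return x + 1, y + 1, z + 1


def feature_name(
    x: int, y: int, z: int, table: PropertyTable | None = None
) -> str:
    """Human-readable column label, e.g. ``'g_Hydrophobic_Aliphatic_Small'``."""
    flat_index(x, y, z)  # range check
    names = (table or default_property_table()).group_names
    return f"g_{names[x - 1]}_{names[y - 1]}_{names[z - 1]}"


def feature_names(table: PropertyTable | None = None) -> list[str]:
    """All 1000 column labels in lexicographic triple order."""
    table = table or default_property_table()
    return [
        feature_name(*triple_from_flat(i), table=table)
        for i in range(N_FEATURES)
    ]


def trigram_features(popm: POPM) -> np.ndarray:
    """1000-dimensional tri-gram feature vector of one POPM.

    Requires ``L >= 3``; windows containing an all-zero row (non-standard
    residue) contribute nothing but still count in the ``L - 2``
    denominator.
    """
    L = popm.length
    if L < MIN_LENGTH:
        raise ValueError(
            f"sequence {popm.sequence_id!r} too short for tri-gram "
            f"(L={L} < {MIN_LENGTH})"
        )
    M = popm.matrix.astype(np.float64)
    grams = np.einsum("ix,iy,iz->xyz", M[:-2], M[1:-1], M[2:]) / (L - 2)
    return grams.reshape(N_FEATURES)


def encode_sequence(
    sequence: str, sequence_id: str = "", table: PropertyTable | None = None
) -> np.ndarray:
    """Convenience: sequence string straight to its tri-gram vector."""
    return trigram_features(build_popm(sequence, sequence_id, table=table))


def encode_dataset(
    sequences: Iterable[tuple[str, str]],
    table: PropertyTable | None = None,
) -> pd.DataFrame:
    """Encode ``(id, sequence)`` pairs into an ``n x 1000`` feature matrix.

    Rows follow input order (indexed by id); columns are the tri-gram
    labels in lexicographic triple order.  Any sequence shorter than 3
    residues raises ``ValueError`` naming the offending id.
    """
    table = table or default_property_table()
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for seq_id, seq in sequences:
        if len(seq) < MIN_LENGTH:
            raise ValueError(
                f"sequence {seq_id!r} too short for tri-gram "
                f"(L={len(seq)} < {MIN_LENGTH})"
            )
        ids.append(seq_id)
        rows.append(encode_sequence(seq, seq_id, table=table))
    return pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, N_FEATURES)),
        index=pd.Index(ids, name="sequence_id"),
        columns=feature_names(table),
    )


class PopmTrigramEncoder(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: residue strings -> tri-gram features.

    Parameters
    ----------
    table_path:
        Optional path to an alternative property-group table; ``None``
        uses the packaged Taylor grouping.
    standardize:
        If True, z-score each feature column on the fitted data.  Off by
        default — raw features already lie in ``[0, 1]``.

    The transformer accepts a 1-d array-like of sequence strings and
    returns an ``(n, 1000)`` float array.
    """

    def __init__(self, table_path: str | None = None, standardize: bool = False):
        self.table_path = table_path
        self.standardize = standardize

    def _table(self) -> PropertyTable:
        if self.table_path is None:
            return default_property_table()
        from .properties import build_property_table

        return build_property_table(self.table_path)

    def _encode(self, X: Sequence[str]) -> np.ndarray:
        table = self._table()
        return np.vstack(
            [encode_sequence(seq, f"seq{i}", table=table) for i, seq in enumerate(X)]
        ) if len(X) else np.empty((0, N_FEATURES))

    def fit(self, X: Sequence[str], y=None) -> "PopmTrigramEncoder":
        raw = self._encode(X)
        self.n_features_in_ = 1
        if self.standardize:
            self.scaler_ = StandardScaler().fit(raw)
        else:
            self.scaler_ = None
        self.feature_names_out_ = np.asarray(feature_names(self._table()))
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "feature_names_out_")
        raw = self._encode(X)
        if self.scaler_ is not None:
            return self.scaler_.transform(raw)
        return raw

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "feature_names_out_")
        return self.feature_names_out_

    def _more_tags(self):
        return {"X_types": ["string"]}
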