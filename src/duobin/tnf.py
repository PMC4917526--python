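"""Canonical tetranucleotide frequency (TNF) vectors and their PCA projection.

Every genome carries a characteristic bias in its 4-mer usage, so scaffolds
assembled from the same organism cluster together in TNF space. Because the
strand of an assembled scaffold is arbitrary, each 4-mer is identified with
its reverse complement, collapsing the 256 raw tetramers to 136 canonical
classes; the vector is exactly invariant under reverse complementation.

The PCA projection is column-centered only (frequencies already share a
scale) and component signs are fixed deterministically, so repeated runs on
the same data produce identical scores.
"""

from __future__ import annotations

import itertools
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Minimum number of valid 4-mer windows below which a scaffold's TNF vector
#: is considered low-confidence (short scaffolds have noisy signatures).
LOW_CONFIDENCE_WINDOWS = 50


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def _build_canonical_index() -> tuple[list[str], np.ndarray]:
    """136 canonical tetramers (lexicographic by canonical representative)
    and the length-256 map raw-index -> canonical column."""
    tetramers = ["".join(t) for t in itertools.product(_BASES, repeat=4)]
    canon = sorted({min(t, reverse_complement(t)) for t in tetramers})
    col = {t: i for i, t in enumerate(canon)}
    fold = np.array([col[min(t, reverse_complement(t))] for t in tetramers], dtype=np.int64)
    return canon, fold


CANONICAL_TETRAMERS, _FOLD = _build_canonical_index()

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def tnf_counts(seq: str) -> np.ndarray:
    """Raw canonical 4-mer window counts (length 136, not normalized)."""
    code = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if code.size < 4:
        return np.zeros(len(CANONICAL_TETRAMERS), dtype=np.int64)
    a, b, c, d = code[:-3], code[1:-2], code[2:-1], code[3:]
    valid = (a < 4) & (b < 4) & (c < 4) & (d < 4)
    idx = (a.astype(np.int64) * 64 + b * 16 + c * 4 + d)[valid]
    counts256 = np.bincount(idx, minlength=256)
    return np.bincount(_FOLD, weights=counts256, minlength=len(CANONICAL_TETRAMERS)).astype(np.int64)


def tnf_vector(seq: str) -> np.ndarray:
    """Normalized canonical TNF vector (sums to 1 over valid windows).

    Windows containing non-ACGT symbols are skipped. Raises ``ValueError``
    when the sequence has no valid window at all, in which case the caller
    should exclude the scaffold.
    """
    counts = tnf_counts(seq)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid 4-mer window in sequence")
    return counts / total


def tnf_matrix(seqs: Mapping[str, str]) -> tuple[pd.DataFrame, list[str]]:
    """TNF vectors for a scaffold set.

    Returns ``(matrix, excluded)`` where ``matrix`` has one row per scaffold
    with at least one valid window (columns = canonical tetramers) and
    ``excluded`` lists scaffolds with none. A boolean ``low_confidence``
    attribute column is not added; use ``n_valid_windows`` if needed.
    """
    rows, index, excluded = [], [], []
    for name, seq in seqs.items():
        counts = tnf_counts(seq)
        total = counts.sum()
        if total == 0:
            excluded.append(name)
            continue
        rows.append(counts / total)
        index.append(name)
    matrix = pd.DataFrame(rows, index=index, columns=CANONICAL_TETRAMERS)
    return matrix, excluded


class TNFPCA(TransformerMixin, BaseEstimator):
    """Deterministic PCA of TNF vectors.

    Column-centering only; no variance scaling. The sign of each component
    is fixed by making its largest-magnitude loading positive, so scores are
    reproducible across runs and row orderings.

    Parameters
    ----------
    n_components : int, default 3
        Number of principal components to retain.

    Attributes
    ----------
    components_ : ndarray of shape (n_components, 136)
    explained_variance_ratio_ : ndarray of shape (n_components,)
    mean_ : ndarray of shape (136,)
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = self._as_array(X)
        if X.shape[0] < self.n_components + 1:
            raise ValueError(
                f"need at least n_components+1={self.n_components + 1} scaffolds, "
                f"got {X.shape[0]}"
            )
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(X)
        components = pca.components_.copy()
        for i, comp in enumerate(components):
            if comp[np.argmax(np.abs(comp))] < 0:
                components[i] = -comp
        self.components_ = components
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.mean_ = pca.mean_
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        index = X.index if isinstance(X, pd.DataFrame) else None
        scores = (self._as_array(X) - self.mean_) @ self.components_.T
        if index is not None:
            return pd.DataFrame(
                scores, index=index,
                columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
            )
        return scores

    @staticmethod
    def _as_array(X) -> np.ndarray:
        arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
        return np.asarray(arr, dtype=float)


def project(matrix: pd.DataFrame, n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Fit-and-transform convenience wrapper around :class:`TNFPCA`.

    Returns ``(scores, explained_variance_ratio)``.
    """
    est = TNFPCA(n_components=n_components).fit(matrix)
    return est.transform(matrix), est.explained_variance_ratio_
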