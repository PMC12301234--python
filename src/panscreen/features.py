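"""Sequence descriptors, normalization and PCA for the KNN triage workflow.

The descriptor set is deliberately small and interpretable: the 20 amino-acid
frequencies, sequence length, mean Kyte-Doolittle hydropathy, approximate net
charge at pH 7, aromaticity, and (when annotation is available) CDR3 length —
25 columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Approximate side-chain charge at pH 7.
CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1}

AROMATIC = set("FWY")


def descriptor_names(with_cdr3: bool = True) -> list[str]:
    names = [f"freq_{aa}" for aa in AA_ORDER]
    names += ["length", "hydropathy", "net_charge", "aromaticity"]
    if with_cdr3:
        names.append("cdr3_length")
    return names


def featurize(
    sequences: list[str],
    cdr3_lengths: list[int] | None = None,
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Compute the descriptor matrix.

    Returns (matrix, errors); sequences containing residues outside the
    standard 20-letter alphabet are dropped from the matrix and listed in
    ``errors`` as (input index, sequence).
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    if cdr3_lengths is not None and len(cdr3_lengths) != len(sequences):
        raise ValueError("cdr3_lengths must align with sequences")
    rows, index, errors = [], [], []
    for i, seq in enumerate(sequences):
        if not seq or any(res not in KYTE_DOOLITTLE for res in seq):
            errors.append((i, seq))
            continue
        n = len(seq)
        row = [seq.count(aa) / n for aa in AA_ORDER]
        row.append(float(n))
        row.append(sum(KYTE_DOOLITTLE[res] for res in seq) / n)
        row.append(sum(CHARGE.get(res, 0.0) for res in seq))
        row.append(sum(res in AROMATIC for res in seq) / n)
        if cdr3_lengths is not None:
            row.append(float(cdr3_lengths[i]))
        rows.append(row)
        index.append(i)
    matrix = pd.DataFrame(rows, index=index,
                          columns=descriptor_names(cdr3_lengths is not None))
    return matrix, errors


@dataclass
class NormalizationStats:
    mean: pd.Series
    sd: pd.Series
    zero_variance: list[str]

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        sd = self.sd.replace(0.0, 1.0)
        z = (matrix[self.mean.index] - self.mean) / sd
        z[self.zero_variance] = 0.0
        return z


def normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationStats]:
    """Per-column z-score (population sd); constant columns map to 0."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to normalize")
    mean = matrix.mean()
    sd = matrix.std(ddof=0)
    zero_var = list(matrix.columns[sd == 0.0])
    stats = NormalizationStats(mean=mean, sd=sd, zero_variance=zero_var)
    return stats.apply(matrix), stats


class SignFixedPCA:
    """PCA with a deterministic sign convention.

    Components are flipped so that each component's largest-magnitude
    loading is positive, removing the arbitrary sign of the SVD.
    """

    def __init__(self, n_components: int):
        self.n_components = n_components
        self._pca = PCA(n_components=n_components, svd_solver="full")

    def fit(self, X: np.ndarray) -> "SignFixedPCA":
        X = np.asarray(X, dtype=float)
        rank = min(X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1])
        if not (1 <= self.n_components <= rank):
            raise ValueError(
                f"n_components={self.n_components} outside [1, rank={rank}]")
        self._pca.fit(X)
        comps = self._pca.components_
        flip = np.sign(comps[np.arange(len(comps)),
                             np.abs(comps).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self._pca.components_ = comps * flip[:, None]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._pca.transform(np.asarray(X, dtype=float))

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        return self._pca.explained_variance_ratio_

    @property
    def components_(self) -> np.ndarray:
        return self._pca.components_


def fit_pca(matrix, n_components: int) -> SignFixedPCA:
    """Fit PCA on a (normalized) descriptor matrix."""
    return SignFixedPCA(n_components).fit(np.asarray(matrix, dtype=float))
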