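"""Input encodings: one-hot sequence and sigmoid-normalized profile.

Both encodings are L x 20 matrices over the standard amino-acid alphabet in
alphabetical one-letter order.  The evolutionary profile compares the
column-wise amino-acid frequency in an MSA with the alignment-wide
frequency: m_ij = sigmoid(log(p_ij / p_i)), so 0.5 means "as frequent here
as anywhere", values above 0.5 mean over-representation at that column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import MSA

__all__ = [
    "AA_ORDER",
    "OneHotMatrix",
    "ProfileMatrix",
    "one_hot",
    "profile_from_msa",
    "stack_features",
]

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


@dataclass
class OneHotMatrix:
    values: np.ndarray  # (L, 20) of {0, 1}
    aa_order: tuple = AA_ORDER

    def __len__(self):
        return len(self.values)


@dataclass
class ProfileMatrix:
    values: np.ndarray  # (L, 20) in (0, 1)
    aa_order: tuple = AA_ORDER

    def __len__(self):
        return len(self.values)


def one_hot(sequence: str) -> OneHotMatrix:
    """Encode a sequence as an L x 20 binary matrix.

    Non-standard letters (X, B, Z, U, O, ...) yield all-zero rows: the
    alphabet is fixed at the 20 standard residues.
    """
    values = np.zeros((len(sequence), 20))
    for i, aa in enumerate(sequence):
        j = _AA_INDEX.get(aa)
        if j is not None:
            values[i, j] = 1.0
    return OneHotMatrix(values=values)


def profile_from_msa(msa: MSA) -> ProfileMatrix:
    """Sigmoid-normalized log-odds profile of an MSA.

    Counts c_ij (amino acid i in column j) exclude gaps and non-standard
    letters.  Pseudocounts are applied at the count level -- one extra
    count per (i, j) cell and L extra counts (L = number of columns) per
    amino acid alignment-wide -- with correspondingly augmented
    denominators:

        p_ij = (c_ij + 1) / (n_j + 20),    n_j = non-gap count in column j
        p_i  = (c_i  + L) / (N  + 20 L),   N   = total non-gap count

    and m_ij = sigmoid(log(p_ij / p_i)) = p_ij / (p_ij + p_i), which is
    strictly inside (0, 1) by construction.
    """
    L = len(msa.query)
    if L == 0:
        return ProfileMatrix(values=np.zeros((0, 20)))
    counts = np.zeros((L, 20))
    for row in msa.rows:
        for j, aa in enumerate(row):
            k = _AA_INDEX.get(aa)
            if k is not None:
                counts[j, k] += 1.0
    n_j = counts.sum(axis=1, keepdims=True)          # (L, 1)
    c_i = counts.sum(axis=0)                          # (20,)
    N = counts.sum()
    p_col = (counts + 1.0) / (n_j + 20.0)             # (L, 20)
    p_all = (c_i + L) / (N + 20.0 * L)                # (20,)
    values = p_col / (p_col + p_all[None, :])
    return ProfileMatrix(values=values)


def stack_features(onehot: OneHotMatrix, profile: ProfileMatrix) -> np.ndarray:
    """Horizontally stack the two encodings into an L x 40 matrix
    ([one-hot | profile]); tree models consume this raw stack."""
    a = np.asarray(onehot.values, dtype=float)
    b = np.asarray(profile.values, dtype=float)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: one-hot {len(a)} vs profile {len(b)}")
    return np.hstack([a.reshape(len(a), 20), b.reshape(len(b), 20)])
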