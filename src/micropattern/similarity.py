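"""Microbe-based disease similarity from signed association records.

Each disease i gets a vector d_i over the M microbes in the association
table. The weight for microbe j combines three ingredients:

* the changing direction E_ij (+1 increased, -1 decreased in disease i),
* the evidence count W_ij (number of association records for the pair),
* an inverse disease-frequency term log(N / n_j), where N is the number of
  diseases in the table and n_j the number of diseases with at least one
  record for microbe j — microbes reported in many diseases are weakly
  informative, exactly as common words are down-weighted in TF-IDF.

so w_ij = E_ij * W_ij * log(N / n_j). Records of opposite direction for the
same pair net out: the implementation uses the signed record sum, which
equals E_ij * W_ij whenever all records for a pair agree in direction.
Disease-disease similarity is the cosine of the two weight vectors, signed
and in [-1, 1].

The logarithm base is immaterial: changing it rescales every weight by the
same positive constant, which cancels in the cosine.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .setdb import AssociationTable

__all__ = [
    "SimilarityMatrix",
    "signed_count",
    "weight_matrix",
    "cosine_similarity",
    "run_similarity",
]


def signed_count(table: AssociationTable, disease: str, microbe: str) -> int:
    """Sum of direction values over all records for (disease, microbe).

    Equals E_ij * W_ij when all records for the pair agree in direction;
    mixed directions partially cancel; absent pair gives 0.
    """
    return sum(
        r.direction for r in table.records if r.disease == disease and r.microbe == microbe
    )


def weight_matrix(table: AssociationTable, log_base: float = math.e) -> pd.DataFrame:
    """Dense disease x microbe matrix of weights w_ij = signed_count * log(N / n_j).

    Rows are the table's diseases, columns its microbes, both sorted. N is
    the number of distinct diseases; n_j counts diseases with any record
    for microbe j, irrespective of direction, so a microbe reported in
    every disease carries zero weight everywhere.
    """
    if log_base <= 1.0:
        raise ValueError("log_base must be > 1")
    df = table.to_frame()
    signed = (
        df.pivot_table(index="disease", columns="microbe", values="direction", aggfunc="sum")
        .reindex(index=list(table.diseases), columns=list(table.microbes))
        .fillna(0.0)
    )
    present = (
        df.drop_duplicates(["disease", "microbe"]).groupby("microbe")["disease"].nunique()
    )
    n_j = present.reindex(list(table.microbes)).to_numpy(dtype=float)
    idf = np.log(table.n_diseases / n_j) / math.log(log_base)
    return signed * idf


def cosine_similarity(a, b) -> float:
    """Cosine of two disease vectors: dot(a, b) / (||a|| * ||b||).

    Accepts aligned pandas Series (index = microbes) or plain 1-d arrays.
    If either vector has zero norm the similarity is defined as 0.
    """
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        if not a.index.equals(b.index):
            raise ValueError("disease vectors are over different microbe universes")
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.ndim != 1:
        raise ValueError("disease vectors must be 1-d and of equal length")
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(av @ bv / (na * nb), -1.0, 1.0))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise cosine similarities between disease weight vectors."""

    diseases: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.diseases), len(self.diseases)):
            raise ValueError("similarity matrix shape does not match disease labels")
        object.__setattr__(self, "values", v)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.diseases.index(a), self.diseases.index(b)])

    def to_frame(self) -> pd.DataFrame:
        """Square matrix with disease labels on both axes."""
        return pd.DataFrame(self.values, index=list(self.diseases), columns=list(self.diseases))

    def to_long(self) -> pd.DataFrame:
        """Each unordered disease pair once: disease_a, disease_b, similarity.

        Pairs are sorted lexicographically with disease_a < disease_b.
        """
        rows = [
            (self.diseases[i], self.diseases[j], self.values[i, j])
            for i in range(len(self.diseases))
            for j in range(i + 1, len(self.diseases))
        ]
        return pd.DataFrame(rows, columns=["disease_a", "disease_b", "similarity"])


def run_similarity(table: AssociationTable, log_base: float = math.e) -> SimilarityMatrix:
    """All pairwise disease similarities over the table's weight vectors."""
    if table.n_diseases < 2:
        raise ValueError("similarity requires at least two distinct diseases")
    W = weight_matrix(table, log_base=log_base).to_numpy()
    norms = np.linalg.norm(W, axis=1)
    zero = norms == 0.0
    if zero.any():
        labels = [d for d, z in zip(table.diseases, zero) if z]
        warnings.warn(
            "zero-norm disease vector(s) (all weights vanish or cancel); "
            "their similarities are reported as 0: " + ", ".join(labels),
            stacklevel=2,
        )
    denom = np.outer(norms, norms)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0.0, W @ W.T / np.where(denom > 0.0, denom, 1.0), 0.0)
    sim = np.clip(sim, -1.0, 1.0)
    sim = (sim + sim.T) / 2.0  # enforce exact symmetry against rounding
    return SimilarityMatrix(diseases=table.diseases, values=sim)
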