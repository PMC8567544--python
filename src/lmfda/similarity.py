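"""Similarity networks: Gaussian interaction-profile kernel and Jaccard.

Two modalities are built per entity side.  Diseases get a GIP kernel over
their association profiles plus the precomputed semantic similarity that
arrives with the dataset; drugs get a GIP kernel over their (transposed)
profiles plus Jaccard similarity of their substructure fingerprints.

The GIP kernel between two entities with binary interaction profiles
y_x, y_y is exp(-gamma * ||y_x - y_y||^2), with the bandwidth normalised by
the mean squared profile norm: gamma = gamma_prime * n / sum_x ||y_x||^2.
This makes the kernel scale-free in the number of interaction partners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_datasets import LabeledMatrix, FingerprintSet

__all__ = [
    "GipParams",
    "SimilarityMatrix",
    "DegenerateBandwidthError",
    "gip_similarity",
    "jaccard_similarity",
    "disease_profiles",
    "drug_profiles",
]


class DegenerateBandwidthError(ValueError):
    """All interaction profiles are zero, so the GIP bandwidth is undefined."""


@dataclass
class GipParams:
    """Bandwidth pre-factor for the GIP kernel; must be positive."""

    gamma_prime: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma_prime > 0:
            raise ValueError("gamma_prime must be > 0")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity in [0, 1] for one entity set, one modality."""

    values: np.ndarray
    entity_ids: list[str]
    modality_name: str = ""

    TOL = 1e-10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity shape {self.values.shape} does not match "
                f"{n} entity ids"
            )
        if n and np.abs(self.values - self.values.T).max() > self.TOL:
            raise ValueError("similarity matrix is not symmetric")
        if self.values.size and (
            self.values.min() < -self.TOL or self.values.max() > 1 + self.TOL
        ):
            raise ValueError("similarity entries outside [0, 1]")


def disease_profiles(assoc: LabeledMatrix) -> np.ndarray:
    """Interaction profiles of diseases: the rows of the association matrix."""
    return np.asarray(assoc.values, dtype=np.float64)


def drug_profiles(assoc: LabeledMatrix) -> np.ndarray:
    """Interaction profiles of drugs: association columns, one per row."""
    return np.asarray(assoc.values, dtype=np.float64).T


def gip_similarity(
    profiles: np.ndarray,
    params: GipParams | None = None,
    entity_ids: list[str] | None = None,
    modality_name: str = "gip",
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary profile rows.

    Entry (x, y) is exp(-gamma ||y_x - y_y||^2) with
    gamma = gamma_prime / mean_x ||y_x||^2.  Raises
    :class:`DegenerateBandwidthError` when every profile is all-zero.
    """
    params = params or GipParams()
    P = np.asarray(profiles, dtype=np.float64)
    if P.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix")
    if not np.isin(P, (0.0, 1.0)).all():
        raise ValueError("profiles must be binary")
    n = P.shape[0]
    sq_norms = (P * P).sum(axis=1)
    mean_sq = sq_norms.mean() if n else 0.0
    if mean_sq == 0.0:
        raise DegenerateBandwidthError(
            "all interaction profiles are zero; GIP bandwidth undefined"
        )
    gamma = params.gamma_prime / mean_sq
    # binary profiles: squared distances are exact integers
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    ids = entity_ids if entity_ids is not None else [f"e{i}" for i in range(n)]
    return SimilarityMatrix(K, list(ids), modality_name)


def jaccard_similarity(fps: FingerprintSet, modality_name: str = "jaccard") -> SimilarityMatrix:
    """Jaccard (Tanimoto) similarity |P∩Q| / |P∪Q| of fingerprint bit sets.

    Convention for all-zero fingerprints (empty ∪ empty = 0/0): similarity 1
    on the diagonal, 0 against everything else, with a warning.
    """
    B = np.asarray(fps.bits, dtype=np.float64)
    if B.shape[0] == 0:
        raise ValueError("fingerprint set is empty")
    pop = B.sum(axis=1)
    inter = B @ B.T
    union = pop[:, None] + pop[None, :] - inter
    if (pop == 0).any():
        warnings.warn(
            f"{int((pop == 0).sum())} drug(s) have empty fingerprints; "
            "their Jaccard similarity is 0 off-diagonal by convention",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 1.0)
    return SimilarityMatrix(J, list(fps.drug_ids), modality_name)
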