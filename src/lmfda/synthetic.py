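"""Synthetic disease-drug bundles with a planted low-rank signal.

The generator emulates the structure of curated repositioning benchmarks
(a sparse binary disease x drug matrix, a drug substructure-fingerprint bit
table, and a disease-disease semantic similarity): latent factors U
(diseases) and V (drugs) are drawn i.i.d. standard normal, associations are
Bernoulli with probability sigmoid(u_i . v_j + c) where the intercept c is
calibrated by bisection to hit a target density, fingerprints are Bernoulli
bits driven by the drug factors, and semantic similarity is a Gaussian
kernel on the disease factors with optional symmetric noise.  Both
side-information sources therefore genuinely carry the latent signal the
model is supposed to exploit, and ``flip_noise`` corrupts the labels
independently of it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit
from scipy.spatial.distance import pdist, squareform

from .io_datasets import DatasetBundle, FingerprintSet, LabeledMatrix

__all__ = ["SynthConfig", "SynthTruth", "generate_bundle", "permute_labels"]


@dataclass
class SynthConfig:
    """Generator parameters; defaults are sized for minutes-scale CV runs."""

    n_diseases: int = 120
    n_drugs: int = 150
    latent_dim: int = 8
    target_density: float = 0.05
    fingerprint_bits: int = 256
    semantic_noise: float = 0.05
    flip_noise: float = 0.02
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.n_drugs < 1 or self.latent_dim < 1:
            raise ValueError("dimensions must be positive")
        if not 0.0 < self.target_density < 1.0:
            raise ValueError("target_density must be in (0, 1)")
        if not 0.0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must be in [0, 0.5)")
        if self.semantic_noise < 0:
            raise ValueError("semantic_noise must be non-negative")
        if self.fingerprint_bits < 1:
            raise ValueError("fingerprint_bits must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SynthTruth:
    """Ground truth behind a generated bundle, for recovery tests."""

    U: np.ndarray  # n_diseases x latent_dim
    V: np.ndarray  # n_drugs x latent_dim
    signal: np.ndarray  # U @ V.T
    intercept: float


def _calibrate_intercept(logits: np.ndarray, target: float, tol: float = 0.005) -> float:
    """Bisect c so that mean sigmoid(logits + c) matches the target density."""
    lo, hi = -50.0, 50.0
    if expit(logits + lo).mean() > target or expit(logits + hi).mean() < target:
        raise ValueError(
            "target density unreachable given the latent logit scale"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        d = expit(logits + mid).mean()
        if abs(d - target) <= tol * 0.1:
            return mid
        if d < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_bundle(cfg: SynthConfig | None = None) -> tuple[DatasetBundle, SynthTruth]:
    """Generate a validated bundle plus the latent truth that produced it."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    U = rng.normal(size=(cfg.n_diseases, cfg.latent_dim))
    V = rng.normal(size=(cfg.n_drugs, cfg.latent_dim))
    logits = U @ V.T
    c = _calibrate_intercept(logits, cfg.target_density)
    prob = expit(logits + c)
    O = (rng.random(prob.shape) < prob).astype(np.float64)
    if cfg.flip_noise > 0:
        flips = rng.random(O.shape) < cfg.flip_noise
        O = np.where(flips, 1.0 - O, O)

    beta = rng.normal(size=(cfg.latent_dim, cfg.fingerprint_bits))
    bit_prob = expit(V @ beta)
    bits = (rng.random(bit_prob.shape) < bit_prob).astype(np.float64)

    d = pdist(U, metric="euclidean")
    sigma = np.median(d) if d.size else 1.0
    S = np.exp(-squareform(d) ** 2 / (2.0 * sigma**2))
    if cfg.semantic_noise > 0:
        noise = rng.normal(0.0, cfg.semantic_noise, size=S.shape)
        S = S + 0.5 * (noise + noise.T)
    S = np.clip(0.5 * (S + S.T), 0.0, 1.0)
    np.fill_diagonal(S, 1.0)

    disease_ids = [f"D{i:04d}" for i in range(cfg.n_diseases)]
    drug_ids = [f"G{j:04d}" for j in range(cfg.n_drugs)]
    bundle = DatasetBundle(
        associations=LabeledMatrix(O, disease_ids, drug_ids),
        fingerprints=FingerprintSet(drug_ids, bits),
        disease_semantic_sim=LabeledMatrix(S, disease_ids, disease_ids),
        metadata={"generator": "synthetic", **cfg.to_dict()},
    )
    return bundle, SynthTruth(U, V, U @ V.T, c)


def permute_labels(bundle: DatasetBundle, seed: int) -> DatasetBundle:
    """Null model: shuffle association cells uniformly, keeping the count.

    Similarities and fingerprints are untouched, so any residual predictive
    performance reflects leakage rather than signal.
    """
    O = bundle.associations.values
    rng = np.random.default_rng(seed)
    flat = O.ravel().copy()
    rng.shuffle(flat)
    permuted = LabeledMatrix(
        flat.reshape(O.shape),
        bundle.associations.row_ids,
        bundle.associations.col_ids,
    )
    return DatasetBundle(
        associations=permuted,
        fingerprints=bundle.fingerprints,
        disease_semantic_sim=bundle.disease_semantic_sim,
        metadata={**bundle.metadata, "label_permutation_seed": seed},
    )
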