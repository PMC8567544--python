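"""Low-rank multimodal fusion of per-entity similarity views.

An entity (a disease or a drug) is described by M modality vectors
z_1 .. z_M — here, its rows in M similarity networks.  A multilinear fusion
layer would form the outer-product tensor Z = z_1 ⊗ .. ⊗ z_M and contract
it with an order-(M+1) weight tensor W plus a bias.  That tensor is never
materialised: W is decomposed as a sum of R rank-1 separable terms,
W = sum_i w_1^(i) ⊗ .. ⊗ w_M^(i), under which the fused output collapses to

    fused = sum_{i=1..R}  (z_1 · w_1^(i)) ∘ .. ∘ (z_M · w_M^(i))  + bias

an element-wise product of per-modality linear projections summed over the
rank.  With ``append_one`` a constant 1 is appended to each modality vector,
so lower-order (unimodal, bimodal, ...) interaction terms survive the
product instead of being annihilated.

``full_tensor_oracle`` materialises W and Z explicitly and performs the full
contraction; it exists purely as an independent correctness check at test
scale and refuses large inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "ModalityView",
    "FusionFactors",
    "FusedFeatures",
    "OracleSizeError",
    "lmf_transform",
    "full_tensor_oracle",
    "init_fusion_factors",
    "fuse_entity_side",
]


class OracleSizeError(ValueError):
    """The explicit tensor contraction was asked for beyond test scale."""


@dataclass
class ModalityView:
    """Per-modality feature matrices sharing one entity row order."""

    modalities: list[np.ndarray]
    entity_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.modalities = [np.asarray(m, dtype=np.float64) for m in self.modalities]
        if not self.modalities:
            raise ValueError("at least one modality is required")
        n = self.modalities[0].shape[0]
        for k, m in enumerate(self.modalities):
            if m.ndim != 2 or m.shape[0] != n:
                raise ValueError(
                    f"modality {k} has shape {m.shape}; expected {n} rows"
                )
        if self.entity_ids is None:
            self.entity_ids = [f"e{i}" for i in range(n)]
        elif len(self.entity_ids) != n:
            raise ValueError("entity id count does not match rows")

    @property
    def n_entities(self) -> int:
        return self.modalities[0].shape[0]

    @property
    def widths(self) -> list[int]:
        return [m.shape[1] for m in self.modalities]


@dataclass
class FusionFactors:
    """Rank-R factor stacks, one per modality, plus an output bias.

    ``factors[m]`` has shape (R, d_m + 1, out_dim) when ``append_one`` is
    on, (R, d_m, out_dim) otherwise.
    """

    factors: list[np.ndarray]
    bias: np.ndarray
    append_one: bool = True

    def __post_init__(self) -> None:
        self.factors = [np.asarray(f, dtype=np.float64) for f in self.factors]
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if not self.factors:
            raise ValueError("at least one modality factor stack is required")
        r, _, out = self.factors[0].shape
        for k, f in enumerate(self.factors):
            if f.ndim != 3 or f.shape[0] != r or f.shape[2] != out:
                raise ValueError(
                    f"factor stack {k} has shape {f.shape}; expected rank {r} "
                    f"and out_dim {out}"
                )
            if not np.isfinite(f).all():
                raise ValueError(f"factor stack {k} has non-finite entries")
        if self.bias.shape != (out,):
            raise ValueError(f"bias shape {self.bias.shape} != ({out},)")
        if not np.isfinite(self.bias).all():
            raise ValueError("bias has non-finite entries")

    @property
    def rank(self) -> int:
        return self.factors[0].shape[0]

    @property
    def out_dim(self) -> int:
        return self.factors[0].shape[2]

    @property
    def input_widths(self) -> list[int]:
        off = 1 if self.append_one else 0
        return [f.shape[1] - off for f in self.factors]


@dataclass
class FusedFeatures:
    """One fused feature row per entity."""

    values: np.ndarray
    entity_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("fused features contain non-finite entries")
        if not self.entity_ids:
            self.entity_ids = [f"e{i}" for i in range(self.values.shape[0])]


def _augmented(view: ModalityView, f: FusionFactors) -> list[np.ndarray]:
    if view.widths != f.input_widths:
        for k, (have, want) in enumerate(zip(view.widths, f.input_widths)):
            if have != want:
                raise ValueError(
                    f"modality {k}: input width {have} does not match factor "
                    f"width {want}"
                )
        raise ValueError(
            f"modality count mismatch: view has {len(view.modalities)}, "
            f"factors have {len(f.factors)}"
        )
    if not f.append_one:
        return list(view.modalities)
    n = view.n_entities
    ones = np.ones((n, 1))
    return [np.hstack([m, ones]) for m in view.modalities]


def lmf_transform(view: ModalityView, f: FusionFactors) -> FusedFeatures:
    """Fuse each entity's modality vectors via the factored weight tensor.

    Per entity: sum over rank of the element-wise product across modalities
    of the per-modality projections, plus the bias.
    """
    mats = _augmented(view, f)
    # (R, n, out) per modality, multiplied elementwise across modalities
    prod = None
    for Z, w in zip(mats, f.factors):
        proj = np.einsum("nd,rdo->rno", Z, w)
        prod = proj if prod is None else prod * proj
    fused = prod.sum(axis=0) + f.bias
    return FusedFeatures(fused, list(view.entity_ids))


def full_tensor_oracle(
    view: ModalityView, f: FusionFactors, max_elements: int = 200_000
) -> FusedFeatures:
    """Reference fusion by explicit tensor materialisation (test scale only).

    Reconstructs the full weight tensor W = sum_i w_1^(i) ⊗ .. ⊗ w_M^(i),
    forms each entity's outer-product tensor Z, and contracts W·Z + b.
    Refuses inputs whose tensors would exceed ``max_elements`` entries.
    """
    mats = _augmented(view, f)
    dims = [m.shape[1] for m in mats]
    w_size = int(np.prod(dims)) * f.out_dim
    if w_size > max_elements or int(np.prod(dims)) > max_elements:
        raise OracleSizeError(
            f"full tensor would hold {w_size} entries (cap {max_elements}); "
            "the oracle is test-scale only"
        )
    # W[d1, .., dM, out] = sum_i outer(w_1^(i)[:, o], .., w_M^(i)[:, o])
    W = np.zeros(dims + [f.out_dim])
    for i in range(f.rank):
        for o in range(f.out_dim):
            block = reduce(np.multiply.outer, [fk[i, :, o] for fk in f.factors])
            W[..., o] += block
    out = np.empty((view.n_entities, f.out_dim))
    flatW = W.reshape(-1, f.out_dim)
    for e in range(view.n_entities):
        Z = reduce(np.multiply.outer, [m[e] for m in mats])
        out[e] = Z.reshape(-1) @ flatW + f.bias
    return FusedFeatures(out, list(view.entity_ids))


def init_fusion_factors(
    dims: list[int],
    rank: int,
    out_dim: int,
    seed: int | np.random.SeedSequence,
    append_one: bool = True,
) -> FusionFactors:
    """Seeded Gaussian factors, zero bias, linear-dominant when append_one.

    Data coordinates get scale 1/sqrt(rank * d_m), keeping per-rank
    projections of O(1)-magnitude inputs at unit order so products across
    modalities neither vanish nor explode.  The appended-constant
    coordinate gets the larger scale 1/sqrt(rank): expanding the product
    across modalities, the cross terms (constant x data projection) are
    then the dominant contribution, so the initial fused features behave
    like random LINEAR projections of the concatenated modalities with
    multiplicative interactions in the tail — a far better-conditioned
    starting point than purely multiplicative features.
    """
    if rank < 1 or out_dim < 1 or any(d < 1 for d in dims):
        raise ValueError("dims, rank and out_dim must all be positive")
    rng = np.random.default_rng(seed)
    factors = []
    for d in dims:
        width = d + 1 if append_one else d
        f = rng.normal(0.0, 1.0 / np.sqrt(rank * d), size=(rank, width, out_dim))
        if append_one:
            f[:, -1, :] = rng.normal(0.0, 1.0 / np.sqrt(rank), size=(rank, out_dim))
        factors.append(f)
    return FusionFactors(factors, np.zeros(out_dim), append_one)


def fuse_entity_side(
    sim_matrices: list[SimilarityMatrix], f: FusionFactors
) -> FusedFeatures:
    """Fuse one entity side from its similarity networks.

    Modality m of entity e is row e of similarity matrix m; all matrices
    must list the same entities in the same order.
    """
    if not sim_matrices:
        raise ValueError("at least one similarity matrix is required")
    ids = sim_matrices[0].entity_ids
    for s in sim_matrices[1:]:
        if s.entity_ids != ids:
            raise ValueError(
                f"entity id order mismatch between modality "
                f"{sim_matrices[0].modality_name!r} and {s.modality_name!r}"
            )
    view = ModalityView([s.values for s in sim_matrices], list(ids))
    return lmf_transform(view, f)
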