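"""Bilinear low-rank scoring of disease-drug pairs, and its training.

Associations are approximated as O ≈ X P Yᵀ where X and Y are the fused
disease/drug feature matrices and P is a projection between the two fused
spaces.  P is never learned directly: it is factored P = W_imc · H_imcᵀ
with a small latent dimension f_p, a standard trace-norm surrogate for the
low-rank constraint.  The training objective is

    min_{W,H}  sum_{(i,j)} (O_ij − x_i W Hᵀ y_jᵀ)²  +  (λ/2)(‖W‖²_F + ‖H‖²_F)

summed over ALL cells, unobserved pairs counting as 0.

Two fitting routes are provided.  ``fit_als`` alternates exact closed-form
ridge solves for W and H on frozen features (each subproblem is a Sylvester
system diagonalised by eigendecomposition, so the objective is provably
non-increasing).  ``fit_joint`` additionally learns the fusion factors that
produce X and Y, by full-batch gradient descent on the same objective with
a guarded (revert-and-halve) step, optionally finished by ``fit_als`` on
the frozen fused features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import numpy as np

from .io_datasets import DatasetBundle, LabeledMatrix
from .similarity import (
    GipParams,
    SimilarityMatrix,
    gip_similarity,
    jaccard_similarity,
    disease_profiles,
    drug_profiles,
)
from .fusion import (
    FusionFactors,
    FusedFeatures,
    ModalityView,
    init_fusion_factors,
    fuse_entity_side,
)

__all__ = [
    "ImcModel",
    "ScoreMatrix",
    "FitReport",
    "TrainConfig",
    "NumericalFailure",
    "score_pair",
    "predict_all",
    "fit_als",
    "fit_joint",
    "build_modalities",
    "predict_bundle",
]


class NumericalFailure(RuntimeError):
    """The optimisation produced a non-finite objective."""


@dataclass
class ImcModel:
    """Factored bilinear projection P = W_imc · H_imcᵀ."""

    W_imc: np.ndarray  # f_d x f_p
    H_imc: np.ndarray  # f_g x f_p
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.W_imc = np.asarray(self.W_imc, dtype=np.float64)
        self.H_imc = np.asarray(self.H_imc, dtype=np.float64)
        if self.W_imc.ndim != 2 or self.H_imc.ndim != 2:
            raise ValueError("W_imc and H_imc must be matrices")
        if self.W_imc.shape[1] != self.H_imc.shape[1]:
            raise ValueError(
                f"latent dims differ: W_imc {self.W_imc.shape}, "
                f"H_imc {self.H_imc.shape}"
            )
        if self.W_imc.shape[1] < 1:
            raise ValueError("latent dimension f_p must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if not (np.isfinite(self.W_imc).all() and np.isfinite(self.H_imc).all()):
            raise ValueError("model factors contain non-finite entries")

    @property
    def f_p(self) -> int:
        return self.W_imc.shape[1]

    @property
    def projection(self) -> np.ndarray:
        """The full f_d x f_g projection matrix P."""
        return self.W_imc @ self.H_imc.T


@dataclass
class ScoreMatrix:
    """Dense association scores, diseases x drugs."""

    values: np.ndarray
    disease_ids: list[str]
    drug_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.disease_ids), len(self.drug_ids)):
            raise ValueError("score shape does not match id lists")
        if not np.isfinite(self.values).all():
            raise ValueError("scores contain non-finite entries")


@dataclass
class FitReport:
    objective_trace: list[float]
    iterations: int
    converged: bool
    seed: int | None = None
    notes: dict = field(default_factory=dict)


@dataclass
class TrainConfig:
    """Hyperparameters for joint training; defaults sized for desk-scale data.

    ``rank_disease``/``rank_drug`` are the fusion ranks R per entity side,
    ``out_dim_*`` the fused feature widths f_d/f_g, ``f_p`` the bilinear
    latent dimension, ``lam`` the ridge weight λ on W_imc/H_imc, and
    ``fusion_l2`` a ridge weight pulling the fusion factor stacks toward
    their seeded initialisation during training (without it, training the
    heavily overparameterised factors memorises the training cells and
    held-out performance collapses).  ``pos_weight`` >= 1 up-weights
    observed positive cells in the loss (gradient path only).
    """

    rank_disease: int = 16
    rank_drug: int = 16
    out_dim_disease: int = 128
    out_dim_drug: int = 128
    f_p: int = 16
    lam: float = 3.0
    fusion_l2: float = 300.0
    lr: float = 1e-3
    epochs: int = 25
    seed: int = 0
    als_refine: bool = True
    als_max_iter: int = 30
    als_tol: float = 1e-8
    pos_weight: float = 1.0
    gamma_prime: float = 1.0
    append_one: bool = True

    def __post_init__(self) -> None:
        if self.pos_weight < 1:
            raise ValueError("pos_weight must be >= 1")
        if self.epochs < 0 or self.lr <= 0:
            raise ValueError("epochs must be >= 0 and lr > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def score_pair(x_i: np.ndarray, model: ImcModel, y_j: np.ndarray) -> float:
    """Association strength x_i · (W_imc H_imcᵀ) · y_jᵀ for one pair."""
    x_i = np.asarray(x_i, dtype=np.float64).ravel()
    y_j = np.asarray(y_j, dtype=np.float64).ravel()
    if x_i.shape[0] != model.W_imc.shape[0]:
        raise ValueError(
            f"disease vector length {x_i.shape[0]} != f_d {model.W_imc.shape[0]}"
        )
    if y_j.shape[0] != model.H_imc.shape[0]:
        raise ValueError(
            f"drug vector length {y_j.shape[0]} != f_g {model.H_imc.shape[0]}"
        )
    return float((x_i @ model.W_imc) @ (model.H_imc.T @ y_j))


def predict_all(X: FusedFeatures, model: ImcModel, Y: FusedFeatures) -> ScoreMatrix:
    """Score every disease-drug pair: X · W_imc · H_imcᵀ · Yᵀ."""
    Xv, Yv = X.values, Y.values
    if Xv.shape[1] != model.W_imc.shape[0] or Yv.shape[1] != model.H_imc.shape[0]:
        raise ValueError(
            f"feature widths ({Xv.shape[1]}, {Yv.shape[1]}) do not match model "
            f"({model.W_imc.shape[0]}, {model.H_imc.shape[0]})"
        )
    S = (Xv @ model.W_imc) @ (Yv @ model.H_imc).T
    return ScoreMatrix(S, list(X.entity_ids), list(Y.entity_ids))


def _objective(
    O: np.ndarray,
    S: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
) -> float:
    R = O - S
    sq = R * R if weights is None else weights * R * R
    return float(sq.sum() + 0.5 * lam * ((W * W).sum() + (H * H).sum()))


def _sylvester_ridge(A: np.ndarray, C: np.ndarray, M: np.ndarray, half_lam: float) -> np.ndarray:
    """Solve A · Z · C + half_lam · Z = M for Z, A and C symmetric PSD."""
    a, U = np.linalg.eigh(A)
    c, V = np.linalg.eigh(C)
    denom = np.outer(a, c) + half_lam
    # jitter singular systems (lam = 0 and rank-deficient features)
    denom = np.where(np.abs(denom) < 1e-10, 1e-10, denom)
    return U @ ((U.T @ M @ V) / denom) @ V.T


def fit_als(
    X: FusedFeatures | np.ndarray,
    Y: FusedFeatures | np.ndarray,
    O: LabeledMatrix | np.ndarray,
    f_p: int = 32,
    lam: float = 0.1,
    max_iter: int = 50,
    tol: float = 1e-8,
    seed: int = 0,
    H_init: np.ndarray | None = None,
) -> tuple[ImcModel, FitReport]:
    """Alternating exact ridge solves for W_imc and H_imc on frozen features.

    Each half-step minimises the full objective exactly in one factor, so
    the recorded objective sequence is non-increasing.  Stops when the
    relative decrease falls below ``tol`` or after ``max_iter`` sweeps.
    """
    Xv = X.values if isinstance(X, FusedFeatures) else np.asarray(X, dtype=np.float64)
    Yv = Y.values if isinstance(Y, FusedFeatures) else np.asarray(Y, dtype=np.float64)
    Ov = O.values if isinstance(O, LabeledMatrix) else np.asarray(O, dtype=np.float64)
    if Ov.shape != (Xv.shape[0], Yv.shape[0]):
        raise ValueError(
            f"association shape {Ov.shape} does not match features "
            f"({Xv.shape[0]}, {Yv.shape[0]})"
        )
    if f_p < 1:
        raise ValueError("f_p must be >= 1")

    rng = np.random.default_rng(seed)
    H = (
        np.asarray(H_init, dtype=np.float64).copy()
        if H_init is not None
        else rng.normal(0.0, 1.0 / np.sqrt(f_p), size=(Yv.shape[1], f_p))
    )
    W = np.zeros((Xv.shape[1], f_p))

    XtX = Xv.T @ Xv
    YtY = Yv.T @ Yv
    half_lam = 0.5 * lam

    trace: list[float] = []
    converged = False
    for it in range(max_iter):
        # W-step: XtX · W · (BᵀB) + (λ/2) W = Xᵀ O B,  B = Y H
        B = Yv @ H
        W = _sylvester_ridge(XtX, B.T @ B, Xv.T @ Ov @ B, half_lam)
        # H-step: YtY · H · (DᵀD) + (λ/2) H = Yᵀ Oᵀ D,  D = X W
        D = Xv @ W
        H = _sylvester_ridge(YtY, D.T @ D, Yv.T @ Ov.T @ D, half_lam)
        obj = _objective(Ov, (Xv @ W) @ (Yv @ H).T, W, H, lam)
        if not np.isfinite(obj):
            raise NumericalFailure(f"non-finite ALS objective at iteration {it}")
        trace.append(obj)
        if it > 0:
            prev = trace[-2]
            if prev - obj <= tol * max(abs(prev), 1.0):
                converged = True
                break
    model = ImcModel(W, H, lam)
    return model, FitReport(trace, len(trace), converged, seed)


def build_modalities(
    bundle: DatasetBundle,
    assoc: LabeledMatrix | None = None,
    gamma_prime: float = 1.0,
) -> tuple[list[SimilarityMatrix], list[SimilarityMatrix]]:
    """Build the per-side modality lists from a bundle.

    Diseases: [GIP over association rows, precomputed semantic similarity].
    Drugs:    [GIP over association columns, fingerprint Jaccard].
    ``assoc`` overrides the bundle's association matrix — cross-validation
    passes the training-masked copy so the GIP kernels never see held-out
    labels.
    """
    A = assoc if assoc is not None else bundle.associations
    if bundle.fingerprints.drug_ids != A.col_ids:
        raise ValueError(
            "fingerprint drug order does not match association columns; "
            "load_bundle aligns them when the id sets are equal"
        )
    gp = GipParams(gamma_prime)
    dis_gip = gip_similarity(
        disease_profiles(A), gp, A.row_ids, modality_name="disease-gip"
    )
    drug_gip = gip_similarity(
        drug_profiles(A), gp, A.col_ids, modality_name="drug-gip"
    )
    semantic = SimilarityMatrix(
        bundle.disease_semantic_sim.values, A.row_ids, "disease-semantic"
    )
    jac = jaccard_similarity(bundle.fingerprints, modality_name="drug-jaccard")
    return [dis_gip, semantic], [drug_gip, jac]


def _lmf_forward(mats: list[np.ndarray], f: FusionFactors) -> tuple[np.ndarray, list[np.ndarray]]:
    """Fused output and the per-modality projection stacks (R, n, out)."""
    # (1, n, d) @ (R, d, out) -> (R, n, out), batched over the rank
    projs = [np.matmul(Z[None, :, :], w) for Z, w in zip(mats, f.factors)]
    prod = projs[0].copy()
    for p in projs[1:]:
        prod *= p
    return prod.sum(axis=0) + f.bias, projs


def _augment(mats: list[np.ndarray], append_one: bool) -> list[np.ndarray]:
    if not append_one:
        return mats
    n = mats[0].shape[0]
    ones = np.ones((n, 1))
    return [np.hstack([m, ones]) for m in mats]


def _lmf_backward(
    G: np.ndarray, mats: list[np.ndarray], projs: list[np.ndarray]
) -> tuple[list[np.ndarray], np.ndarray]:
    """Gradients of the factor stacks and bias given d(loss)/d(fused)."""
    M = len(mats)
    grads = []
    for m in range(M):
        others = None
        for k in range(M):
            if k == m:
                continue
            others = projs[k] if others is None else others * projs[k]
        gA = G[None, :, :] if others is None else G[None, :, :] * others
        grads.append(np.matmul(mats[m].T[None, :, :], gA))
    return grads, G.sum(axis=0)


def fit_joint(
    bundle: DatasetBundle,
    config: TrainConfig | None = None,
    assoc: LabeledMatrix | None = None,
) -> tuple[FusionFactors, FusionFactors, ImcModel, FitReport]:
    """Jointly train fusion factors and the bilinear completion model.

    Builds the similarity modalities, initialises everything from
    ``config.seed``, then minimises the ridge objective by guarded
    full-batch gradient descent on the fusion factors and biases.  With the
    default uniform cell weighting, W_imc/H_imc are kept at their exact
    conditional ridge optimum (one alternating sweep per accepted step —
    block-coordinate / variable-projection style), which couples the
    fusion gradient to the completion model far more effectively than
    simultaneous gradient steps; with ``pos_weight`` > 1 the closed-form
    sweeps are unavailable and W_imc/H_imc take plain gradient steps too.
    Optionally finishes with :func:`fit_als` on the frozen fused features.

    The recorded loss trace is non-increasing by construction: a step that
    would raise the loss is reverted and the learning rate halved (it
    regrows by 1.2x after each accepted step).

    ``assoc`` optionally overrides the bundle's association matrix (used by
    cross-validation to train on a masked copy).
    """
    cfg = config or TrainConfig()
    A = assoc if assoc is not None else bundle.associations
    O = np.asarray(A.values, dtype=np.float64)
    dis_sims, drug_sims = build_modalities(bundle, A, cfg.gamma_prime)

    root = np.random.SeedSequence(cfg.seed)
    ss_d, ss_g, ss_wh = root.spawn(3)
    fd = init_fusion_factors(
        [s.values.shape[1] for s in dis_sims],
        cfg.rank_disease,
        cfg.out_dim_disease,
        ss_d,
        cfg.append_one,
    )
    fg = init_fusion_factors(
        [s.values.shape[1] for s in drug_sims],
        cfg.rank_drug,
        cfg.out_dim_drug,
        ss_g,
        cfg.append_one,
    )
    rng = np.random.default_rng(ss_wh)
    W = rng.normal(0.0, 1.0 / np.sqrt(cfg.f_p), size=(cfg.out_dim_disease, cfg.f_p))
    H = rng.normal(0.0, 1.0 / np.sqrt(cfg.f_p), size=(cfg.out_dim_drug, cfg.f_p))

    mats_d = _augment([s.values for s in dis_sims], cfg.append_one)
    mats_g = _augment([s.values for s in drug_sims], cfg.append_one)
    weights = (
        None
        if cfg.pos_weight == 1.0
        else 1.0 + (cfg.pos_weight - 1.0) * O
    )

    exact_wh = weights is None
    half_lam = 0.5 * cfg.lam

    # ridge-to-initialisation on the fusion factors: the seeded init is a
    # well-conditioned random-features map, and unconstrained training of
    # the (heavily overparameterised) factor stacks memorises the training
    # cells; penalising the departure from init interpolates between frozen
    # random features (fusion_l2 -> inf) and free training (fusion_l2 = 0)
    init_ref = [f.copy() for f in fd.factors + fg.factors]

    def freg(fd_, fg_):
        return 0.5 * cfg.fusion_l2 * sum(
            float(((f - f0) ** 2).sum())
            for f, f0 in zip(fd_.factors + fg_.factors, init_ref)
        )

    def wh_sweeps(Xf_, Yf_, W_, H_, sweeps):
        XtX, YtY = Xf_.T @ Xf_, Yf_.T @ Yf_
        for _ in range(sweeps):
            B = Yf_ @ H_
            W_ = _sylvester_ridge(XtX, B.T @ B, Xf_.T @ O @ B, half_lam)
            D = Xf_ @ W_
            H_ = _sylvester_ridge(YtY, D.T @ D, Yf_.T @ O.T @ D, half_lam)
        return W_, H_

    def forward(fd_, fg_, W_, H_):
        Xf, projs_d = _lmf_forward(mats_d, fd_)
        Yf, projs_g = _lmf_forward(mats_g, fg_)
        S = (Xf @ W_) @ (Yf @ H_).T
        return Xf, Yf, S, projs_d, projs_g

    Xf, projs_d = _lmf_forward(mats_d, fd)
    Yf, projs_g = _lmf_forward(mats_g, fg)
    if exact_wh:
        W, H = wh_sweeps(Xf, Yf, W, H, sweeps=5)  # warm start at the
        # conditional optimum of the initial fused features
    S = (Xf @ W) @ (Yf @ H).T
    loss = _objective(O, S, W, H, cfg.lam, weights) + freg(fd, fg)
    if not np.isfinite(loss):
        raise NumericalFailure(
            "initial objective is non-finite; try a smaller learning rate "
            "or smaller initial scales"
        )
    trace = [loss]
    lr = cfg.lr
    for epoch in range(cfg.epochs):
        Rm = S - O
        G_S = 2.0 * (Rm if weights is None else weights * Rm)
        YH = Yf @ H
        XW = Xf @ W
        gW = Xf.T @ G_S @ YH + cfg.lam * W
        gH = Yf.T @ G_S.T @ XW + cfg.lam * H
        G_X = G_S @ YH @ W.T
        G_Y = G_S.T @ XW @ H.T
        gfd, gbd = _lmf_backward(G_X, mats_d, projs_d)
        gfg, gbg = _lmf_backward(G_Y, mats_g, projs_g)
        if cfg.fusion_l2:
            nd = len(fd.factors)
            gfd = [
                g + cfg.fusion_l2 * (f - f0)
                for g, f, f0 in zip(gfd, fd.factors, init_ref[:nd])
            ]
            gfg = [
                g + cfg.fusion_l2 * (f - f0)
                for g, f, f0 in zip(gfg, fg.factors, init_ref[nd:])
            ]

        def stepped(lr_):
            fd_ = FusionFactors(
                [f - lr_ * g for f, g in zip(fd.factors, gfd)],
                fd.bias - lr_ * gbd,
                fd.append_one,
            )
            fg_ = FusionFactors(
                [f - lr_ * g for f, g in zip(fg.factors, gfg)],
                fg.bias - lr_ * gbg,
                fg.append_one,
            )
            return fd_, fg_, W - lr_ * gW, H - lr_ * gH

        accepted = False
        while lr >= 1e-15:
            try:
                fd_n, fg_n, W_n, H_n = stepped(lr)
                Xf_n, pd_n = _lmf_forward(mats_d, fd_n)
                Yf_n, pg_n = _lmf_forward(mats_g, fg_n)
                if exact_wh:
                    W_n, H_n = wh_sweeps(Xf_n, Yf_n, W, H, sweeps=1)
                S_n = (Xf_n @ W_n) @ (Yf_n @ H_n).T
                new_loss = _objective(O, S_n, W_n, H_n, cfg.lam, weights) + freg(
                    fd_n, fg_n
                )
            except (ValueError, FloatingPointError, np.linalg.LinAlgError):
                new_loss = np.inf
            if np.isfinite(new_loss) and new_loss <= loss:
                fd, fg, W, H = fd_n, fg_n, W_n, H_n
                Xf, Yf, S, projs_d, projs_g = Xf_n, Yf_n, S_n, pd_n, pg_n
                loss = new_loss
                accepted = True
                lr *= 1.2  # cautiously regrow the step after a success
                break
            lr *= 0.5
        trace.append(loss)
        if not accepted:
            break  # no descent direction at machine precision

    notes = {"stage": "gd", "final_lr": lr}
    model = ImcModel(W, H, cfg.lam)
    if cfg.als_refine:
        model, als_rep = fit_als(
            FusedFeatures(Xf, A.row_ids),
            FusedFeatures(Yf, A.col_ids),
            O,
            f_p=cfg.f_p,
            lam=cfg.lam,
            max_iter=cfg.als_max_iter,
            tol=cfg.als_tol,
            seed=cfg.seed,
            H_init=H,
        )
        pen = freg(fd, fg)  # factors frozen: constant offset keeps the
        trace.extend(v + pen for v in als_rep.objective_trace)  # trace comparable
        notes["als_iterations"] = als_rep.iterations
        notes["als_converged"] = als_rep.converged
    report = FitReport(trace, len(trace) - 1, True, cfg.seed, notes)
    return fd, fg, model, report


def predict_bundle(
    bundle: DatasetBundle,
    fd: FusionFactors,
    fg: FusionFactors,
    model: ImcModel,
    assoc: LabeledMatrix | None = None,
    gamma_prime: float = 1.0,
) -> ScoreMatrix:
    """Score every pair of a bundle with trained fusion factors and model."""
    A = assoc if assoc is not None else bundle.associations
    dis_sims, drug_sims = build_modalities(bundle, A, gamma_prime)
    X = fuse_entity_side(dis_sims, fd)
    Y = fuse_entity_side(drug_sims, fg)
    return predict_all(X, model, Y)
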