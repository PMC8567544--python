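import numpy as np
import pytest

from lmfda.fusion import (
    FusedFeatures,
    FusionFactors,
    ModalityView,
    OracleSizeError,
    full_tensor_oracle,
    fuse_entity_side,
    init_fusion_factors,
    lmf_transform,
)
from lmfda.similarity import SimilarityMatrix


def _random_instance(rng, M=None, append_one=None):
    M = M if M is not None else int(rng.integers(1, 4))
    append_one = bool(rng.integers(0, 2)) if append_one is None else append_one
    dims = [int(rng.integers(1, 5)) for _ in range(M)]
    rank = int(rng.integers(1, 4))
    out_dim = int(rng.integers(1, 4))
    n = int(rng.integers(1, 6))
    view = ModalityView([rng.normal(size=(n, d)) for d in dims])
    factors = [
        rng.normal(size=(rank, d + (1 if append_one else 0), out_dim)) for d in dims
    ]
    f = FusionFactors(factors, rng.normal(size=out_dim), append_one)
    return view, f


class TestLmfTransform:
    def test_hand_computed_selector(self):
        # w1 picks z1[0], w2 picks z2[1]: fused = 3 * 6 = 18
        view = ModalityView([np.array([[3.0, 4.0]]), np.array([[5.0, 6.0]])])
        f = FusionFactors(
            [np.array([[[1.0], [0.0]]]), np.array([[[0.0], [1.0]]])],
            np.zeros(1),
            append_one=False,
        )
        out = lmf_transform(view, f)
        assert out.values[0, 0] == pytest.approx(18.0)

    def test_zero_modality_annihilates(self, rng):
        view = ModalityView([rng.normal(size=(3, 4)), np.zeros((3, 2))])
        f = FusionFactors(
            [rng.normal(size=(2, 4, 3)), rng.normal(size=(2, 2, 3))],
            rng.normal(size=3),
            append_one=False,
        )
        out = lmf_transform(view, f)
        np.testing.assert_allclose(out.values, np.tile(f.bias, (3, 1)))

    def test_width_mismatch_names_modality(self, rng):
        view = ModalityView([rng.normal(size=(2, 3)), rng.normal(size=(2, 5))])
        f = FusionFactors(
            [rng.normal(size=(1, 3, 2)), rng.normal(size=(1, 4, 2))],
            np.zeros(2),
            append_one=False,
        )
        with pytest.raises(ValueError, match="modality 1"):
            lmf_transform(view, f)

    def test_linear_in_single_modality(self, rng):
        """With append_one off, output is linear in each modality alone."""
        view, f = _random_instance(rng, M=2, append_one=False)
        z2 = view.modalities[1]
        a, bcoef = 2.5, -1.25
        va = ModalityView([a * view.modalities[0], z2])
        vb = ModalityView([bcoef * view.modalities[0], z2])
        vab = ModalityView([(a + bcoef) * view.modalities[0], z2])
        lhs = lmf_transform(vab, f).values - f.bias
        rhs = (lmf_transform(va, f).values - f.bias) + (
            lmf_transform(vb, f).values - f.bias
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestOracleEquivalence:
    def test_matches_oracle_randomized(self):
        """Factored fusion equals the explicit tensor contraction (200 draws)."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            view, f = _random_instance(rng)
            fast = lmf_transform(view, f).values
            slow = full_tensor_oracle(view, f).values
            np.testing.assert_allclose(fast, slow, atol=1e-8)

    def test_all_ones_closed_form(self):
        # rank 1, M = 2, all-ones factors/inputs, no bias: every output
        # coordinate equals d1 * d2 (sum over the all-ones outer product)
        d1, d2 = 3, 4
        view = ModalityView([np.ones((2, d1)), np.ones((2, d2))])
        f = FusionFactors(
            [np.ones((1, d1, 2)), np.ones((1, d2, 2))], np.zeros(2), append_one=False
        )
        out = full_tensor_oracle(view, f)
        np.testing.assert_allclose(out.values, d1 * d2)

    def test_bias_only(self, rng):
        view = ModalityView([rng.normal(size=(3, 2))])
        bias = rng.normal(size=4)
        f = FusionFactors([np.zeros((2, 2, 4))], bias, append_one=False)
        np.testing.assert_allclose(
            full_tensor_oracle(view, f).values, np.tile(bias, (3, 1))
        )

    def test_size_cap_refusal(self, rng):
        view = ModalityView([rng.normal(size=(1, 100)), rng.normal(size=(1, 100))])
        f = FusionFactors(
            [rng.normal(size=(1, 101, 30)), rng.normal(size=(1, 101, 30))],
            np.zeros(30),
        )
        with pytest.raises(OracleSizeError):
            full_tensor_oracle(view, f)


class TestInitFactors:
    def test_determinism_and_seed_sensitivity(self):
        a = init_fusion_factors([5, 7], rank=3, out_dim=4, seed=42)
        b = init_fusion_factors([5, 7], rank=3, out_dim=4, seed=42)
        c = init_fusion_factors([5, 7], rank=3, out_dim=4, seed=43)
        for fa, fb in zip(a.factors, b.factors):
            np.testing.assert_array_equal(fa, fb)
        assert any(
            not np.array_equal(fa, fc) for fa, fc in zip(a.factors, c.factors)
        )

    def test_shapes_and_invariants(self):
        f = init_fusion_factors([5, 7], rank=3, out_dim=4, seed=0)
        assert f.rank == 3 and f.out_dim == 4
        assert [s.shape for s in f.factors] == [(3, 6, 4), (3, 8, 4)]
        assert f.input_widths == [5, 7]

    def test_rejects_bad_dims(self):
        with pytest.raises(ValueError):
            init_fusion_factors([0], rank=1, out_dim=1, seed=0)


class TestFuseEntitySide:
    def _sims(self, rng, n=5):
        ids = [f"e{i}" for i in range(n)]
        mats = []
        for name in ("m1", "m2"):
            A = rng.random((n, n))
            S = np.clip(0.5 * (A + A.T), 0, 1)
            np.fill_diagonal(S, 1.0)
            mats.append(SimilarityMatrix(S, ids, name))
        return mats

    def test_matches_oracle(self, rng):
        sims = self._sims(rng)
        f = init_fusion_factors([5, 5], rank=2, out_dim=3, seed=1)
        fused = fuse_entity_side(sims, f)
        view = ModalityView([s.values for s in sims], sims[0].entity_ids)
        np.testing.assert_allclose(
            fused.values, full_tensor_oracle(view, f).values, atol=1e-8
        )

    def test_row_permutation_equivariance(self, rng):
        sims = self._sims(rng, n=6)
        f = init_fusion_factors([6, 6], rank=2, out_dim=4, seed=2)
        base = fuse_entity_side(sims, f).values
        perm = rng.permutation(6)
        permuted = [
            SimilarityMatrix(
                s.values[np.ix_(perm, perm)],
                [s.entity_ids[p] for p in perm],
                s.modality_name,
            )
            for s in sims
        ]
        # permuting entities permutes the modality *columns* too, so refit
        # factors are not comparable; equivariance holds for row order only
        rows_only = [
            ModalityView([s.values[perm] for s in sims]),
        ][0]
        out = lmf_transform(rows_only, f).values
        np.testing.assert_allclose(out, base[perm], atol=1e-12)

    def test_id_order_mismatch_raises(self, rng):
        sims = self._sims(rng)
        bad = SimilarityMatrix(
            sims[1].values, list(reversed(sims[1].entity_ids)), "m2"
        )
        f = init_fusion_factors([5, 5], rank=1, out_dim=2, seed=0)
        with pytest.raises(ValueError, match="id order"):
            fuse_entity_side([sims[0], bad], f)

    def test_single_modality_is_linear_map(self, rng):
        sims = self._sims(rng)[:1]
        f = init_fusion_factors([5], rank=3, out_dim=2, seed=3, append_one=False)
        fused = fuse_entity_side(sims, f).values
        # rank-R stack of linear maps sums to one linear map
        Wsum = f.factors[0].sum(axis=0)
        np.testing.assert_allclose(fused, sims[0].values @ Wsum + f.bias, atol=1e-10)
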