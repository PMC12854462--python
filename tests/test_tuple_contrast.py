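"""Pseudo-labels, tuple-disturbed negatives and the InfoNCE loss."""

import numpy as np
import pytest

from stcontrast.autodiff import Tensor
from stcontrast.tuple_contrast import (
    AlphaMixture,
    ContrastBatch,
    TupleSample,
    assign_pseudo_labels,
    draw_negative,
    info_nce,
    info_nce_fused,
    sample_negative_indices,
)


def _tuples(n, d, rng, K=2):
    labels = np.arange(n) % K
    return [
        TupleSample(rng.standard_normal(d), rng.standard_normal(d), int(labels[i]), i)
        for i in range(n)
    ]


class TestPseudoLabels:
    def test_two_blobs_perfectly_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        a = rng.standard_normal((40, 5)) + 10
        b = rng.standard_normal((40, 5)) - 10
        h = np.vstack([a, b])
        truth = np.array([0] * 40 + [1] * 40)
        labels = assign_pseudo_labels(h, 2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_allowed(self):
        rng = np.random.default_rng(1)
        h = rng.standard_normal((5, 3))
        labels = assign_pseudo_labels(h, 5, seed=0)
        assert len(np.unique(labels)) <= 5

    def test_fixed_seed_deterministic(self):
        rng = np.random.default_rng(2)
        h = rng.standard_normal((30, 4))
        assert np.array_equal(
            assign_pseudo_labels(h, 3, seed=9), assign_pseudo_labels(h, 3, seed=9)
        )

    def test_identical_embeddings_single_cluster(self):
        labels = assign_pseudo_labels(np.ones((10, 3)), 2, seed=0)
        assert len(np.unique(labels)) == 1


class TestDrawNegative:
    def test_full_disturb_certainty(self, rng):
        pool = _tuples(6, 3, rng)
        neg = draw_negative(pool[0], pool, AlphaMixture([1.0, 0, 0]), rng)
        src = pool[neg.spot_index]
        assert np.array_equal(neg.v1, src.v1) and np.array_equal(neg.v2, src.v2)
        assert src.pseudo_label != pool[0].pseudo_label

    def test_image_view_swap_only(self, rng):
        pool = _tuples(6, 3, rng)
        anchor = pool[0]
        neg = draw_negative(anchor, pool, AlphaMixture([0, 0, 1.0]), rng)
        assert np.array_equal(neg.v1, anchor.v1)
        assert np.array_equal(neg.v2, pool[neg.spot_index].v2)

    def test_frequencies_match_mixture_within_3_sigma(self, rng):
        pool = _tuples(8, 2, rng)
        mix = AlphaMixture.uniform()
        n = 10_000
        counts = np.zeros(3)
        anchor = pool[0]
        for _ in range(n):
            neg = draw_negative(anchor, pool, mix, rng)
            if np.array_equal(neg.v1, anchor.v1):
                counts[2] += 1
            elif np.array_equal(neg.v2, anchor.v2):
                counts[1] += 1
            else:
                counts[0] += 1
        sigma = np.sqrt(n * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - n / 3) < 3 * sigma)

    def test_single_modality_negative_differs_in_exactly_one_view(self, rng):
        pool = _tuples(10, 4, rng)
        for _ in range(500):
            anchor = pool[int(rng.integers(10))]
            kind = int(rng.integers(1, 3))
            mix = AlphaMixture([0, 1.0, 0] if kind == 1 else [0, 0, 1.0])
            neg = draw_negative(anchor, pool, mix, rng)
            same_v1 = np.array_equal(neg.v1, anchor.v1)
            same_v2 = np.array_equal(neg.v2, anchor.v2)
            assert same_v1 != same_v2  # exactly one view untouched

    def test_mismatched_label_constraint(self, rng):
        pool = _tuples(9, 2, rng, K=3)
        for _ in range(200):
            anchor = pool[0]
            neg = draw_negative(anchor, pool, AlphaMixture([1.0, 0, 0]), rng)
            assert pool[neg.spot_index].pseudo_label != anchor.pseudo_label

    def test_fallback_when_all_labels_equal(self, rng, caplog):
        pool = [
            TupleSample(np.zeros(2), np.zeros(2), 0, i) for i in range(4)
        ]
        neg = draw_negative(pool[0], pool, AlphaMixture([1, 0, 0]), rng)
        assert neg.spot_index != 0

    def test_vectorized_sampler_respects_label_constraint(self, rng):
        labels = np.array([0, 0, 1, 1, 2, 2])
        src, kinds = sample_negative_indices(labels, 8, AlphaMixture.uniform(), rng)
        for i in range(6):
            assert np.all(labels[src[i]] != labels[i])
        assert set(np.unique(kinds)) <= {0, 1, 2}


class TestAlphaMixture:
    def test_simplex_enforced(self):
        with pytest.raises(ValueError):
            AlphaMixture([0.5, 0.5, 0.5])

    def test_uniform_valid(self):
        m = AlphaMixture.uniform()
        assert m.alpha.sum() == pytest.approx(1.0)


class TestInfoNCE:
    def test_tied_scores_give_ln2(self):
        pos = Tensor(np.array([[1.0]]))
        neg = Tensor(np.array([[1.0]]))
        from stcontrast.tuple_contrast import info_nce_scores

        loss = info_nce_scores(pos, neg, tau=0.5)
        assert float(loss.data) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_dominant_positive_drives_loss_to_zero(self):
        from stcontrast.tuple_contrast import info_nce_scores

        loss = info_nce_scores(Tensor(np.array([[50.0]])), Tensor(np.array([[0.0]])), 1.0)
        assert float(loss.data) < 1e-12

    def test_matches_scalar_loop_oracle(self, rng):
        d, B, n_neg, tau = 3, 4, 2, 0.5
        Wf = Tensor(rng.standard_normal((2 * d, d)))
        anchors = _tuples(B, d, rng)
        positives = [
            TupleSample(t.v1 + 0.1, t.v2 - 0.1, t.pseudo_label, t.spot_index)
            for t in anchors
        ]
        negatives = [
            [draw_negative(a, anchors, AlphaMixture.uniform(), rng) for _ in range(n_neg)]
            for a in anchors
        ]
        batch = ContrastBatch(anchors, positives, negatives, tau=tau)
        loss = float(info_nce(batch, Wf).data)

        def fused(t):
            return np.concatenate([t.v1, t.v2]) @ Wf.data

        total = 0.0
        for a, p, negs in zip(anchors, positives, negatives):
            sp_ = fused(a) @ fused(p)
            for ng in negs:
                sn = fused(a) @ fused(ng)
                total += -np.log(
                    np.exp(sp_ / tau) / (np.exp(sp_ / tau) + np.exp(sn / tau))
                )
        assert loss == pytest.approx(total / (B * n_neg), rel=1e-10)

    def test_shift_invariance_of_scores(self, rng):
        from stcontrast.tuple_contrast import info_nce_scores

        pos = rng.standard_normal((5, 1))
        neg = rng.standard_normal((5, 1))
        a = float(info_nce_scores(Tensor(pos), Tensor(neg), 0.7).data)
        b = float(info_nce_scores(Tensor(pos + 11.3), Tensor(neg + 11.3), 0.7).data)
        assert a == pytest.approx(b, rel=1e-12)

    def test_monotone_decreasing_in_positive_score(self):
        from stcontrast.tuple_contrast import info_nce_scores

        neg = Tensor(np.array([[0.3]]))
        losses = [
            float(info_nce_scores(Tensor(np.array([[s]])), neg, 0.5).data)
            for s in np.linspace(-2, 2, 9)
        ]
        assert np.all(np.diff(losses) < 0)

    def test_fused_path_matches_tuple_path(self, rng):
        d, B, n_neg = 3, 4, 3
        Wf = Tensor(rng.standard_normal((2 * d, d)))
        anchors = _tuples(B, d, rng)
        positives = [
            TupleSample(t.v1 * 1.1, t.v2, t.pseudo_label, t.spot_index) for t in anchors
        ]
        negatives = [
            [draw_negative(a, anchors, AlphaMixture.uniform(), rng) for _ in range(n_neg)]
            for a in anchors
        ]
        batch = ContrastBatch(anchors, positives, negatives, tau=0.4)
        via_tuples = float(info_nce(batch, Wf).data)

        def stack(samples):
            return Tensor(np.stack([np.concatenate([s.v1, s.v2]) for s in samples])) @ Wf

        a_f = stack(anchors)
        p_f = stack(positives)
        n_f = stack([s for negs in negatives for s in negs])
        idx = np.repeat(np.arange(B), n_neg)
        via_fused = float(info_nce_fused(a_f, p_f, n_f, idx, 0.4).data)
        assert via_tuples == pytest.approx(via_fused, rel=1e-12)
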