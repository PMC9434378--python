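import numpy as np
import pytest

from limbtrack.detection import (BoneNetConfig, TrainConfig, VotingConfig,
                                 bonenet_loss, build_bonenet, count_parameters,
                                 encode_vector_field, vote_landmark)
from limbtrack.detection.bonenet import BASELINE_DEPTHS, BONENET_DEPTHS
from limbtrack.detection.train import train_bonenet


def random_case(rng, shape=(64, 64)):
    mask = np.zeros(shape, bool)
    r0, c0 = rng.integers(12, shape[0] - 12, 2)
    h, w = rng.integers(8, 14, 2)
    mask[r0 - h // 2:r0 + h // 2, c0 - w // 2:c0 + w // 2] = True
    lm = np.array([r0, c0]) + rng.uniform(-3, 3, 2)
    return mask, lm


def corrupt(field, mask, frac, rng):
    f = field.copy()
    rr, cc = np.nonzero(mask)
    idx = rng.choice(len(rr), int(frac * len(rr)), replace=False)
    ang = rng.uniform(0, 2 * np.pi, len(idx))
    f[0, rr[idx], cc[idx]] = np.cos(ang)
    f[1, rr[idx], cc[idx]] = np.sin(ang)
    return f


class TestEncodeVectorField:
    def test_unit_norm_on_mask(self):
        rng = np.random.default_rng(0)
        mask, lm = random_case(rng)
        tgt = encode_vector_field(mask, lm)
        norms = np.linalg.norm(tgt.field[:, mask], axis=0)
        assert np.all((np.abs(norms - 1.0) < 1e-12) | (norms == 0.0))
        assert np.all(tgt.field[:, ~mask] == 0.0)

    def test_collinearity_landmark_on_every_ray(self):
        rng = np.random.default_rng(1)
        mask, lm = random_case(rng)
        tgt = encode_vector_field(mask, lm)
        rr, cc = np.nonzero(mask)
        p = np.stack([rr, cc], 1).astype(float)
        v = tgt.field[:, rr, cc].T
        d = lm[None] - p
        cross = d[:, 0] * v[:, 1] - d[:, 1] * v[:, 0]
        t = np.einsum("nd,nd->n", d, v)
        assert np.abs(cross).max() <= 1e-12
        assert np.all(t >= 0)

    def test_single_pixel_mask_at_landmark_gives_zero_field(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 4] = True
        tgt = encode_vector_field(mask, np.array([3.0, 4.0]))
        assert np.all(tgt.field == 0.0)

    def test_nonfinite_landmark_rejected(self):
        with pytest.raises(ValueError):
            encode_vector_field(np.ones((4, 4), bool), np.array([np.nan, 1.0]))


class TestVoting:
    def test_exact_field_recovers_landmark(self):
        rng = np.random.default_rng(2)
        for t in range(10):
            mask, lm = random_case(rng)
            obs = vote_landmark(encode_vector_field(mask, lm),
                                config=VotingConfig(seed=t))
            assert np.linalg.norm(obs.mu_hat - lm) <= 0.5
            assert obs.sigma <= 0.5
            assert obs.omega == pytest.approx(1.0 / (obs.sigma + 1e-6))

    def test_robust_to_20_percent_corruption(self):
        rng = np.random.default_rng(3)
        for t in range(10):
            mask, lm = random_case(rng)
            f = corrupt(encode_vector_field(mask, lm).field, mask, 0.2, rng)
            obs = vote_landmark(f, mask, VotingConfig(seed=t))
            assert np.linalg.norm(obs.mu_hat - lm) <= 1.0

    def test_single_pixel_mask_is_degenerate(self):
        mask = np.zeros((8, 8), bool)
        mask[2, 2] = True
        field = np.zeros((2, 8, 8))
        field[0, 2, 2] = 1.0
        with pytest.raises(ValueError):
            vote_landmark(field, mask, VotingConfig(seed=0))

    def test_parallel_field_is_degenerate(self):
        mask = np.ones((4, 4), bool)
        field = np.zeros((2, 4, 4))
        field[0] = 1.0   # every vector identical
        with pytest.raises(ValueError):
            vote_landmark(field, mask, VotingConfig(seed=0))

    def test_encode_vote_round_trip_50_cases(self):
        rng = np.random.default_rng(4)
        for t in range(50):
            mask, lm = random_case(rng)
            obs = vote_landmark(encode_vector_field(mask, lm),
                                config=VotingConfig(seed=t))
            assert np.linalg.norm(obs.mu_hat - lm) <= 0.5

    def test_graceful_degradation_with_corruption(self):
        rng = np.random.default_rng(5)
        med = {}
        for frac in (0.0, 0.1, 0.2, 0.4):
            errs = []
            for t in range(20):
                mask, lm = random_case(rng)
                f = encode_vector_field(mask, lm).field
                if frac:
                    f = corrupt(f, mask, frac, np.random.default_rng(100 + t))
                obs = vote_landmark(f, mask, VotingConfig(seed=t))
                errs.append(np.linalg.norm(obs.mu_hat - lm))
            med[frac] = np.median(errs)
        fracs = sorted(med)
        assert all(med[a] <= med[b] + 1e-6 for a, b in zip(fracs, fracs[1:]))


class TestBoneNet:
    def test_output_shapes(self):
        net = build_bonenet(BoneNetConfig(input_size=64, K=5, seed=0))
        x = np.zeros((2, 1, 64, 64))
        fields, seg = net.forward(x, train=False)
        assert fields.shape == (2, 10, 64, 64)
        assert seg.shape == (2, 2, 64, 64)

    def test_five_basic_blocks_added_over_baseline(self):
        assert tuple(np.subtract(BONENET_DEPTHS, BASELINE_DEPTHS)) == (1, 1, 2, 1)
        assert sum(BONENET_DEPTHS) - sum(BASELINE_DEPTHS) == 5

    def test_deeper_encoder_has_more_parameters(self):
        deep = build_bonenet(BoneNetConfig(input_size=64, K=4))
        base = build_bonenet(BoneNetConfig(input_size=64, K=4,
                                           depths=BASELINE_DEPTHS))
        assert count_parameters(deep) > count_parameters(base)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            BoneNetConfig(input_size=60, K=4)
        net = build_bonenet(BoneNetConfig(input_size=64, K=2))
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 60, 60)))


class TestLoss:
    def _case(self):
        rng = np.random.default_rng(6)
        mask = np.zeros((1, 8, 8))
        mask[0, 2:6, 2:6] = 1.0
        tf = rng.normal(size=(1, 4, 8, 8)) * mask[:, None]
        return mask, tf

    def test_perfect_prediction_minimizes_both_terms(self):
        mask, tf = self._case()
        seg = np.stack([np.where(mask[0] > 0, -20.0, 20.0),
                        np.where(mask[0] > 0, 20.0, -20.0)])[None]
        total, fl, ce = bonenet_loss(tf, seg, tf, mask)
        assert fl == 0.0
        assert ce == pytest.approx(0.0, abs=1e-8)

    def test_huber_closed_form_single_pixel(self):
        mask = np.zeros((1, 4, 4))
        mask[0, 1, 1] = 1.0
        tf = np.zeros((1, 2, 4, 4))
        pf = tf.copy()
        pf[0, 0, 1, 1] = 0.5       # residual (0.5, 0) on one masked pixel
        seg = np.zeros((1, 2, 4, 4))
        _, fl, _ = bonenet_loss(pf, seg, tf, mask)
        # smooth-L1 of 0.5 is 0.125; averaged over 2 field channels
        assert fl == pytest.approx(0.125 / 2)

    def test_prediction_outside_mask_does_not_matter(self):
        mask, tf = self._case()
        seg = np.zeros((1, 2, 8, 8))
        base, _, _ = bonenet_loss(tf, seg, tf, mask)
        perturbed = tf + (1.0 - mask[:, None]) * 17.0
        other, _, _ = bonenet_loss(perturbed, seg, tf, mask)
        assert other == pytest.approx(base)

    def test_printed_sign_variant_subtracts_cross_entropy(self):
        mask, tf = self._case()
        seg = np.zeros((1, 2, 8, 8))
        plus, fl, ce = bonenet_loss(tf, seg, tf, mask, ce_sign=+1.0)
        minus, _, _ = bonenet_loss(tf, seg, tf, mask, ce_sign=-1.0)
        assert plus == pytest.approx(fl + ce)
        assert minus == pytest.approx(fl - ce)


class TestTraining:
    @staticmethod
    def _toy_data(n, rng, size=32, K=2):
        xs, fs, ms = [], [], []
        for _ in range(n):
            mask = np.zeros((size, size), bool)
            r0, c0 = rng.integers(10, size - 10, 2)
            mask[r0 - 6:r0 + 6, c0 - 5:c0 + 5] = True
            img = mask.astype(float) * 0.8 + rng.normal(0, 0.05, (size, size))
            lms = np.stack([rng.uniform(r0 - 6, r0 + 6, K),
                            rng.uniform(c0 - 5, c0 + 5, K)], 1)
            fs.append(np.concatenate(
                [encode_vector_field(mask, lm).field for lm in lms], 0))
            xs.append(img[None])
            ms.append(mask.astype(float))
        return np.stack(xs), np.stack(fs), np.stack(ms)

    def test_same_seed_identical_histories(self):
        rng = np.random.default_rng(7)
        xs, fs, ms = self._toy_data(6, rng)
        kw = dict(net_config=BoneNetConfig(input_size=32, K=2, seed=1,
                                           widths=(4, 8, 12, 16), decoder_width=8),
                  train_config=TrainConfig(max_epochs=3, seed=1))
        _, h1 = train_bonenet(xs, fs, ms, **kw)
        _, h2 = train_bonenet(xs, fs, ms, **kw)
        assert h1["train"] == h2["train"]
        assert h1["val"] == h2["val"]

    def test_loss_decreases_on_toy_set(self):
        rng = np.random.default_rng(8)
        xs, fs, ms = self._toy_data(8, rng)
        _, hist = train_bonenet(
            xs, fs, ms,
            net_config=BoneNetConfig(input_size=32, K=2, seed=0,
                                     widths=(4, 8, 12, 16), decoder_width=8),
            train_config=TrainConfig(base_lr=1e-3, decay_epochs=0,
                                     max_epochs=8, seed=0))
        assert hist["train"][-1] < hist["train"][0]

    def test_divergence_aborts_with_diagnostics(self):
        rng = np.random.default_rng(9)
        xs, fs, ms = self._toy_data(2, rng)
        xs[0, 0, 0, 0] = np.nan     # poisoned input -> non-finite loss
        with pytest.raises(RuntimeError, match="diverged"):
            train_bonenet(
                xs, fs, ms,
                net_config=BoneNetConfig(input_size=32, K=2, seed=0,
                                         widths=(4, 8, 12, 16), decoder_width=8),
                train_config=TrainConfig(max_epochs=5, seed=0))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        from limbtrack.detection import (build_bonenet, save_checkpoint,
                                         load_checkpoint)
        net = build_bonenet(BoneNetConfig(input_size=32, K=2, seed=3,
                                          widths=(4, 8, 12, 16),
                                          decoder_width=8))
        x = np.random.default_rng(0).normal(size=(1, 1, 32, 32))
        a = net.forward(x, train=False)
        path = tmp_path / "net.npz"
        save_checkpoint(net, path)
        net2 = load_checkpoint(path)
        b = net2.forward(x, train=False)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
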