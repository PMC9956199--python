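"""CCRBM core: conditionals vs exact enumeration, centering, CD training."""

import numpy as np
import pytest

from hecare import ccrbm


TOY = ccrbm.CCRBMStructure(visible_length=4, n_filters=1, filter_width=2, pool_block=3)


def toy_params(seed=42, scale=0.8):
    rng = np.random.default_rng(seed)
    params = ccrbm.CCRBMParameters.initial(TOY, rng, scale=scale)
    params.hidden_bias = rng.normal(0, 0.5, TOY.n_filters)
    params.visible_bias = float(rng.normal(0, 0.5))
    return ccrbm.initialize_offsets(params, TOY)


def exact_hidden_posterior(v, params, centered=True):
    """P(h | v) and P(block off | v) by brute-force enumeration."""
    vs, hs, probs = ccrbm.enumerate_joint(params, TOY, centered)
    mask = np.all(vs == v, axis=1)
    pv, hv = probs[mask], hs[mask]
    pv = pv / pv.sum()
    unit = (hv * pv[:, None, None]).sum(axis=0)
    off = pv[hv.sum(axis=(1, 2)) == 0].sum()
    return unit, off


class TestStructure:
    def test_detection_length_and_blocks(self):
        s = ccrbm.CCRBMStructure(visible_length=5, n_filters=2, filter_width=3,
                                 pool_block=3)
        assert s.detection_length == 3
        assert s.blocks == ((0, 1, 2),)
        assert s.feature_dim == 2

    def test_partial_final_block(self):
        s = ccrbm.CCRBMStructure(visible_length=5, n_filters=2, filter_width=2,
                                 pool_block=3)
        assert s.detection_length == 4
        assert s.blocks == ((0, 1, 2), (3,))

    def test_filter_wider_than_input_rejected(self):
        with pytest.raises(ccrbm.CCRBMError):
            ccrbm.CCRBMStructure(visible_length=3, filter_width=5)

    def test_flat_parameter_count(self):
        s = ccrbm.CCRBMStructure(visible_length=5, n_filters=2, filter_width=3)
        assert s.n_flat_params == 2 * 3 + 2 + 1


class TestBottomUpSignal:
    def test_zero_filters_give_bias(self):
        params = toy_params()
        params.filters = np.zeros_like(params.filters)
        params.hidden_bias = np.array([0.5])
        s = ccrbm.bottom_up_signal(np.array([1.0, 0, 0, 0]), params, TOY,
                                   centered=False)
        assert np.allclose(s, 0.5)

    def test_hand_convolution(self):
        params = toy_params()
        params.filters = np.array([[2.0, 3.0]])
        params.hidden_bias = np.array([0.0])
        s = ccrbm.bottom_up_signal(np.array([1.0, 0, 0, 0]), params, TOY,
                                   centered=False)
        assert np.allclose(s, [[2.0, 0.0, 0.0]])

    def test_centering_annihilates_matching_input(self):
        params = toy_params()
        v = np.full(4, 0.3)
        params.alpha_v = v.copy()
        s = ccrbm.bottom_up_signal(v, params, TOY, centered=True)
        assert np.allclose(s, params.hidden_bias[:, None])


class TestEnergy:
    def test_zero_state_zero_energy(self):
        params = toy_params()
        v = np.zeros(4)
        h = np.zeros((1, 3))
        params.visible_bias = 0.0
        assert ccrbm.energy(v, h, params, TOY, centered=False) == 0.0

    def test_centered_reduces_to_plain_at_zero_offsets(self):
        params = toy_params().zero_offsets()
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = (rng.random(4) < 0.5).astype(float)
            h = np.zeros((1, 3))
            k = rng.integers(4)
            if k < 3:
                h[0, k] = 1.0
            e_c = ccrbm.energy(v, h, params, TOY, centered=True)
            e_p = ccrbm.energy(v, h, params, TOY, centered=False)
            assert e_c == e_p

    def test_block_constraint_enforced(self):
        params = toy_params()
        h = np.array([[1.0, 1.0, 0.0]])
        with pytest.raises(ccrbm.BlockConstraintError):
            ccrbm.energy(np.zeros(4), h, params, TOY)

    def test_energy_matches_term_by_term_oracle(self):
        """Exhaustive check on all 2^4 x 4 valid toy states."""
        import itertools

        params = toy_params(seed=5)
        for vbits in itertools.product((0.0, 1.0), repeat=4):
            v = np.array(vbits)
            for active in (-1, 0, 1, 2):
                h = np.zeros((1, 3))
                if active >= 0:
                    h[0, active] = 1.0
                # independent term-by-term summation
                vc = v - params.alpha_v
                hc = h - params.alpha_h
                expected = 0.0
                for k in range(3):
                    conv = sum(
                        params.filters[0, i] * vc[k + i] for i in range(2)
                    )
                    expected -= hc[0, k] * (conv + params.hidden_bias[0])
                expected -= params.visible_bias * vc.sum()
                got = ccrbm.energy(v, h, params, TOY, centered=True)
                assert got == pytest.approx(expected, abs=1e-12)


class TestConditionals:
    def test_uniform_block_softmax(self):
        params = toy_params()
        params.filters = np.zeros_like(params.filters)
        params.hidden_bias = np.zeros(1)
        params = params.zero_offsets()
        p, p_off = ccrbm.hidden_conditional(np.zeros(4), params, TOY)
        assert np.allclose(p, 0.25)
        assert np.allclose(p_off, 0.25)

    def test_saturated_unit_wins_block(self):
        params = toy_params().zero_offsets()
        params.filters = np.array([[50.0, 0.0]])
        params.hidden_bias = np.zeros(1)
        p, p_off = ccrbm.hidden_conditional(np.array([1.0, 0, 0, 0]), params, TOY)
        assert p[0, 0] > 1 - 1e-10
        assert (p[0, 1:] < 1e-10).all()
        assert p_off[0, 0] < 1e-10

    def test_block_normalization_property(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            params = toy_params(seed=rng.integers(2**31))
            v = rng.random(4)
            p, p_off = ccrbm.hidden_conditional(v, params, TOY)
            assert abs(p.sum() + p_off.sum() - 1.0) < 1e-10

    def test_hidden_conditional_matches_enumeration(self):
        params = toy_params(seed=42)
        for vbits in [(0, 0, 0, 0), (1, 0, 1, 0), (1, 1, 1, 1), (0, 1, 0, 1)]:
            v = np.array(vbits, dtype=float)
            p, p_off = ccrbm.hidden_conditional(v, params, TOY)
            unit, off = exact_hidden_posterior(v, params)
            assert np.max(np.abs(p - unit)) < 1e-10
            assert abs(p_off[0, 0] - off) < 1e-10

    def test_visible_conditional_matches_enumeration(self):
        params = toy_params(seed=42)
        vs, hs, probs = ccrbm.enumerate_joint(params, TOY)
        for idx in range(0, len(hs), 17):
            h = hs[idx]
            mask = np.all(hs.reshape(len(hs), -1) == h.ravel(), axis=1)
            pv, vv = probs[mask], vs[mask]
            pv = pv / pv.sum()
            exact = (vv * pv[:, None]).sum(axis=0)
            got = ccrbm.visible_conditional(h, params, TOY)
            assert np.max(np.abs(got - exact)) < 1e-10

    def test_visible_at_offset_equals_half(self):
        params = toy_params()
        params.visible_bias = 0.0
        p = ccrbm.visible_conditional(params.alpha_h.copy(), params, TOY)
        assert np.allclose(p, 0.5)

    def test_visible_saturates_with_large_negative_bias(self):
        params = toy_params().zero_offsets()
        params.visible_bias = -50.0
        p = ccrbm.visible_conditional(np.zeros((1, 3)), params, TOY)
        assert np.all(p < 1e-10)

    def test_centered_conditionals_reduce_to_plain(self):
        params = toy_params().zero_offsets()
        v = np.array([1.0, 0.0, 1.0, 1.0])
        pc, poc = ccrbm.hidden_conditional(v, params, TOY, centered=True)
        pp, pop = ccrbm.hidden_conditional(v, params, TOY, centered=False)
        assert np.array_equal(pc, pp) and np.array_equal(poc, pop)


class TestSampling:
    def test_uniform_block_frequencies(self):
        params = toy_params()
        params.filters = np.zeros_like(params.filters)
        params.hidden_bias = np.zeros(1)
        params = params.zero_offsets()
        rng = np.random.default_rng(0)
        counts = np.zeros(4)  # three units + off
        n = 20_000
        for _ in range(n):
            state = ccrbm.sample_hidden(np.zeros(4), params, TOY, rng)
            active = np.flatnonzero(state.hidden[0])
            counts[active[0] if len(active) else 3] += 1
        assert np.allclose(counts / n, 0.25, atol=0.02)

    def test_block_constraint_always_satisfied(self):
        params = toy_params(seed=3)
        rng = np.random.default_rng(1)
        for _ in range(200):
            state = ccrbm.sample_hidden(rng.random(4), params, TOY, rng)
            state.validate(TOY)

    def test_fixed_seed_reproducible_chain(self):
        params = toy_params(seed=3)

        def chain(seed):
            rng = np.random.default_rng(seed)
            v = np.zeros(4)
            out = []
            for _ in range(10):
                state = ccrbm.sample_hidden(v, params, TOY, rng)
                v = ccrbm.sample_visible(state.hidden, params, TOY, rng)
                out.append(v.copy())
            return np.stack(out)

        assert np.array_equal(chain(7), chain(7))


class TestEnumeration:
    def test_probabilities_sum_to_one(self):
        _, _, probs = ccrbm.enumerate_joint(toy_params(), TOY)
        assert abs(probs.sum() - 1.0) < 1e-12

    def test_uniform_at_zero_parameters(self):
        params = toy_params()
        params.filters = np.zeros_like(params.filters)
        params.hidden_bias = np.zeros(1)
        params.visible_bias = 0.0
        params = params.zero_offsets()
        _, _, probs = ccrbm.enumerate_joint(params, TOY)
        assert np.allclose(probs, probs[0])

    def test_state_space_guard(self):
        big = ccrbm.CCRBMStructure(visible_length=5, n_filters=6, filter_width=2,
                                   pool_block=2)
        params = ccrbm.CCRBMParameters.initial(big)
        with pytest.raises(ccrbm.CCRBMError, match="state space"):
            ccrbm.enumerate_joint(params, big, max_states=100)


class TestOffsets:
    def test_full_replacement_at_rate_one(self):
        params = toy_params()
        mv, mh = np.full(4, 0.7), np.full((1, 3), 0.2)
        out = ccrbm.update_offsets(params, mv, mh, ema_rate=1.0)
        assert np.allclose(out.alpha_v, 0.7)
        assert np.allclose(out.alpha_h, 0.2)

    def test_zero_rate_forbidden(self):
        with pytest.raises(ccrbm.CCRBMError):
            ccrbm.update_offsets(toy_params(), np.zeros(4), np.zeros((1, 3)), 0.0)

    def test_geometric_convergence_to_constant_batch(self):
        params = toy_params()
        mv, mh = np.full(4, 0.6), np.full((1, 3), 0.6)
        for _ in range(400):
            params = ccrbm.update_offsets(params, mv, mh, ema_rate=0.05)
        assert np.allclose(params.alpha_v, 0.6, atol=1e-6)
        assert np.allclose(params.alpha_h, 0.6, atol=1e-6)


class TestCD:
    def test_zero_learning_rate_leaves_params_unchanged(self):
        params = toy_params()
        # learning_rate must be positive; emulate "no step" via lr -> tiny
        params.learning_rate = 1e-300
        rng = np.random.default_rng(0)
        v = (np.random.default_rng(1).random((16, 4)) < 0.5).astype(float)
        out = ccrbm.cd_update(v, params, TOY, rng, ema_rate=1e-300)
        assert np.allclose(out.filters, params.filters)
        assert np.allclose(out.hidden_bias, params.hidden_bias)

    def test_centered_gradients_reduce_to_plain(self):
        """Zero offsets: centered and plain CD gradients agree bitwise."""
        params = toy_params().zero_offsets()
        v = (np.random.default_rng(1).random((32, 4)) < 0.5).astype(float)
        gc = ccrbm.cd_gradients(v, params, TOY, np.random.default_rng(5), k=2,
                                centered=True)
        gp = ccrbm.cd_gradients(v, params, TOY, np.random.default_rng(5), k=2,
                                centered=False)
        assert np.array_equal(gc[0], gp[0])
        assert np.array_equal(gc[1], gp[1])
        assert gc[2] == gp[2]

    def test_cd_gradient_aligns_with_exact_gradient(self):
        """CD-5 vs central-difference gradient of the exact log-likelihood."""

        def loglik(vbatch, params):
            vs, _, probs = ccrbm.enumerate_joint(params, TOY)
            ll = 0.0
            for v in vbatch:
                ll += np.log(probs[np.all(vs == v, axis=1)].sum())
            return ll / len(vbatch)

        def numgrad(vbatch, params, eps=1e-5):
            flat = []
            for i in range(params.filters.shape[0]):
                for j in range(params.filters.shape[1]):
                    p1, p2 = params.copy(), params.copy()
                    p1.filters[i, j] += eps
                    p2.filters[i, j] -= eps
                    flat.append((loglik(vbatch, p1) - loglik(vbatch, p2)) / (2 * eps))
            for i in range(len(params.hidden_bias)):
                p1, p2 = params.copy(), params.copy()
                p1.hidden_bias[i] += eps
                p2.hidden_bias[i] -= eps
                flat.append((loglik(vbatch, p1) - loglik(vbatch, p2)) / (2 * eps))
            p1, p2 = params.copy(), params.copy()
            p1.visible_bias += eps
            p2.visible_bias -= eps
            flat.append((loglik(vbatch, p1) - loglik(vbatch, p2)) / (2 * eps))
            return np.array(flat)

        rng = np.random.default_rng(0)
        cosines = []
        for _ in range(100):
            params = ccrbm.CCRBMParameters.initial(TOY, rng, scale=0.7)
            params.hidden_bias = rng.normal(0, 0.7, 1)
            params.visible_bias = float(rng.normal(0, 0.7))
            params = ccrbm.initialize_offsets(params, TOY)
            rates = rng.choice([0.15, 0.85], size=4)
            vbatch = (rng.random((500, 4)) < rates).astype(float)
            exact = numgrad(vbatch, params)
            gw, gb, go, _ = ccrbm.cd_gradients(vbatch, params, TOY, rng, k=5)
            cd = np.concatenate([gw.ravel(), gb, [go]])
            cosines.append(
                cd @ exact / (np.linalg.norm(cd) * np.linalg.norm(exact) + 1e-12)
            )
        assert np.mean(cosines) > 0.9

    def test_empty_batch_rejected(self):
        with pytest.raises(ccrbm.CCRBMError):
            ccrbm.cd_gradients(np.empty((0, 4)), toy_params(), TOY,
                               np.random.default_rng(0))

    def test_training_reduces_reconstruction_error(self):
        """Median over 5 seeds: error after training strictly below epoch 0."""
        from hecare.synth import SyntheticConfig, cohort_matrix, generate_cohort

        structure = ccrbm.CCRBMStructure()  # 5 visible, 2 filters, width 3
        drops = []
        for seed in range(5):
            x, _ = cohort_matrix(
                generate_cohort(SyntheticConfig(n_records=500, seed=seed))
            )
            rng = np.random.default_rng(seed)
            params = ccrbm.CCRBMParameters.initial(structure, rng, scale=0.1)
            params, log = ccrbm.train_ccrbm(x, params, structure, epochs=20, rng=rng)
            drops.append(log[0]["reconstruction_error"] - log[-1]["reconstruction_error"])
        assert np.median(drops) > 0.0


class TestFeaturesAndReadout:
    def test_uniform_signal_features(self):
        params = toy_params()
        params.filters = np.zeros_like(params.filters)
        params.hidden_bias = np.zeros(1)
        params = params.zero_offsets()
        feats = ccrbm.extract_features(np.zeros(4), params, TOY)
        assert np.allclose(feats, 0.75)  # 1 - 1/(1+3)

    def test_features_are_probabilities(self):
        params = toy_params(seed=9)
        rng = np.random.default_rng(2)
        feats = ccrbm.extract_features(rng.random((50, 4)), params, TOY)
        assert np.all((feats >= 0) & (feats <= 1))

    def test_features_deterministic(self):
        params = toy_params(seed=9)
        v = np.array([0.2, 0.8, 0.1, 0.9])
        assert np.array_equal(
            ccrbm.extract_features(v, params, TOY),
            ccrbm.extract_features(v, params, TOY),
        )

    def test_null_readout_gives_half_confidence(self):
        readout = ccrbm.LogisticReadout(weights=np.zeros(3), bias=0.0)
        assert readout.confidence(np.array([0.3, 0.5, 0.9])) == pytest.approx(0.5)

    def test_confidence_monotone_in_logit(self):
        readout = ccrbm.LogisticReadout(weights=np.array([1.0]), bias=0.0)
        confs = readout.confidence(np.linspace(-3, 3, 20)[:, None])
        assert np.all(np.diff(confs) > 0)

    def test_untrained_model_refuses_to_predict(self):
        model = ccrbm.CCRBMModel(structure=TOY, params=toy_params())
        with pytest.raises(ccrbm.UntrainedModelError):
            model.predict(np.zeros(4))

    def test_readout_learns_separable_features(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0.3, 0.05, (200, 2)), rng.normal(0.7, 0.05, (200, 2))])
        y = np.repeat([0, 1], 200)
        readout = ccrbm.train_readout(x, y)
        pred = (readout.confidence(x) >= 0.5).astype(int)
        assert np.mean(pred == y) > 0.95


class TestSerialization:
    def test_model_json_roundtrip(self, tmp_path):
        params = toy_params(seed=12)
        readout = ccrbm.LogisticReadout(
            weights=np.array([0.5]), bias=-0.25,
            feature_mean=np.array([0.6]), feature_scale=np.array([0.1]),
        )
        model = ccrbm.CCRBMModel(structure=TOY, params=params, readout=readout)
        path = tmp_path / "model.json"
        model.save(path)
        back = ccrbm.CCRBMModel.load(path)
        assert back.structure == model.structure
        assert np.array_equal(back.params.filters, model.params.filters)
        assert np.array_equal(back.readout.weights, model.readout.weights)
        label, conf = back.predict(np.array([0.1, 0.9, 0.4, 0.2]))
        assert label in (0, 1) and 0.0 <= conf <= 1.0
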