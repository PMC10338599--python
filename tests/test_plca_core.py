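"""Tests of the EM decomposition: E/M steps, sparsity, fitting and recovery."""

import numpy as np
import pytest

from plcalds import (
    ActivationSet,
    e_step_3d,
    e_step_4d,
    fit_plca,
    m_step_3d,
    m_step_4d,
    reconstruct,
    sample_from_plca_model,
    symptom_activation,
)
from plcalds.dictionary import DictionaryTensor
from plcalds.synthetic_cohort import ConfigurationError, ValidationError
from tests.conftest import random_activations, random_dictionary_3d, random_dictionary_4d


def loop_posterior_3d(V, templates, p_s, p_a):
    """Index-loop reference for the 3D E-step (no vectorisation)."""
    F, S, A = templates.shape
    T = V.shape[1]
    post = np.zeros((S, A, F, T))
    for t in range(T):
        for f in range(F):
            denom = 0.0
            for s in range(S):
                for a in range(A):
                    denom += templates[f, s, a] * p_s[s, t] * p_a[a, s, t]
            for s in range(S):
                for a in range(A):
                    num = templates[f, s, a] * p_s[s, t] * p_a[a, s, t]
                    post[s, a, f, t] = num / denom if denom > 0 else 1.0 / (S * A)
    return post


def loop_m_step_3d(post, V, kappa):
    S, A, F, T = post.shape
    p_s = np.zeros((S, T))
    p_a = np.zeros((A, S, T))
    for t in range(T):
        masses = np.zeros(S)
        for s in range(S):
            for a in range(A):
                for f in range(F):
                    masses[s] += post[s, a, f, t] * V[f, t]
        powered = masses ** kappa
        p_s[:, t] = powered / powered.sum() if powered.sum() > 0 else 1.0 / S
        for s in range(S):
            sub = np.zeros(A)
            for a in range(A):
                for f in range(F):
                    sub[a] += post[s, a, f, t] * V[f, t]
            p_a[:, s, t] = sub / sub.sum() if sub.sum() > 0 else 1.0 / A
    return p_s, p_a


def loop_posterior_4d(V, templates, p_s, p_a, p_m):
    F, M, S, A = templates.shape
    T = V.shape[1]
    post = np.zeros((M, S, A, F, T))
    for t in range(T):
        for f in range(F):
            denom = 0.0
            for m in range(M):
                for s in range(S):
                    for a in range(A):
                        denom += (templates[f, m, s, a] * p_s[s, t]
                                  * p_a[a, s, t] * p_m[m, s, t])
            for m in range(M):
                for s in range(S):
                    for a in range(A):
                        num = (templates[f, m, s, a] * p_s[s, t]
                               * p_a[a, s, t] * p_m[m, s, t])
                        post[m, s, a, f, t] = num / denom if denom > 0 else 1.0 / (M * S * A)
    return post


def loop_m_step_4d(post, V, kappa):
    M, S, A, F, T = post.shape
    p_s = np.zeros((S, T))
    p_a = np.zeros((A, S, T))
    p_m = np.zeros((M, S, T))
    for t in range(T):
        masses = np.einsum("msaf,f->s", post[..., t], V[:, t])
        powered = masses ** kappa
        p_s[:, t] = powered / powered.sum()
        for s in range(S):
            sub_a = np.einsum("maf,f->a", post[:, s, :, :, t], V[:, t])
            p_a[:, s, t] = sub_a / sub_a.sum()
            sub_m = np.einsum("maf,f->m", post[:, s, :, :, t], V[:, t])
            p_m[:, s, t] = sub_m / sub_m.sum()
    return p_s, p_a, p_m


class TestESteps:
    def test_single_component_posterior_is_one(self):
        dic = random_dictionary_3d(F=4, S=1, A=1, seed=0)
        p_s, p_a, _ = random_activations(1, 1, 3, seed=0)
        post = e_step_3d(np.ones((4, 3)), dic, ActivationSet(p_s, p_a))
        np.testing.assert_allclose(post, 1.0)

    def test_uniform_inputs_give_symmetric_posterior(self):
        F, S, A, T = 5, 2, 3, 4
        dic = DictionaryTensor(templates=np.full((F, S, A), 1.0 / F),
                               symptom_names=["a", "b"])
        acts = ActivationSet(np.full((S, T), 1 / S), np.full((A, S, T), 1 / A))
        post = e_step_3d(np.ones((F, T)), dic, acts)
        np.testing.assert_allclose(post, 1.0 / (S * A))

    def test_two_template_posterior_hand_value(self):
        # F=2, S=2, A=1: P(f|s1)=[.75,.25], P(f|s2)=[.25,.75], P(s|t)=[.5,.5]
        templates = np.array([[[0.75], [0.25]], [[0.25], [0.75]]])
        acts = ActivationSet(np.full((2, 1), 0.5), np.ones((1, 2, 1)))
        dic = DictionaryTensor(templates=templates, symptom_names=["a", "b"])
        post = e_step_3d(np.ones((2, 1)), dic, acts)
        assert post[0, 0, 0, 0] == pytest.approx(0.75)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        dic = random_dictionary_3d(F=6, S=3, A=3, seed=1)
        p_s, p_a, _ = random_activations(3, 3, 5, seed=2)
        V = rng.uniform(0, 2, (6, 5))
        post = e_step_3d(V, dic, ActivationSet(p_s, p_a))
        np.testing.assert_allclose(
            post, loop_posterior_3d(V, dic.templates, p_s, p_a), atol=1e-12)

    def test_4d_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        dic = random_dictionary_4d(F=3, M=2, S=2, A=2, seed=3)
        p_s, p_a, p_m = random_activations(2, 2, 4, seed=4, M=2)
        V = rng.uniform(0, 2, (3, 4))
        post = e_step_4d(V, dic, ActivationSet(p_s, p_a, p_m))
        np.testing.assert_allclose(
            post, loop_posterior_4d(V, dic.templates, p_s, p_a, p_m), atol=1e-12)
        np.testing.assert_allclose(post.sum(axis=(0, 1, 2)), 1.0, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        dic = random_dictionary_3d(F=4, S=2, A=3, seed=0)
        p_s, p_a, _ = random_activations(2, 3, 5, seed=0)
        with pytest.raises(ValidationError):
            e_step_3d(np.ones((3, 5)), dic, ActivationSet(p_s, p_a))


class TestMSteps:
    def test_degenerate_posterior_gives_one_hot(self):
        post = np.zeros((2, 1, 3, 2))
        post[0] = 1.0
        p_s, _ = m_step_3d(post, np.ones((3, 2)), kappa=1.0)
        np.testing.assert_allclose(p_s, [[1, 1], [0, 0]])

    def test_plain_update_hand_value(self):
        # V=[3,1], posterior over s given f = [.75,.25] -> masses (2.5, 1.5)
        post = np.array([[[[0.75], [0.25]]], [[[0.25], [0.75]]]]).transpose(1, 0, 2, 3)
        post = np.zeros((2, 1, 2, 1))
        post[0, 0, :, 0] = [0.75, 0.25]
        post[1, 0, :, 0] = [0.25, 0.75]
        V = np.array([[3.0], [1.0]])
        p_s, _ = m_step_3d(post, V, kappa=1.0)
        assert p_s[0, 0] == pytest.approx(0.625)

    def test_sparsity_sharpens_dominant_class(self):
        post = np.zeros((2, 1, 2, 1))
        post[0, 0, :, 0] = [0.75, 0.25]
        post[1, 0, :, 0] = [0.25, 0.75]
        V = np.array([[3.0], [1.0]])
        p_kappa, _ = m_step_3d(post, V, kappa=1.1)
        assert p_kappa[0, 0] == pytest.approx(2.5 ** 1.1 / (2.5 ** 1.1 + 1.5 ** 1.1))
        assert p_kappa[0, 0] > 0.625
        # monotone in kappa
        prev = 0.0
        for kappa in (1.0, 1.2, 1.5, 2.0):
            val, _ = m_step_3d(post, V, kappa=kappa)
            assert val[0, 0] > prev
            prev = val[0, 0]

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        dic = random_dictionary_3d(F=6, S=3, A=3, seed=5)
        p_s, p_a, _ = random_activations(3, 3, 4, seed=6)
        V = rng.uniform(0.1, 2, (6, 4))
        post = e_step_3d(V, dic, ActivationSet(p_s, p_a))
        got_s, got_a = m_step_3d(post, V, kappa=1.1)
        exp_s, exp_a = loop_m_step_3d(post, V, 1.1)
        np.testing.assert_allclose(got_s, exp_s, atol=1e-12)
        np.testing.assert_allclose(got_a, exp_a, atol=1e-12)

    def test_4d_matches_loop_oracle_and_3d_reduction(self):
        rng = np.random.default_rng(7)
        dic4 = random_dictionary_4d(F=3, M=2, S=2, A=2, seed=7)
        p_s, p_a, p_m = random_activations(2, 2, 4, seed=8, M=2)
        V = rng.uniform(0.1, 2, (3, 4))
        post = e_step_4d(V, dic4, ActivationSet(p_s, p_a, p_m))
        got = m_step_4d(post, V, kappa=1.1)
        exp = loop_m_step_4d(post, V, 1.1)
        for g, e in zip(got, exp):
            np.testing.assert_allclose(g, e, atol=1e-12)

    def test_m_equals_one_reduces_to_3d(self):
        rng = np.random.default_rng(9)
        templates = rng.dirichlet(np.ones(4), size=(2, 3)).transpose(2, 0, 1)
        dic3 = DictionaryTensor(templates=templates, symptom_names=["a", "b"])
        dic4 = DictionaryTensor(templates=templates[:, None], symptom_names=["a", "b"],
                                season_names=("spring",))
        p_s, p_a, _ = random_activations(2, 3, 5, seed=10)
        p_m = np.ones((1, 2, 5))
        V = rng.uniform(0.1, 2, (4, 5))
        post3 = e_step_3d(V, dic3, ActivationSet(p_s, p_a))
        post4 = e_step_4d(V, dic4, ActivationSet(p_s, p_a, p_m))
        np.testing.assert_allclose(post4[0], post3, atol=1e-12)
        s3, a3 = m_step_3d(post3, V, 1.1)
        s4, a4, m4 = m_step_4d(post4, V, 1.1)
        np.testing.assert_allclose(s4, s3, atol=1e-12)
        np.testing.assert_allclose(a4, a3, atol=1e-12)
        np.testing.assert_allclose(m4, 1.0, atol=1e-12)

    def test_nonpositive_kappa_rejected(self):
        with pytest.raises(ConfigurationError):
            m_step_3d(np.ones((1, 1, 2, 1)), np.ones((2, 1)), kappa=0.0)


class TestFitting:
    def test_kl_non_increasing_with_plain_em(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            dic = random_dictionary_3d(F=8, S=3, A=3, seed=seed)
            V = rng.uniform(0.1, 1, (8, 20))
            acts = fit_plca(V, dic, kappa=1.0, n_iter=40, seed=seed)
            kl = np.array(acts.kl_history)
            assert np.all(np.diff(kl) <= 1e-10)

    def test_distributions_normalised_after_fit(self):
        rng = np.random.default_rng(11)
        dic = random_dictionary_4d(F=5, M=4, S=2, A=3, seed=11)
        V = rng.uniform(0.1, 1, (5, 12))
        acts = fit_plca(V, dic, model="4D", seed=11)
        acts.validate()

    def test_parameter_recovery_from_model_samples(self):
        # data generated in expectation mode from known activations
        errors = []
        for seed in range(3):
            dic = random_dictionary_3d(F=20, S=2, A=3, seed=seed)
            p_s, p_a, _ = random_activations(2, 3, 50, seed=seed + 50)
            energy = np.random.default_rng(seed).uniform(5, 15, 50)
            V = sample_from_plca_model(dic.templates, p_s, p_a, energy, n_draws=0)
            acts = fit_plca(V, dic, kappa=1.0, n_iter=40, seed=seed + 100)
            errors.append(np.abs(acts.p_s_given_t - p_s).mean())
        assert np.mean(errors) < 0.05

    def test_higher_kappa_lowers_activation_entropy(self):
        rng = np.random.default_rng(13)
        dic = random_dictionary_3d(F=10, S=3, A=3, seed=13)
        V = rng.uniform(0.1, 1, (10, 30))

        def mean_entropy(kappa):
            acts = fit_plca(V, dic, kappa=kappa, n_iter=40, seed=7)
            p = acts.p_s_given_t
            return float(-np.sum(np.where(p > 0, p * np.log(p), 0.0), axis=0).mean())

        e10, e15 = mean_entropy(1.0), mean_entropy(1.5)
        assert e15 < e10

    def test_masked_init_zeros_survive(self):
        dic = random_dictionary_3d(F=6, S=2, A=3, seed=14)
        rng = np.random.default_rng(14)
        V = rng.uniform(0.1, 1, (6, 8))
        init = np.zeros((2, 8))
        init[0, :4] = 1.0
        init[1, 4:] = 1.0
        acts = fit_plca(V, dic, seed=0, init_p_s_given_t=init)
        assert np.all(acts.p_s_given_t[1, :4] == 0)
        assert np.all(acts.p_s_given_t[0, 4:] == 0)

    def test_uniform_init_is_deterministic(self):
        dic = random_dictionary_3d(F=6, S=2, A=3, seed=15)
        rng = np.random.default_rng(15)
        V = rng.uniform(0.1, 1, (6, 8))
        a = fit_plca(V, dic, init="uniform", seed=1)
        b = fit_plca(V, dic, init="uniform", seed=99)
        np.testing.assert_array_equal(a.p_s_given_t, b.p_s_given_t)

    def test_single_component_reconstruction(self):
        # with S=A=1 the mixture collapses to the lone template scaled by P(t)
        dic = random_dictionary_3d(F=5, S=1, A=1, seed=16)
        rng = np.random.default_rng(16)
        V = rng.uniform(0.1, 1, (5, 6))
        acts = fit_plca(V, dic, seed=0)
        recon = reconstruct(dic, acts, V.sum(axis=0))
        expected = dic.templates[:, 0, 0][:, None] * V.sum(axis=0)[None, :]
        np.testing.assert_allclose(recon, expected, atol=1e-12)


class TestSymptomActivation:
    def test_energy_scaling_properties(self):
        p_s, p_a, _ = random_activations(3, 2, 6, seed=17)
        energy = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        out = symptom_activation(ActivationSet(p_s, p_a), energy)
        np.testing.assert_allclose(out.p_st.sum(axis=0), energy, atol=1e-12)
        np.testing.assert_allclose(out.p_st[:, 0], 0.0)

    def test_uniform_activation_splits_energy_evenly(self):
        acts = ActivationSet(np.full((4, 3), 0.25), np.ones((1, 4, 3)))
        out = symptom_activation(acts, np.array([4.0, 8.0, 0.0]))
        np.testing.assert_allclose(out.p_st[:, 0], 1.0)
        np.testing.assert_allclose(out.p_st[:, 1], 2.0)
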