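import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import bernoulli, gamma as gamma_dist

from reeftrack import hmm as H
from reeftrack.hmm import (
    BernoulliStream,
    FittedHMM,
    GammaStream,
    HMMParams,
    HMMSpec,
    fit_hmm,
    forward_loglik,
    moment_init,
    permute_states,
    rank_models,
    stationary_distribution,
    transition_matrices,
    viterbi,
)


# ------------------------------------------------------------------ oracles


def emission_pdf(params, stream, state, x):
    """Independent per-observation density (scipy-based)."""
    if np.isnan(x):
        return 1.0
    d = params.emission[stream.name]
    if stream.family == "bernoulli":
        return bernoulli.pmf(x, d["p"][state])
    m, sd = d["mean"][state], d["sd"][state]
    shape, scale = m * m / sd / sd, sd * sd / m
    if getattr(stream, "zero_inflated", False):
        pi0 = d["zero_mass"][state]
        if x == 0.0:
            return pi0
        return (1 - pi0) * gamma_dist.pdf(x, shape, scale=scale)
    return gamma_dist.pdf(x, shape, scale=scale)


def brute_force(spec, params, df, covariates=None):
    """Enumerate all K^T paths: total likelihood and best path."""
    k = spec.n_states
    t = len(df)
    tms = transition_matrices(spec, params, covariates, t)
    pi = stationary_distribution(tms.mean(axis=0))
    total = 0.0
    best_p, best_path = -1.0, None
    for path in itertools.product(range(k), repeat=t):
        p = pi[path[0]]
        for s in spec.streams:
            p *= emission_pdf(params, s, path[0], df[s.name].iloc[0])
        for i in range(1, t):
            p *= tms[i - 1, path[i - 1], path[i]]
            for s in spec.streams:
                p *= emission_pdf(params, s, path[i], df[s.name].iloc[i])
        total += p
        if p > best_p:
            best_p, best_path = p, path
    return np.log(total), np.array(best_path), np.log(best_p)


def _params_3state(seed=0):
    rng = np.random.default_rng(seed)
    p = HMMParams(
        {
            "g": {
                "mean": np.array([1.0, 3.0, 6.0]),
                "sd": np.array([0.5, 1.0, 2.0]),
                "zero_mass": np.array([0.3, 0.05, 0.1]),
            },
            "b": {"p": np.array([0.1, 0.5, 0.9])},
        },
        rng.normal(0, 1, (3, 3, 1)),
    )
    return p


SPEC_3 = HMMSpec(3, (GammaStream("g", zero_inflated=True), BernoulliStream("b")))


class TestForwardOracle:
    def test_one_state_is_sum_of_log_densities(self):
        spec = HMMSpec(1, (GammaStream("g"),))
        params = HMMParams(
            {"g": {"mean": np.array([2.0]), "sd": np.array([1.0])}},
            np.zeros((1, 1, 1)),
        )
        x = np.array([0.5, 2.0, 3.5])
        expected = sum(
            np.log(gamma_dist.pdf(v, 4.0, scale=0.5)) for v in x
        )
        got = forward_loglik(spec, params, pd.DataFrame({"g": x}))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_enumeration_k3_t6_with_missing_and_zeros(self):
        params = _params_3state()
        df = pd.DataFrame(
            {
                "g": [0.0, 2.5, np.nan, 6.0, 1.0, 0.0],
                "b": [0.0, 1.0, 1.0, np.nan, 0.0, 1.0],
            }
        )
        expected, _, _ = brute_force(SPEC_3, params, df)
        got = forward_loglik(SPEC_3, params, df)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_enumeration_k4_t7_gamma_only(self):
        rng = np.random.default_rng(3)
        spec = HMMSpec(4, (GammaStream("g"),))
        params = HMMParams(
            {
                "g": {
                    "mean": np.array([1.0, 2.0, 4.0, 8.0]),
                    "sd": np.array([0.5, 0.8, 1.5, 3.0]),
                }
            },
            rng.normal(0, 0.8, (4, 4, 1)),
        )
        df = pd.DataFrame({"g": rng.gamma(2.0, 1.5, 7)})
        expected, _, _ = brute_force(spec, params, df)
        assert forward_loglik(spec, params, df) == pytest.approx(expected, abs=1e-10)

    def test_enumeration_with_transition_covariates(self):
        rng = np.random.default_rng(4)
        spec = HMMSpec(
            2, (GammaStream("g"),), covariates=("z",)
        )
        params = HMMParams(
            {"g": {"mean": np.array([1.0, 5.0]), "sd": np.array([0.5, 2.0])}},
            rng.normal(0, 1, (2, 2, 2)),
        )
        df = pd.DataFrame({"g": rng.gamma(2, 1, 6), "z": rng.normal(0, 1, 6)})
        expected, _, _ = brute_force(spec, params, df, covariates=df)
        assert forward_loglik(spec, params, df) == pytest.approx(expected, abs=1e-10)

    def test_all_missing_gives_zero(self):
        params = _params_3state()
        df = pd.DataFrame({"g": [np.nan] * 5, "b": [np.nan] * 5})
        assert forward_loglik(SPEC_3, params, df) == pytest.approx(0.0, abs=1e-12)

    def test_independent_sequences_add(self):
        params = _params_3state()
        df1 = pd.DataFrame({"g": [1.0, 2.0], "b": [0.0, 1.0], "tag_id": "A"})
        df2 = pd.DataFrame({"g": [3.0, 0.0], "b": [1.0, 1.0], "tag_id": "B"})
        both = pd.concat([df1, df2], ignore_index=True)
        ll = forward_loglik(SPEC_3, params, both, seq_col="tag_id")
        ll1 = forward_loglik(SPEC_3, params, df1)
        ll2 = forward_loglik(SPEC_3, params, df2)
        assert ll == pytest.approx(ll1 + ll2, abs=1e-10)

    def test_invalid_gamma_params_raise(self):
        params = _params_3state()
        params.emission["g"]["sd"][0] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            forward_loglik(SPEC_3, params, pd.DataFrame({"g": [1.0], "b": [1.0]}))


class TestViterbi:
    def test_enumeration_k4_t7(self):
        rng = np.random.default_rng(5)
        spec = HMMSpec(4, (GammaStream("g"),))
        params = HMMParams(
            {
                "g": {
                    "mean": np.array([1.0, 2.0, 4.0, 8.0]),
                    "sd": np.array([0.6, 0.9, 1.4, 2.5]),
                }
            },
            rng.normal(0, 0.7, (4, 4, 1)),
        )
        df = pd.DataFrame({"g": rng.gamma(2.0, 2.0, 7)})
        _, best_path, best_logp = brute_force(spec, params, df)
        path = viterbi(spec, params, df)
        assert np.array_equal(path, best_path)

    def test_separated_emissions_reduce_to_nearest_state(self):
        spec = HMMSpec(2, (GammaStream("g"),))
        params = HMMParams(
            {"g": {"mean": np.array([1.0, 100.0]), "sd": np.array([0.01, 1.0])}},
            np.full((2, 2, 1), 0.0),
        )
        df = pd.DataFrame({"g": [1.0, 100.0, 1.0, 1.0, 100.0]})
        path = viterbi(spec, params, df)
        assert np.array_equal(path, [0, 1, 0, 0, 1])

    def test_identity_transitions_give_constant_path(self):
        spec = HMMSpec(2, (GammaStream("g"),))
        params = HMMParams(
            {"g": {"mean": np.array([1.0, 1.5]), "sd": np.array([0.5, 0.5])}},
            np.zeros((2, 2, 1)),
        )
        params.beta[..., 0][~np.eye(2, dtype=bool)] = -50.0  # ~identity matrix
        df = pd.DataFrame({"g": [1.0, 1.2, 1.4, 1.1, 1.3]})
        path = viterbi(spec, params, df, initial=np.array([1.0, 0.0]))
        assert np.array_equal(path, np.zeros(5, dtype=int))

    def test_beats_random_paths(self):
        rng = np.random.default_rng(6)
        params = _params_3state(seed=7)
        df = pd.DataFrame(
            {"g": rng.gamma(2, 1.5, 12), "b": rng.integers(0, 2, 12).astype(float)}
        )
        t = len(df)
        tms = transition_matrices(SPEC_3, params, None, t)
        pi = stationary_distribution(tms.mean(axis=0))

        def path_logp(path):
            lp = np.log(pi[path[0]])
            for s in SPEC_3.streams:
                lp += np.log(emission_pdf(params, s, path[0], df[s.name].iloc[0]))
            for i in range(1, t):
                lp += np.log(tms[i - 1, path[i - 1], path[i]])
                for s in SPEC_3.streams:
                    lp += np.log(emission_pdf(params, s, path[i], df[s.name].iloc[i]))
            return lp

        best = path_logp(viterbi(SPEC_3, params, df))
        for _ in range(1000):
            rand = rng.integers(0, 3, t)
            assert path_logp(rand) <= best + 1e-9


class TestTransitions:
    @given(
        st.lists(
            st.floats(min_value=-5.0, max_value=5.0), min_size=3, max_size=3
        ),
        st.floats(min_value=-10.0, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_one_at_arbitrary_covariates(self, beta_vals, z):
        spec = HMMSpec(3, (GammaStream("g"),), covariates=("z",))
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 1, (3, 3, 2))
        beta[0, 1, 1], beta[0, 2, 1], beta[1, 0, 1] = beta_vals
        params = HMMParams(
            {"g": {"mean": np.ones(3), "sd": np.ones(3)}}, beta
        )
        cov = pd.DataFrame({"z": [z]})
        tm = transition_matrices(spec, params, cov, 1)[0]
        assert np.allclose(tm.sum(axis=1), 1.0, atol=1e-12)
        assert (tm > 0).all()

    def test_stationary_distribution_fixed_point(self):
        rng = np.random.default_rng(1)
        m = rng.dirichlet(np.ones(4), size=4)
        pi = stationary_distribution(m)
        assert np.allclose(pi @ m, pi, atol=1e-10)
        assert pi.sum() == pytest.approx(1.0)


class TestGammaParametrization:
    @given(
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_mean_sd_shape_scale_roundtrip(self, mean, sd):
        shape = mean**2 / sd**2
        scale = sd**2 / mean
        mean_back = shape * scale
        sd_back = np.sqrt(shape) * scale
        assert mean_back == pytest.approx(mean, rel=1e-12)
        assert sd_back == pytest.approx(sd, rel=1e-12)


class TestFit:
    def test_one_state_matches_single_gamma_ml(self):
        rng = np.random.default_rng(8)
        x = rng.gamma(4.0, 0.5, 2000)
        spec = HMMSpec(1, (GammaStream("g"),))
        fit = fit_hmm(spec, pd.DataFrame({"g": x}), n_starts=1, seed=0)
        # oracle: scipy's closed ML fit of a single Gamma
        shape, _, scale = gamma_dist.fit(x, floc=0.0)
        assert fit.params.emission["g"]["mean"][0] == pytest.approx(
            shape * scale, rel=1e-3
        )
        assert fit.params.emission["g"]["sd"][0] == pytest.approx(
            np.sqrt(shape) * scale, rel=1e-2
        )

    def test_small_recovery_and_decoding(self):
        from reeftrack.experiments import behaviour_recovery

        res = behaviour_recovery(seed=3, n_seq=6, t_len=250, n_starts=1)
        assert res["worst_rel_error"] < 0.15
        assert res["balanced_accuracy"] > 0.9

    def test_refit_from_truth_reaches_same_optimum(self):
        from reeftrack.experiments import (
            default_behaviour_truth,
            simulate_gamma_hmm,
        )

        spec = HMMSpec(
            3, (GammaStream("step", zero_inflated=True), GammaStream("vedba"))
        )
        true = default_behaviour_truth()
        df = simulate_gamma_hmm(spec, true, 4, 200, seed=9)
        from_truth = fit_hmm(
            spec, df, seq_col="tag_id", init=true, n_starts=1, seed=0
        )
        perturbed = fit_hmm(spec, df, seq_col="tag_id", n_starts=3, seed=1)
        assert from_truth.loglik >= forward_loglik(
            spec, true, df, seq_col="tag_id"
        ) - 1e-9
        assert abs(from_truth.loglik - perturbed.loglik) < 1e-3 * max(
            1.0, abs(perturbed.loglik)
        ) + 0.5

    def test_moment_init_in_domain(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "g": np.concatenate([rng.gamma(2, 1, 50), np.zeros(5)]),
                "b": rng.integers(0, 2, 55).astype(float),
            }
        )
        init = moment_init(SPEC_3, df)
        assert (init.emission["g"]["mean"] > 0).all()
        assert (init.emission["g"]["sd"] > 0).all()
        assert ((init.emission["g"]["zero_mass"] > 0) & (init.emission["g"]["zero_mass"] < 1)).all()


class TestRanking:
    def _dummy(self, loglik, n_params, n_obs=100):
        spec = HMMSpec(1, (GammaStream("g"),))
        params = HMMParams(
            {"g": {"mean": np.ones(1), "sd": np.ones(1)}}, np.zeros((1, 1, 1))
        )
        return FittedHMM(spec, params, loglik, n_params, True, n_obs)

    def test_aic_formula(self):
        m = self._dummy(-100.0, 5)
        assert m.aic == 210.0

    def test_ascending_order_with_delta(self):
        tab = rank_models([self._dummy(-100.0, 5), self._dummy(-90.0, 5)])
        assert list(tab["index"]) == [1, 0]
        assert tab["delta_aic"].iloc[0] == 0.0
        assert tab["delta_aic"].iloc[1] == pytest.approx(20.0)

    def test_duplicate_models_stable_tie(self):
        tab = rank_models([self._dummy(-100.0, 5), self._dummy(-100.0, 5)])
        assert list(tab["index"]) == [0, 1]

    def test_different_data_rejected(self):
        with pytest.raises(ValueError, match="different observation"):
            rank_models([self._dummy(-100.0, 5, 100), self._dummy(-90.0, 5, 99)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])


class TestPermute:
    def test_permutation_is_inverse_consistent(self):
        params = _params_3state(seed=11)
        fitted = FittedHMM(SPEC_3, params, -10.0, SPEC_3.n_params(), True, 50)
        perm = np.array([2, 0, 1])
        out = permute_states(fitted, perm)
        assert np.allclose(
            out.params.emission["g"]["mean"],
            params.emission["g"]["mean"][perm],
        )
        df = pd.DataFrame({"g": [1.0, 3.0, 6.0, 0.0], "b": [0.0, 1.0, 1.0, 0.0]})
        ll_before = forward_loglik(SPEC_3, params, df)
        ll_after = forward_loglik(SPEC_3, out.params, df)
        assert ll_before == pytest.approx(ll_after, abs=1e-9)
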