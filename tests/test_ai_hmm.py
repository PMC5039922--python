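import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phaseai.ai_hmm import (
    STATE_A1,
    STATE_A2,
    STATE_N,
    AIEvent,
    HMMParams,
    build_transition_matrix,
    call_events,
    detect_track,
    emission_matrix,
    emission_prob,
    encode_track,
    estimate_fraction,
    estimate_gamma_em,
    forward_backward,
    simulate_hmm_track,
    stationary_distribution,
    viterbi_segments,
)
from phaseai.vcf_io import MarkerTable

from _oracles import enumerate_hmm
from conftest import make_table


def random_params(rng):
    return HMMParams(
        prevalence=rng.uniform(0.01, 0.4),
        mean_event_markers=rng.uniform(2.0, 500.0),
        gamma=rng.uniform(0.55, 0.95),
        switch_rate=rng.uniform(0.0, 0.3),
    )


def random_track(rng, n):
    z = rng.choice([0.0, 1.0, np.nan], size=n, p=[0.4, 0.4, 0.2])
    return z


class TestHMMParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"prevalence": 0.0},
            {"prevalence": 1.0},
            {"mean_event_markers": 1.0},
            {"gamma": 0.5},
            {"gamma": 1.0},
            {"switch_rate": 0.5},
            {"switch_rate": -0.1},
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            HMMParams(**kw)


class TestTransitionMatrix:
    def test_rows_sum_to_one(self):
        T = build_transition_matrix(HMMParams())
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_exit_mass_is_reciprocal_length(self):
        T = build_transition_matrix(HMMParams(mean_event_markers=100.0))
        assert T[STATE_A1, STATE_N] == pytest.approx(0.01)
        assert T[STATE_A2, STATE_N] == pytest.approx(0.01)

    def test_vanishing_prevalence_limit(self):
        T = build_transition_matrix(HMMParams(prevalence=1e-9))
        assert T[STATE_N, STATE_A1] < 1e-9
        assert T[STATE_N, STATE_A2] < 1e-9

    def test_invalid_entry_rate_named_error(self):
        with pytest.raises(ValueError, match="prevalence.*mean_event_markers"):
            build_transition_matrix(
                HMMParams(prevalence=0.9, mean_event_markers=2.0)
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_stationary_ai_mass_eigen_oracle(self, seed):
        """Leading left eigenvector of T carries AI mass == prevalence."""
        rng = np.random.default_rng(seed)
        params = random_params(rng)
        T = build_transition_matrix(params)
        w, v = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = pi / pi.sum()
        assert pi[STATE_A1] + pi[STATE_A2] == pytest.approx(
            params.prevalence, abs=1e-9
        )
        assert np.allclose(pi, stationary_distribution(params), atol=1e-9)


class TestEmissions:
    def test_null_emission(self):
        assert emission_prob(STATE_N, 1, 0.8) == 0.5
        assert emission_prob(STATE_N, 0, 0.8) == 0.5

    def test_ai_emissions(self):
        assert emission_prob(STATE_A1, 1, 0.8) == 0.8
        assert emission_prob(STATE_A1, 0, 0.8) == pytest.approx(0.2)
        assert emission_prob(STATE_A2, 0, 0.8) == 0.8
        assert emission_prob(STATE_A2, 1, 0.8) == pytest.approx(0.2)

    def test_missing_uninformative(self):
        for s in (STATE_N, STATE_A1, STATE_A2):
            assert emission_prob(s, np.nan, 0.8) == 1.0
            assert emission_prob(s, None, 0.8) == 1.0

    def test_normalized_over_observations(self):
        E = emission_matrix(0.77)
        assert np.allclose(E[:, 0] + E[:, 1], 1.0)

    def test_matrix_matches_scalar(self):
        E = emission_matrix(0.8)
        for s in range(3):
            for code, z in ((0, 0), (1, 1), (2, np.nan)):
                assert E[s, code] == emission_prob(s, z, 0.8)


class TestForwardBackward:
    def test_all_missing_returns_prior(self):
        params = HMMParams(prevalence=0.07)
        post = forward_backward(np.full(50, np.nan), params)
        assert np.allclose(post.p_ai, 0.07, atol=1e-12)

    def test_posteriors_normalized(self):
        rng = np.random.default_rng(0)
        z = random_track(rng, 500)
        post = forward_backward(z, HMMParams())
        assert np.allclose(post.state_probs.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng)
        n = int(rng.integers(1, 11))
        z = random_track(rng, n)
        post = forward_backward(z, params)
        T = build_transition_matrix(params)
        pi = stationary_distribution(params)
        E = emission_matrix(params.gamma)
        want_post, _, want_ll = enumerate_hmm(encode_track(z), T, pi, E)
        assert np.allclose(post.state_probs, want_post, atol=1e-10)
        assert post.loglik == pytest.approx(want_ll, abs=1e-10)

    def test_constant_track_high_posterior(self):
        z = np.ones(200)
        params = HMMParams(prevalence=0.05, gamma=0.8)
        post = forward_backward(z, params)
        assert np.all(post.p_ai[50:150] > 0.99)

    def test_interior_posterior_monotone_in_length(self):
        params = HMMParams(prevalence=0.05, gamma=0.8)
        mids = []
        for n in (4, 8, 16, 32, 64):
            post = forward_backward(np.ones(n), params)
            mids.append(post.p_ai[n // 2])
        assert np.all(np.diff(mids) >= -1e-12)

    def test_interior_posterior_monotone_in_gamma(self):
        mids = []
        for g in (0.55, 0.65, 0.75, 0.85, 0.95):
            post = forward_backward(np.ones(40), HMMParams(gamma=g))
            mids.append(post.p_ai[20])
        assert np.all(np.diff(mids) >= -1e-12)

    def test_relabel_symmetry_p_ai(self):
        rng = np.random.default_rng(5)
        z = random_track(rng, 300)
        params = HMMParams()
        p1 = forward_backward(z, params)
        p2 = forward_backward(1.0 - z, params)  # NaN stays NaN
        assert np.allclose(p1.p_ai, p2.p_ai, atol=1e-12)
        # the two AI orientations swap exactly
        assert np.allclose(
            p1.state_probs[:, STATE_A1], p2.state_probs[:, STATE_A2], atol=1e-12
        )

    def test_chromosomes_independent(self):
        rng = np.random.default_rng(9)
        z = random_track(rng, 100)
        params = HMMParams()
        ids = np.array([0] * 60 + [1] * 40)
        joint = forward_backward(z, params, chrom_ids=ids)
        a = forward_backward(z[:60], params)
        b = forward_backward(z[60:], params)
        assert np.allclose(joint.state_probs[:60], a.state_probs, atol=1e-12)
        assert np.allclose(joint.state_probs[60:], b.state_probs, atol=1e-12)
        assert joint.loglik == pytest.approx(a.loglik + b.loglik, abs=1e-8)

    def test_underflow_free_long_track(self):
        rng = np.random.default_rng(1)
        z = (rng.random(1_000_000) < 0.5).astype(float)
        post = forward_backward(z, HMMParams())
        assert np.isfinite(post.loglik)
        assert np.all(np.isfinite(post.p_ai))

    def test_empty_track_error(self):
        with pytest.raises(ValueError):
            forward_backward(np.array([]), HMMParams())


class TestViterbi:
    def test_all_missing_all_n(self):
        path = viterbi_segments(np.full(30, np.nan), HMMParams(prevalence=0.05))
        assert np.all(path == STATE_N)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_argmax(self, seed):
        rng = np.random.default_rng(seed + 1000)
        params = random_params(rng)
        n = int(rng.integers(1, 11))
        z = random_track(rng, n)
        path = viterbi_segments(z, params)
        T = build_transition_matrix(params)
        pi = stationary_distribution(params)
        E = emission_matrix(params.gamma)
        _, want_path, _ = enumerate_hmm(encode_track(z), T, pi, E)
        assert np.array_equal(path, want_path)

    def test_relabel_swaps_orientations(self):
        rng = np.random.default_rng(2)
        z = random_track(rng, 200)
        params = HMMParams(gamma=0.9, prevalence=0.2)
        p1 = viterbi_segments(z, params)
        p2 = viterbi_segments(1.0 - z, params)
        swap = {STATE_N: STATE_N, STATE_A1: STATE_A2, STATE_A2: STATE_A1}
        assert np.array_equal(p2, np.array([swap[s] for s in p1]))


class TestCallEvents:
    def _post(self, p):
        return np.asarray(p, dtype=float)

    def test_no_marker_above_cut(self):
        table = make_table(5)
        events = call_events(self._post([0.1] * 5), table, np.ones(5), 0.9, 1)
        assert events == []

    def test_single_run(self):
        n = 50
        table = make_table(n)
        p = np.zeros(n)
        p[10:40] = 0.99
        events = call_events(self._post(p), table, np.ones(n), 0.9, 10)
        assert len(events) == 1
        ev = events[0]
        assert ev.n_markers == 30
        assert ev.start_pos == table.pos[10]
        assert ev.end_pos == table.pos[39]

    def test_runs_not_merged_across_gap(self):
        n = 41
        table = make_table(n)
        p = np.full(n, 0.95)
        p[20] = 0.5
        events = call_events(self._post(p), table, np.ones(n), 0.9, 10)
        assert len(events) == 2

    def test_short_run_dropped(self):
        n = 20
        table = make_table(n)
        p = np.zeros(n)
        p[5:10] = 0.99
        assert call_events(self._post(p), table, np.ones(n), 0.9, 10) == []

    def test_missing_flanks_trimmed(self):
        n = 30
        table = make_table(n)
        p = np.zeros(n)
        p[5:25] = 0.99
        z = np.ones(n)
        z[5] = z[6] = z[24] = np.nan
        events = call_events(self._post(p), table, z, 0.9, 5)
        assert len(events) == 1
        assert events[0].start_pos == table.pos[7]
        assert events[0].end_pos == table.pos[23]
        assert events[0].n_markers == 17

    def test_mean_raf_dev_and_fraction(self):
        n = 12
        rng = np.random.default_rng(0)
        ref = np.full(n, 58)
        hap1 = rng.permutation([0, 1] * (n // 2))
        table = MarkerTable(
            np.full(n, "1", dtype=object),
            1000 * np.arange(1, n + 1),
            ref,
            100 - ref,
            hap1,
            1 - hap1,
        )
        events = call_events(self._post(np.ones(n)), table, np.ones(n), 0.9, 5)
        assert len(events) == 1
        assert events[0].mean_raf_dev == pytest.approx(0.08)
        assert events[0].est_fraction_cnloh == pytest.approx(0.16)


class TestEstimateFraction:
    @pytest.mark.parametrize("model", ["cnloh", "deletion", "amplification"])
    def test_zero_dev_zero_fraction(self, model):
        assert estimate_fraction(0.0, model) == 0.0

    def test_cnloh_inverts_forward_model(self):
        # forward: f=0.16 -> favored RAF (1+f)/2 = 0.58 -> d = 0.08
        assert estimate_fraction(0.08, "cnloh") == pytest.approx(0.16)

    def test_deletion_round_trip(self):
        # forward: f=0.5 -> kept-allele RAF 1/(2-f) = 2/3 -> d = 1/6
        assert estimate_fraction(1 / 6, "deletion") == pytest.approx(0.5)

    def test_amplification_round_trip(self):
        f = 0.3
        d = (1 + f) / (2 + f) - 0.5
        assert estimate_fraction(d, "amplification") == pytest.approx(f)

    def test_amplification_capped(self):
        assert estimate_fraction(0.49, "amplification") == 1.0
        assert estimate_fraction(0.5, "amplification") == 1.0

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            estimate_fraction(0.1, "duplication")


class TestEstimateGammaEM:
    def test_recovers_gamma_from_model_draws(self):
        rng = np.random.default_rng(0)
        truth = HMMParams(prevalence=0.2, mean_event_markers=200.0, gamma=0.8)
        _, z = simulate_hmm_track(truth, 50_000, rng)
        start = HMMParams(prevalence=0.2, mean_event_markers=200.0, gamma=0.65)
        res = estimate_gamma_em(z, start, max_iter=100, tol=1e-5)
        assert 0.75 <= res.gamma <= 0.85

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(1)
        truth = HMMParams(prevalence=0.1, gamma=0.85)
        _, z = simulate_hmm_track(truth, 5_000, rng)
        res = estimate_gamma_em(z, HMMParams(gamma=0.6), max_iter=40, tol=0.0)
        ll = np.array(res.loglik_history)
        assert np.all(np.diff(ll) >= -1e-8)

    def test_null_drifts_toward_half_and_no_calls(self):
        rng = np.random.default_rng(2)
        z = rng.integers(0, 2, size=20_000).astype(float)
        res = estimate_gamma_em(z, HMMParams(), max_iter=60)
        assert res.gamma < 0.62
        post = forward_backward(
            z, HMMParams(gamma=max(res.gamma, 0.5 + 1e-6))
        )
        assert np.all(post.p_ai < 0.5)

    def test_all_missing_returns_input_gamma(self, caplog):
        with caplog.at_level("WARNING"):
            res = estimate_gamma_em(np.full(200, np.nan), HMMParams(gamma=0.7))
        assert res.gamma == 0.7
        assert "missing" in caplog.text


class TestDetectTrack:
    def test_detects_simulated_run(self):
        rng = np.random.default_rng(4)
        n = 2000
        table = make_table(n)
        # inject an imbalanced stretch by rebuilding depths: RAF 0.58 tracking hap1
        ref = table.ref_depth.copy()
        alt = table.alt_depth.copy()
        lo, hi = 800, 1200
        depth = 100
        for i in range(lo, hi):
            p = 0.58 if table.hap1[i] == 0 else 0.42
            r = rng.binomial(depth, p)
            ref[i], alt[i] = r, depth - r
        out = ref.copy()
        table2 = MarkerTable(table.chrom, table.pos, ref, alt, table.hap1, table.hap2)
        res = detect_track(table2)
        assert len(res.events) >= 1
        ev = max(res.events, key=lambda e: e.n_markers)
        assert ev.start_pos >= table.pos[lo - 50]
        assert ev.end_pos <= table.pos[hi + 50 - 1]

    def test_posterior_prior_relation_held(self):
        table = make_table(100, seed=8)
        res = detect_track(table, em=False)
        assert np.allclose(
            res.posteriors.state_probs.sum(axis=1), 1.0, atol=1e-9
        )


class TestPropertyInvariants:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_posterior_sums_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng)
        z = random_track(rng, int(rng.integers(1, 200)))
        post = forward_backward(z, params)
        assert np.allclose(post.state_probs.sum(axis=1), 1.0, atol=1e-9)
        flipped = forward_backward(1.0 - z, params)
        assert np.allclose(post.p_ai, flipped.p_ai, atol=1e-10)
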