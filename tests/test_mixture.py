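import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from epimix.annotation_io import PATTERNS, ScoreTrack, TrainingSample
from epimix.mixture import (
    BernoulliMarkMixture,
    MixtureParams,
    _e_step,
    _m_step,
    em_fit,
    functional_fraction,
    gs_posterior,
    load_mixture_params,
    log_likelihood,
    overlap_log_odds,
    pattern_posteriors,
    save_mixture_params,
    score_genome,
    tissue_count_profile,
)
from conftest import dense_mark_matrix, random_trackset


def simulate_vectors(pi, p1, p0, n, rng):
    z = rng.random(n) < pi
    rates = np.where(z[:, None], p1, p0)
    return (rng.random((n, 8)) < rates).astype(np.int8), z


class TestLogLikelihood:
    def test_equal_components_reduce_to_single_bernoulli(self, rng):
        rates = np.full(8, 0.3)
        params = MixtureParams(0.5, rates, rates)
        vecs, _ = simulate_vectors(0.5, rates, rates, 500, rng)
        sample = TrainingSample.from_vectors(vecs)
        expected = float(
            (vecs @ np.log(rates) + (1 - vecs) @ np.log1p(-rates)).sum()
        )
        assert log_likelihood(params, sample) == pytest.approx(expected, rel=1e-12)

    def test_single_all_zero_observation(self):
        # pi 0.1, p1 = 0.8, p0 = 0.05: direct arithmetic
        params = MixtureParams(0.1, np.full(8, 0.8), np.full(8, 0.05))
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = 1
        expected = np.log(0.1 * 0.2**8 + 0.9 * 0.95**8)
        assert log_likelihood(params, counts) == pytest.approx(expected, rel=1e-14)

    def test_per_site_equals_pattern_lookup(self, rng):
        params = MixtureParams(0.2, rng.uniform(0.5, 0.9, 8), rng.uniform(0.05, 0.3, 8))
        vecs, _ = simulate_vectors(0.2, params.p1, params.p0, 300, rng)
        per_site = 0.0
        for v in vecs:
            l1 = np.prod(params.p1**v * (1 - params.p1) ** (1 - v))
            l0 = np.prod(params.p0**v * (1 - params.p0) ** (1 - v))
            per_site += np.log(params.pi * l1 + (1 - params.pi) * l0)
        pattern = log_likelihood(params, TrainingSample.from_vectors(vecs))
        assert pattern == pytest.approx(per_site, rel=1e-10)

    def test_empty_data_errors(self):
        params = MixtureParams(0.5, np.full(8, 0.7), np.full(8, 0.1))
        with pytest.raises(ValueError, match="empty"):
            log_likelihood(params, np.zeros(256, dtype=np.int64))


class TestEmFit:
    def test_m_step_with_unit_responsibilities_gives_empirical_means(self, rng):
        vecs = (rng.random((400, 8)) < 0.4).astype(np.int8)
        counts = TrainingSample.from_vectors(vecs).pattern_counts
        params = _m_step(counts, np.ones(256))
        np.testing.assert_allclose(params.p1, vecs.mean(axis=0), atol=1e-12)

    def test_loglik_nondecreasing_each_iteration(self, rng):
        for _ in range(20):
            pi = rng.uniform(0.05, 0.5)
            p1 = rng.uniform(0.4, 0.95, 8)
            p0 = rng.uniform(0.02, 0.4, 8)
            vecs, _ = simulate_vectors(pi, p1, p0, 2000, rng)
            _, trace = em_fit(
                TrainingSample.from_vectors(vecs),
                seed=int(rng.integers(1 << 30)),
                n_restarts=1,
                max_iter=200,
            )
            diffs = np.diff(trace.loglik_per_iter)
            assert (diffs >= -1e-9 * np.abs(trace.loglik_per_iter[:-1])).all()

    def test_seventeen_free_parameters(self, rng):
        vecs, _ = simulate_vectors(0.2, np.full(8, 0.7), np.full(8, 0.1), 2000, rng)
        params, _ = em_fit(TrainingSample.from_vectors(vecs), seed=0)
        assert params.n_parameters == 17
        assert params.as_vector().shape == (17,)

    def test_parameter_recovery_improves_with_n(self):
        # estimates converge toward truth as n grows
        truth = MixtureParams(0.1, np.full(8, 0.7), np.full(8, 0.1))
        errs = []
        for n in (20_000, 200_000):
            rng = np.random.default_rng(99)
            vecs, _ = simulate_vectors(truth.pi, truth.p1, truth.p0, n, rng)
            params, _ = em_fit(TrainingSample.from_vectors(vecs), seed=0)
            errs.append(
                np.abs(params.as_vector() - truth.as_vector()).max()
            )
        assert errs[1] < errs[0]

    def test_single_pattern_data_is_rejected(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[255] = 1000
        with pytest.raises(ValueError, match="single mark pattern"):
            em_fit(counts)

    def test_functional_component_is_annotation_rich(self, rng):
        vecs, _ = simulate_vectors(0.15, np.full(8, 0.75), np.full(8, 0.08),
                                   30_000, rng)
        params, _ = em_fit(TrainingSample.from_vectors(vecs), seed=3)
        assert params.p1.mean() >= params.p0.mean()

    def test_explicit_init_runs_single_start(self, rng):
        vecs, _ = simulate_vectors(0.2, np.full(8, 0.7), np.full(8, 0.1), 5000, rng)
        init = MixtureParams(0.3, np.full(8, 0.6), np.full(8, 0.2))
        sample = TrainingSample.from_vectors(vecs)
        p_a, _ = em_fit(sample, init=init)
        p_b, _ = em_fit(sample, init=init)
        np.testing.assert_array_equal(p_a.as_vector(), p_b.as_vector())


class TestGsPosterior:
    def test_equal_components_give_prior(self):
        rates = np.full(8, 0.4)
        params = MixtureParams(0.37, rates, rates)
        for code in (0, 17, 255):
            assert gs_posterior(params, PATTERNS[code]) == pytest.approx(0.37)

    def test_all_ones_vector_direct_arithmetic(self):
        params = MixtureParams(0.1, np.full(8, 0.8), np.full(8, 0.05))
        num = 0.1 * 0.8**8
        expected = num / (num + 0.9 * 0.05**8)
        got = gs_posterior(params, np.ones(8))
        assert got == pytest.approx(expected, rel=1e-12)
        assert 1 - got < 3e-9  # essentially certain functional

    def test_posterior_in_unit_interval(self, rng):
        params = MixtureParams(0.2, rng.uniform(0.5, 0.9, 8), rng.uniform(0.01, 0.3, 8))
        post = gs_posterior(params, PATTERNS)
        assert ((post >= 0) & (post <= 1)).all()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        code=st.integers(0, 255),
        i=st.integers(0, 7),
        bump=st.floats(0.01, 0.2),
    )
    def test_monotone_in_functional_rate(self, code, i, bump):
        """Raising p1[i] never lowers the posterior of a vector with A_i = 1."""
        a = PATTERNS[code].copy()
        a[i] = 1.0
        p1 = np.full(8, 0.6)
        lo = gs_posterior(MixtureParams(0.3, p1, np.full(8, 0.1)), a)
        p1_hi = p1.copy()
        p1_hi[i] = min(0.6 + bump, 0.999)
        hi = gs_posterior(MixtureParams(0.3, p1_hi, np.full(8, 0.1)), a)
        assert hi >= lo - 1e-12


class TestScoreGenome:
    def test_equals_perbp_oracle(self, toy_trackset):
        ts, dense = toy_trackset
        params = MixtureParams(0.2, np.full(8, 0.7), np.full(8, 0.1))
        track = score_genome(params, ts)
        for chrom, length in ts.genome.items():
            mat = dense_mark_matrix(dense, chrom, length)
            oracle = np.asarray(gs_posterior(params, mat.astype(float)))
            np.testing.assert_array_equal(track.dense(chrom), oracle)

    def test_no_peaks_gives_constant_allzero_posterior(self):
        ts, _ = random_trackset({"c": 5000}, np.random.default_rng(0), density=0.0)
        params = MixtureParams(0.2, np.full(8, 0.7), np.full(8, 0.1))
        track = score_genome(params, ts)
        expected = gs_posterior(params, np.zeros(8))
        s, e, v = track.runs["c"]
        assert list(s) == [0] and list(e) == [5000]
        assert v[0] == pytest.approx(expected)

    def test_at_most_256_distinct_values(self, toy_trackset):
        ts, _ = toy_trackset
        params = MixtureParams(0.2, np.full(8, 0.8), np.full(8, 0.05))
        track = score_genome(params, ts)
        values = np.concatenate([track.runs[c][2] for c in track.runs])
        assert np.unique(values).size <= 256


class TestSummaries:
    def test_functional_fraction_all_ones(self, toy_genome=None):
        genome = {"c": 1000}
        track = ScoreTrack.constant(genome, 1.0)
        assert functional_fraction(track, 0.5) == 1.0
        assert functional_fraction(track, 1.0) == 1.0

    def test_functional_fraction_cutoff_zero_universal(self):
        track = ScoreTrack.constant({"c": 1000}, 0.01)
        assert functional_fraction(track, 0.0) == 1.0

    def test_functional_fraction_counts_thresholded_bp(self):
        genome = {"c": 1000}
        track = ScoreTrack.from_runs(
            genome, {"c": ([0, 100], [100, 1000], [0.9, 0.2])}
        )
        assert functional_fraction(track, 0.5) == pytest.approx(0.1)

    def test_tissue_count_profile_identical_tracks(self):
        genome = {"c": 1000}
        t = ScoreTrack.from_runs(genome, {"c": ([100], [300], [0.9])})
        prof = tissue_count_profile({"a": t, "b": t, "d": t}, 0.5)
        assert prof == {0: 800, 1: 0, 2: 0, 3: 200}

    def test_tissue_count_profile_disjoint_tracks(self):
        genome = {"c": 1000}
        a = ScoreTrack.from_runs(genome, {"c": ([0], [100], [0.9])})
        b = ScoreTrack.from_runs(genome, {"c": ([500], [700], [0.9])})
        prof = tissue_count_profile({"a": a, "b": b}, 0.5)
        assert prof == {0: 700, 1: 300, 2: 0}

    def test_tissue_count_profile_matches_perbp_oracle(self, rng):
        genome = {"c": 2000, "d": 1500}
        tracks = {
            name: TestScoreTrackHelper.random_track(rng, genome)
            for name in ("x", "y", "z")
        }
        prof = tissue_count_profile(tracks, 0.5)
        dense_counts = {k: 0 for k in range(4)}
        for chrom, length in genome.items():
            k = sum(
                (tracks[n].dense(chrom) >= 0.5).astype(int) for n in tracks
            )
            for kk in range(4):
                dense_counts[kk] += int((k == kk).sum())
        assert prof == dense_counts

    def test_tissue_count_profile_rejects_mismatched_genomes(self):
        a = ScoreTrack.constant({"c": 100}, 1.0)
        b = ScoreTrack.constant({"c": 200}, 1.0)
        with pytest.raises(ValueError, match="genome"):
            tissue_count_profile({"a": a, "b": b})

    def test_overlap_log_odds_toy_table(self):
        # a covers [0,150), b covers [0,100)+[150,175) on a 1000 bp genome:
        # n11=100, n10=50, n01=25, n00=825
        genome = {"c": 1000}
        a = ScoreTrack.from_runs(genome, {"c": ([0], [150], [1.0])})
        b = ScoreTrack.from_runs(genome, {"c": ([0, 150], [100, 175], [1.0, 1.0])})
        expected = np.log((100.5 * 825.5) / (50.5 * 25.5))
        assert overlap_log_odds(a, b, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_overlap_log_odds_independent_tracks_near_zero(self, rng):
        genome = {"c": 200_000}
        a = TestScoreTrackHelper.random_track(rng, genome, block=100)
        b = TestScoreTrackHelper.random_track(rng, genome, block=100)
        assert abs(overlap_log_odds(a, b, 0.5)) < 0.2

    def test_overlap_log_odds_self_is_large_finite(self):
        genome = {"c": 1000}
        a = ScoreTrack.from_runs(genome, {"c": ([0], [100], [0.9])})
        val = overlap_log_odds(a, a, 0.5)
        assert np.isfinite(val) and val > 5


class TestScoreTrackHelper:
    @staticmethod
    def random_track(rng, genome, block=50):
        runs = {}
        for chrom, length in genome.items():
            n = length // block
            vals = rng.random(n)
            starts = np.arange(n) * block
            ends = starts + block
            runs[chrom] = (starts, ends, vals)
        return ScoreTrack.from_runs(genome, runs)


class TestSerialization:
    def test_roundtrip_is_bit_exact(self, tmp_path, rng):
        params = MixtureParams(
            rng.uniform(0.05, 0.5),
            rng.uniform(0.5, 0.9, 8),
            rng.uniform(0.01, 0.3, 8),
        )
        path = tmp_path / "params.txt"
        save_mixture_params(path, params)
        loaded, marks = load_mixture_params(path)
        assert loaded.pi == params.pi
        np.testing.assert_array_equal(loaded.p1, params.p1)
        np.testing.assert_array_equal(loaded.p0, params.p0)
        assert len(marks) == 8


class TestEstimatorApi:
    def test_fit_attributes_and_posterior(self, rng):
        X, z = simulate_vectors(0.2, np.full(8, 0.75), np.full(8, 0.08), 20_000, rng)
        est = BernoulliMarkMixture(random_state=0).fit(X)
        assert 0 < est.pi_ < 1
        assert est.p1_.shape == est.p0_.shape == (8,)
        proba = est.predict_proba(X[:100])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        # posterior separates planted components
        post = est.posterior(X)
        assert post[z].mean() > post[~z].mean() + 0.3

    def test_clone_and_get_params(self):
        est = BernoulliMarkMixture(tol=1e-6, n_restarts=2, random_state=7)
        params = clone(est).get_params()
        assert params["tol"] == 1e-6
        assert params["n_restarts"] == 2
        assert params["random_state"] == 7

    def test_sample_weight_equals_repetition(self, rng):
        X = (rng.random((200, 8)) < 0.5).astype(np.int8)
        w = rng.integers(1, 4, size=200)
        a = BernoulliMarkMixture(random_state=1).fit(X, sample_weight=w)
        b = BernoulliMarkMixture(random_state=1).fit(np.repeat(X, w, axis=0))
        np.testing.assert_allclose(a.p1_, b.p1_, atol=1e-10)
        assert a.pi_ == pytest.approx(b.pi_, abs=1e-10)
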