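"""Generator statistics and the exact Bayes decoding oracle."""

import numpy as np
import pytest
from scipy import stats

from condasp.io_features import AA_ALPHABET, N_AA
from condasp.synthetic import (N_STATES, SyntheticSpec, bayes_q8, default_spec,
                               posterior_decode, run_structured_transition,
                               sample_states, simulate_dataset,
                               simulate_protein, stationary_distribution,
                               strong_signal_spec)

from conftest import brute_force_posteriors


def _spec(transition=None, emissions=None, initial=None, pssm_noise_sd=0.0,
          length_range=(10, 20), seed=0, n_proteins=4):
    if transition is None:
        transition = run_structured_transition(0.85)
    if initial is None:
        initial = stationary_distribution(transition)
    if emissions is None:
        emissions = np.full((N_STATES, N_AA), 1.0 / N_AA)
    return SyntheticSpec(n_proteins=n_proteins, length_range=length_range,
                         transition=transition, initial=initial,
                         emissions=emissions, pssm_noise_sd=pssm_noise_sd,
                         seed=seed)


def _identity_emissions():
    """State k emits residue k with certainty."""
    e = np.zeros((N_STATES, N_AA))
    e[np.arange(N_STATES), np.arange(N_STATES)] = 1.0
    return e


class TestSpecValidation:
    def test_non_stochastic_rows_rejected(self):
        T = run_structured_transition(0.85)
        T[0, 0] += 0.01
        with pytest.raises(ValueError, match="sum to 1"):
            _spec(transition=T)

    def test_degenerate_self_transition_rejected(self):
        T = np.eye(N_STATES)
        with pytest.raises(ValueError):
            _spec(transition=T)

    def test_length_range_floor(self):
        with pytest.raises(ValueError):
            _spec(length_range=(1, 5))

    def test_spec_json_round_trip(self):
        spec = default_spec(seed=3, n_proteins=7)
        back = SyntheticSpec.from_json(spec.to_json())
        assert back.n_proteins == 7 and back.length_range == spec.length_range
        assert np.array_equal(back.transition, spec.transition)
        assert np.array_equal(back.emissions, spec.emissions)


class TestSimulation:
    def test_record_satisfies_all_invariants(self):
        spec = default_spec(seed=5, n_proteins=1)
        r = simulate_protein(spec, np.random.default_rng(0), "t")
        assert spec.length_range[0] <= len(r) <= spec.length_range[1]
        assert r.pssm.shape == (len(r), N_AA)
        assert r.labels is not None and len(r.labels) == len(r)

    def test_deterministic_emissions_make_labels_recoverable(self):
        spec = _spec(emissions=_identity_emissions(), length_range=(50, 50))
        r = simulate_protein(spec, np.random.default_rng(1))
        lookup = {AA_ALPHABET[k]: "GHIEBTSL"[k] for k in range(8)}
        assert "".join(lookup[c] for c in r.sequence) == r.labels

    def test_pssm_rows_are_log_emissions_when_noise_free(self):
        spec = _spec(emissions=_identity_emissions(), length_range=(20, 20))
        r = simulate_protein(spec, np.random.default_rng(1))
        k0 = "GHIEBTSL".index(r.labels[0])
        assert r.pssm[0, k0] == pytest.approx(0.0)  # log 1

    def test_fixed_seed_is_bit_identical(self):
        spec = default_spec(seed=9, n_proteins=1)
        a = simulate_protein(spec, np.random.default_rng(42))
        b = simulate_protein(spec, np.random.default_rng(42))
        assert a.sequence == b.sequence and a.labels == b.labels
        assert np.array_equal(a.pssm, b.pssm)

    def test_mean_run_length_matches_geometric(self):
        # p_stay = 0.9 -> geometric run length, mean 1/(1-0.9) = 10
        spec = _spec(transition=run_structured_transition(0.9))
        states = sample_states(spec, 10_000, np.random.default_rng(7))
        runs = np.diff(np.flatnonzero(np.r_[True, states[1:] != states[:-1], True]))
        assert np.mean(runs) == pytest.approx(10.0, rel=0.10)

    def test_run_length_distribution_is_geometric(self):
        # chi-square GOF of completed run lengths against Geometric(1 - p_stay)
        p_stay = 0.85
        spec = _spec(transition=run_structured_transition(p_stay))
        rng = np.random.default_rng(1234)
        runs = []
        while len(runs) < 100_000:
            states = sample_states(spec, 70_000, rng)
            change = np.flatnonzero(np.r_[True, states[1:] != states[:-1], True])
            runs.extend(np.diff(change)[1:-1])  # drop censored first/last runs
        runs = np.asarray(runs[:100_000])
        kmax = 40
        observed = np.bincount(np.minimum(runs, kmax), minlength=kmax + 1)[1:]
        p = 1.0 - p_stay
        probs = p * p_stay ** np.arange(0, kmax)
        probs[-1] = p_stay ** (kmax - 1)  # tail lump
        chi2 = stats.chisquare(observed, probs * len(runs))
        assert chi2.pvalue > 0.01


class TestDatasetSplits:
    def test_fraction_arithmetic(self):
        ds = simulate_dataset(default_spec(seed=1, n_proteins=10), (0.8, 0.1, 0.1))
        assert (len(ds.train), len(ds.valid), len(ds.test)) == (8, 1, 1)

    def test_ids_disjoint_and_seed_reproducible(self):
        spec = default_spec(seed=2, n_proteins=12)
        a = simulate_dataset(spec)
        b = simulate_dataset(spec)
        ids = [r.id for part in (a.train, a.valid, a.test) for r in part]
        assert len(set(ids)) == len(ids) == 12
        assert [r.id for r in a.train] == [r.id for r in b.train]
        assert all(x.labels == y.labels for x, y in zip(a.train, b.train))

    def test_different_seeds_differ(self):
        a = simulate_dataset(default_spec(seed=3, n_proteins=12))
        b = simulate_dataset(default_spec(seed=4, n_proteins=12))
        assert any(x.labels != y.labels for x, y in zip(a.train, b.train))

    def test_empty_split_is_configuration_error(self):
        with pytest.raises(ValueError, match="empty split"):
            simulate_dataset(default_spec(seed=1, n_proteins=5), (0.9, 0.05, 0.05))


class TestPosteriorDecode:
    def test_matches_exhaustive_path_enumeration(self):
        spec = default_spec(seed=6, n_proteins=1)
        rng = np.random.default_rng(0)
        for n in (1, 3, 5):
            r = simulate_protein(
                _spec(emissions=spec.emissions, transition=spec.transition,
                      initial=spec.initial, length_range=(n, n) if n >= 2 else (2, 2)),
                rng)
            seq = r.sequence[:n]
            obs = [AA_ALPHABET.index(c) for c in seq]
            r.sequence, r.pssm, r.labels = seq, r.pssm[:n], r.labels[:n]
            _, post = posterior_decode(spec, r)
            ref = brute_force_posteriors(spec.initial, spec.transition,
                                         spec.emissions, obs)
            assert np.allclose(post, ref, atol=1e-9)
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_hmmlearn_smoothing(self):
        hmm = pytest.importorskip("hmmlearn.hmm")
        spec = default_spec(seed=8, n_proteins=1)
        r = simulate_protein(spec, np.random.default_rng(2))
        m = hmm.CategoricalHMM(n_components=8, n_features=N_AA)
        m.startprob_, m.transmat_, m.emissionprob_ = (
            spec.initial, spec.transition, spec.emissions)
        obs = np.array([[AA_ALPHABET.index(c)] for c in r.sequence])
        ref = m.predict_proba(obs)
        _, post = posterior_decode(spec, r)
        assert np.allclose(post, ref, atol=1e-9)

    def test_deterministic_emissions_decode_exactly(self):
        spec = _spec(emissions=_identity_emissions(), length_range=(30, 30))
        r = simulate_protein(spec, np.random.default_rng(3))
        decoded, _ = posterior_decode(spec, r)
        assert decoded == r.labels

    def test_uniform_emissions_ignore_the_sequence(self):
        spec = _spec(length_range=(12, 12))  # uniform emissions
        r1 = simulate_protein(spec, np.random.default_rng(4))
        r2 = simulate_protein(spec, np.random.default_rng(5))
        n = min(len(r1), len(r2))
        r1.sequence, r1.pssm = r1.sequence[:n], r1.pssm[:n]
        r1.labels = r1.labels[:n]
        r2.sequence, r2.pssm = r2.sequence[:n], r2.pssm[:n]
        r2.labels = r2.labels[:n]
        _, p1 = posterior_decode(spec, r1)
        _, p2 = posterior_decode(spec, r2)
        assert np.allclose(p1, p2, atol=1e-12)


class TestBayesQ8:
    def test_deterministic_emissions_reach_one(self):
        spec = _spec(emissions=_identity_emissions(), length_range=(20, 30),
                     n_proteins=3)
        rng = np.random.default_rng(0)
        recs = [simulate_protein(spec, rng, f"r{i}") for i in range(3)]
        assert bayes_q8(spec, recs) == 1.0

    def test_no_signal_matches_chance(self):
        # uniform chain + uniform emissions: decoding cannot beat 1/8
        T = np.full((N_STATES, N_STATES), 1.0 / N_STATES)
        spec = _spec(transition=T, initial=np.full(N_STATES, 1.0 / N_STATES),
                     length_range=(100, 100))
        rng = np.random.default_rng(11)
        recs = [simulate_protein(spec, rng, f"r{i}") for i in range(100)]
        assert bayes_q8(spec, recs) == pytest.approx(1.0 / 8.0, abs=0.02)

    def test_sharper_emissions_never_hurt(self):
        rng_e = np.random.default_rng(21)
        flat = rng_e.dirichlet(np.full(N_AA, 5.0), size=N_STATES)
        spec_flat = _spec(emissions=flat, length_range=(80, 80), seed=1)
        spec_sharp = strong_signal_spec(seed=1)
        spec_sharp.length_range = (80, 80)
        rng = np.random.default_rng(5)
        flat_recs = [simulate_protein(spec_flat, rng, f"f{i}") for i in range(40)]
        sharp_recs = [simulate_protein(spec_sharp, rng, f"s{i}") for i in range(40)]
        assert bayes_q8(spec_sharp, sharp_recs) > bayes_q8(spec_flat, flat_recs)

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError):
            bayes_q8(default_spec(), [])
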