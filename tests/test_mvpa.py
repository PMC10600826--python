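import hashlib

import numpy as np
import pytest

from rlmvpa._errors import InputError, TrainingError
from rlmvpa.mvpa import (
    DecoderConfig,
    RewardDecoder,
    center_rows,
    decoding_report,
    distances_to_frame,
    loso_decode,
    results_to_frame,
    train_reward_decoder,
)
from rlmvpa.synthetic_data import CohortConfig, NeuralSession, generate_cohort


class TestCenterRows:
    def test_arithmetic(self):
        out = center_rows(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(out, [[-1.0, 0.0, 1.0]])

    def test_idempotent(self, rng):
        m = center_rows(rng.normal(size=(20, 10)))
        assert np.allclose(center_rows(m), m)

    def test_row_means_vanish(self, rng):
        m = center_rows(rng.normal(size=(90, 200)))
        assert np.all(np.abs(m.mean(axis=1)) < 1e-12)

    def test_errors(self):
        with pytest.raises(InputError):
            center_rows(np.empty((0, 5)))
        with pytest.raises(InputError):
            center_rows(np.ones((5, 1)))


def _toy_sessions(n_subjects=4, n_trials=40, n_voxels=30, snr=3.0, noise=0.5, seed=0,
                  kappa=1.0):
    rng = np.random.default_rng(seed)
    w = rng.normal(size=n_voxels)
    w /= np.linalg.norm(w)
    sessions = {}
    for s in range(n_subjects):
        win = rng.random(n_trials) < 0.5
        z = np.where(win, 1.0, -1.0)
        v = rng.uniform(-0.5, 1.0, size=n_trials)
        sessions[s] = NeuralSession(
            subject=s,
            network=0,
            outcome=snr * z[:, None] * w[None, :] + noise * rng.normal(size=(n_trials, n_voxels)),
            choice=kappa * v[:, None] * w[None, :] + noise * rng.normal(size=(n_trials, n_voxels)),
            win=win,
            kappa=kappa,
            noise_sd=noise,
        )
        sessions[s].v = v
    return sessions, w


class TestTrainRewardDecoder:
    def test_separable_perfect_training_accuracy(self, rng):
        sessions, _ = _toy_sessions(noise=1e-6)
        X = np.vstack([s.outcome for s in sessions.values()])
        y = np.concatenate([s.win for s in sessions.values()])
        dec = train_reward_decoder(X, y.astype(int))
        assert np.mean((dec.decision(X) > 0) == y) == 1.0

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(TrainingError):
            train_reward_decoder(X, np.ones(10, dtype=int))

    def test_stacking_matches_manual(self):
        sessions, _ = _toy_sessions()
        mats = [s.outcome for s in sessions.values()]
        labels = [s.win.astype(int) for s in sessions.values()]
        a = train_reward_decoder(mats, labels)
        b = train_reward_decoder(np.vstack(mats), np.concatenate(labels))
        probe = np.vstack(mats)[:5]
        assert np.allclose(a.decision(probe), b.decision(probe))


class TestLosoDecode:
    def test_needs_three_subjects(self):
        sessions, _ = _toy_sessions(n_subjects=2)
        with pytest.raises(InputError):
            loso_decode(sessions)

    def test_noiseless_perfect(self):
        sessions, _ = _toy_sessions(n_subjects=3, noise=1e-6)
        for r in loso_decode(sessions):
            assert r.accuracy == 1.0

    def test_accuracy_is_mean_of_rates(self):
        sessions, _ = _toy_sessions(snr=1.0, noise=1.5)
        for r in loso_decode(sessions):
            assert r.accuracy == (r.sensitivity + r.specificity) / 2.0

    def test_matches_naive_decoder_path(self):
        # precomputed-Gram fast path vs per-fold RewardDecoder refit
        sessions, _ = _toy_sessions(seed=3)
        X = np.vstack([center_rows(sessions[s].outcome) for s in sorted(sessions)])
        gamma = 1.0 / (X.shape[1] * X.var())
        cfg = DecoderConfig(gamma=gamma)
        results = loso_decode(sessions, cfg)
        for held_out in sorted(sessions):
            train = [s for s in sorted(sessions) if s != held_out]
            dec = train_reward_decoder(
                [sessions[s].outcome for s in train],
                [sessions[s].win.astype(int) for s in train],
                cfg,
            )
            d = dec.decision(sessions[held_out].choice)
            got = next(r for r in results if r.subject == held_out)
            assert np.allclose(got.distances, d, atol=1e-4)

    def test_distances_track_value_when_coupled(self):
        sessions, w = _toy_sessions(n_subjects=5, kappa=2.0, noise=0.5, seed=4)
        results = loso_decode(sessions)
        cors = [
            np.corrcoef(r.distances, sessions[r.subject].v)[0, 1] for r in results
        ]
        assert np.mean(cors) > 0.5

    def test_row_offset_invariance(self):
        sessions, _ = _toy_sessions(seed=5)
        base = loso_decode(sessions)
        shifted = {
            s: NeuralSession(
                subject=sess.subject, network=0, outcome=sess.outcome,
                choice=sess.choice + 7.5, win=sess.win, kappa=sess.kappa,
                noise_sd=sess.noise_sd,
            )
            for s, sess in sessions.items()
        }
        for a, b in zip(base, loso_decode(shifted)):
            assert np.allclose(a.distances, b.distances, atol=1e-6)

    def test_heldout_data_not_in_own_training_stack(self):
        # the train-set for fold s must be invariant to subject s's own data
        sessions, _ = _toy_sessions(seed=6)
        held_out = 0

        def train_hash(sess_map):
            X = np.vstack(
                [center_rows(sess_map[s].outcome) for s in sorted(sess_map) if s != held_out]
            )
            return hashlib.sha256(X.tobytes()).hexdigest()

        before = train_hash(sessions)
        zeroed = dict(sessions)
        zeroed[held_out] = NeuralSession(
            subject=held_out, network=0,
            outcome=np.zeros_like(sessions[held_out].outcome),
            choice=np.zeros_like(sessions[held_out].choice),
            win=sessions[held_out].win, kappa=0.0, noise_sd=1.0,
        )
        assert train_hash(zeroed) == before

    def test_single_class_heldout_recorded_missing(self):
        sessions, _ = _toy_sessions(n_subjects=4, seed=7)
        s0 = sessions[0]
        sessions[0] = NeuralSession(
            subject=0, network=0, outcome=s0.outcome, choice=s0.choice,
            win=np.ones_like(s0.win, dtype=bool), kappa=s0.kappa, noise_sd=s0.noise_sd,
        )
        r = next(x for x in loso_decode(sessions) if x.subject == 0)
        assert np.isnan(r.specificity)
        assert np.isnan(r.accuracy)

    def test_snr_ladder_monotone(self):
        cfg_base = dict(n_subjects=6, n_trials=30, n_voxels=30, noise=1.0)
        means = []
        for snr in (0.3, 1.0, 3.0):
            accs = []
            for seed in range(3):
                sessions, _ = _toy_sessions(snr=snr, seed=seed, **cfg_base)
                accs.append(results_to_frame(loso_decode(sessions))["accuracy"].mean())
            means.append(np.mean(accs))
        assert means[1] >= means[0] - 0.05
        assert means[2] >= means[1] - 0.05


class TestDecodingReport:
    def test_row_count_and_flags(self, small_cohort):
        results = []
        for n in range(small_cohort.config.n_networks):
            results.extend(loso_decode(small_cohort.network_sessions(n)))
        report = decoding_report(results, seed=0)
        assert len(report) == small_cohort.config.n_networks
        assert report["above_chance"].all()  # default SNR decodes well
        assert (report["mean_accuracy"] > 0.5).all()

    def test_chance_input_not_flagged(self, rng):
        sessions, _ = _toy_sessions(n_subjects=8, snr=0.0, noise=1.0, seed=8)
        report = decoding_report(loso_decode(sessions), seed=1)
        assert not report["above_chance"].any()

    def test_distances_frame_shape(self):
        sessions, _ = _toy_sessions()
        results = loso_decode(sessions)
        df = distances_to_frame(results)
        assert len(df) == sum(len(r.distances) for r in results)
        assert list(df.columns) == ["subject", "network", "trial", "distance"]
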