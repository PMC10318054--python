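import numpy as np
import pytest

from pwavekit.core import Hypnogram
from pwavekit.photometry import compute_dff
from pwavekit.synth import (
    GroundTruth,
    SimConfig,
    default_transition_matrix,
    simulate_hypnogram,
    simulate_session,
    stationary_distribution,
    synth_laser,
    synth_lfp,
    synth_photometry,
)
from pwavekit.core import STATES


def markov_fraction_variance(P: np.ndarray, pi: np.ndarray, state: int, n: int) -> float:
    """Asymptotic variance of the occupancy fraction of ``state`` for an
    ergodic chain, via the fundamental matrix (exact, no series truncation):
    sigma^2 = pi_s (1 - pi_s) + 2 pi_s (M_ss - 1),
    M = (I - P + 1 pi^T)^{-1}."""
    k = P.shape[0]
    M = np.linalg.inv(np.eye(k) - P + np.outer(np.ones(k), pi))
    pi_s = pi[state]
    var = pi_s * (1 - pi_s) + 2 * pi_s * (M[state, state] - 1)
    return var / n


class TestHypnogramGeneration:
    def test_identity_matrix_keeps_initial_state(self):
        cfg = SimConfig(duration_s=300.0, transition_matrix=np.eye(4), initial_state="W")
        with pytest.warns(UserWarning, match="REM is unreachable"):
            cfg.validate()
        hyp = simulate_hypnogram(cfg)
        assert np.all(hyp.labels == "W")

    def test_zero_is_to_rem_probability_means_no_rem(self):
        m = default_transition_matrix().copy()
        m[2, 3] = 0.0
        m[2] /= m[2].sum()
        with pytest.warns(UserWarning, match="REM is unreachable"):
            cfg = SimConfig(duration_s=3600.0, transition_matrix=m, seed=3)
        hyp = simulate_hypnogram(cfg)
        assert not np.any(hyp.labels == "R")

    def test_direct_nrem_to_rem_rejected(self):
        m = default_transition_matrix().copy()
        m[1, 3] = 0.05
        m[1] /= m[1].sum()
        with pytest.raises(ValueError, match="only via IS"):
            SimConfig(transition_matrix=m)

    def test_nonstochastic_matrix_rejected(self):
        m = default_transition_matrix().copy()
        m[0, 0] += 0.2
        with pytest.raises(ValueError, match="summing to 1"):
            SimConfig(transition_matrix=m)

    def test_rem_always_preceded_by_is(self):
        cfg = SimConfig(duration_s=10_800.0, seed=11)
        labels = simulate_hypnogram(cfg).labels
        onsets = np.flatnonzero((labels[1:] == "R") & (labels[:-1] != "R")) + 1
        assert onsets.size > 0
        assert all(labels[i - 1] == "I" for i in onsets)

    def test_fractions_match_stationary_distribution(self):
        # mean over 10 independent 3 h chains vs the eigen-decomposition
        # stationary distribution; the SE uses the Markov-CLT variance from
        # the fundamental matrix (epochs are strongly autocorrelated, so the
        # naive binomial SE would be far too tight)
        n_chains = 10
        fracs = []
        cfg = None
        for seed in range(n_chains):
            cfg = SimConfig(duration_s=10_800.0, seed=seed)
            hyp = simulate_hypnogram(cfg)
            fracs.append([hyp.fractions()[s] for s in STATES])
        fracs = np.mean(fracs, axis=0)
        P = cfg.transition_matrix
        pi = stationary_distribution(P)
        n = cfg.n_epochs
        for i, s in enumerate(STATES):
            se = np.sqrt(markov_fraction_variance(P, pi, i, n) / n_chains)
            assert abs(fracs[i] - pi[i]) <= 3 * se, s

    def test_min_epochs_enforced(self):
        cfg = SimConfig(
            duration_s=7200.0, seed=5,
            min_epochs={"W": 6, "N": 16, "I": 6, "R": 16},
        )
        hyp = simulate_hypnogram(cfg)
        eps = hyp.episodes[:-1]  # final episode may be cut by session end
        mins = {"W": 15.0, "N": 40.0, "I": 15.0, "R": 40.0}
        assert all(e.duration_s >= mins[e.state] for e in eps)

    def test_determinism(self):
        cfg = SimConfig(duration_s=600.0, seed=42)
        assert np.array_equal(
            simulate_hypnogram(cfg).labels, simulate_hypnogram(cfg).labels
        )


class TestLFPSynthesis:
    def test_zero_rates_give_empty_truth(self):
        cfg = SimConfig(
            duration_s=120.0, seed=0,
            pwave_rates={s: 0.0 for s in STATES},
        )
        hyp = simulate_hypnogram(cfg)
        ch, gt = synth_lfp(hyp, cfg)
        assert gt.pwave_times.size == 0
        assert abs(ch["lfp_primary"]).max() < 10 * cfg.lfp_noise_sd_mv

    def test_degenerate_von_mises_pins_phases(self):
        from pwavekit.events import theta_phase_of_events
        from pwavekit.synth import synth_eeg_emg

        cfg = SimConfig(
            duration_s=600.0, seed=2, theta_coupling_kappa=400.0,
            transition_matrix=np.array(
                [[0, 0, 1, 0], [0, 0, 1, 0], [0, 0, 0.01, 0.99], [0, 0, 0.01, 0.99]]
            ),
            initial_state="I",
        )
        hyp = simulate_hypnogram(cfg)
        ch, aux = synth_eeg_emg(hyp, cfg)
        _, gt = synth_lfp(hyp, cfg, eeg_aux=aux)
        phases = theta_phase_of_events(
            ch["eeg_parietal"], cfg.rate_ephys_hz, gt.pwave_times,
            hyp.episodes_of("R"), min_episode_s=30.0,
        )
        assert phases.size > 50
        # circular mean at the configured preferred phase (rising, -pi/2)
        mean_phase = np.angle(np.exp(1j * phases).mean())
        assert abs(mean_phase - (-np.pi / 2)) < 0.25
        # strong concentration
        assert np.abs(np.exp(1j * phases).mean()) > 0.8

    def test_truth_times_sorted_and_in_range(self, short_session):
        _, _, gt = short_session
        assert np.all(np.diff(gt.pwave_times) > 0)
        assert gt.pwave_times[0] > 0 and gt.pwave_times[-1] < gt.hypnogram.duration_s

    def test_evoked_events_follow_their_pulse(self, default_session):
        _, _, gt = default_session
        ev = gt.pwave_times[gt.pwave_provenance == "laser_triggered"]
        assert ev.size > 0
        onsets = gt.laser.onsets_s[gt.evoked_flags]
        # each evoked event lies within (0, 100 ms] of some successful pulse
        for t in ev:
            lat = t - onsets[onsets <= t]
            assert lat.size and lat.min() <= 0.1 + 1e-9

    def test_evoked_success_rates_match_config(self):
        cfg = SimConfig(duration_s=7200.0, seed=13, laser_mode="brief_pulse")
        _, gt = simulate_session(cfg)
        states = gt.hypnogram.state_at(gt.laser.onsets_s)
        for s in ("N", "W"):
            sel = states == s
            n = sel.sum()
            if n < 20:
                continue
            p = cfg.evoked_success_by_state[s]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(gt.evoked_flags[sel].mean() - p) <= 3.5 * se, s


class TestPhotometrySynthesis:
    def test_noiseless_state_baseline_recovered_after_dff(self):
        # with zero transients and zero noise the recovered dF/F reproduces
        # the state-baseline profile up to the scale 1/(1 + mean calcium)
        # that the isosbestic regression absorbs (~3% here): state contrasts
        # agree to 10% relative and the traces are near-perfectly correlated
        cfg = SimConfig(
            duration_s=400.0, seed=0, motion_noise_sd=0.0,
            transient_amp_dff=0.0, bleach_tau_s=500.0,
        )
        labels = (["N"] * 16 + ["R"] * 16 + ["I"] * 8) * 4
        hyp = Hypnogram(labels, 2.5)
        ch, calcium = synth_photometry(hyp, np.empty(0), cfg)
        tr = compute_dff(ch["photo_465"], ch["photo_405"], cfg.rate_photo_hz)
        rate = cfg.rate_photo_hz
        edge = int(10 * rate)
        means = {}
        for s in "NIR":
            mask = np.zeros(tr.dff.size, bool)
            for e in hyp.episodes_of(s):
                mask[int((e.onset_s + 3) * rate) : int((e.offset_s - 3) * rate)] = True
            mask[:edge] = False
            mask[-edge:] = False
            means[s] = (tr.dff[mask].mean(), calcium[mask].mean())
        for s in "IR":
            got = means[s][0] - means["N"][0]
            want = means[s][1] - means["N"][1]
            assert got == pytest.approx(want, rel=0.10), s
        assert np.corrcoef(tr.dff[edge:-edge], calcium[edge:-edge])[0, 1] > 0.98

    def test_shared_noise_only_cancels(self):
        cfg = SimConfig(
            duration_s=200.0, seed=1, transient_amp_dff=0.0,
            photo_baseline_dff={s: 0.0 for s in STATES},
        )
        hyp = Hypnogram(["N"] * 80, 2.5)
        ch, _ = synth_photometry(hyp, np.empty(0), cfg)
        tr = compute_dff(ch["photo_465"], ch["photo_405"], cfg.rate_photo_hz)
        assert np.abs(tr.dff).max() < 1e-6

    def test_event_triggered_peak_near_half_second(self, short_session):
        from pwavekit.photometry import event_triggered

        cfg, rec, gt = short_session
        tr = compute_dff(
            rec["photo_465"].data, rec["photo_405"].data, cfg.rate_photo_hz
        )
        rem = gt.hypnogram.state_at(gt.pwave_times) == "R"
        _, taxis, mean_tr = event_triggered(
            tr.dff, cfg.rate_photo_hz, gt.pwave_times[rem], window_s=(-2, 3)
        )
        assert 0.3 <= taxis[np.argmax(mean_tr)] <= 0.7

    def test_nonpositive_bleach_tau_rejected(self):
        with pytest.raises(ValueError, match="bleach_tau_s"):
            SimConfig(bleach_tau_s=-1.0)


class TestLaserProtocols:
    def test_open_loop_train_arithmetic(self):
        cfg = SimConfig(duration_s=1800.0, seed=4, laser_mode="open_loop")
        hyp = simulate_hypnogram(cfg)
        laser = synth_laser(hyp, cfg)
        n_trains = len(np.unique(laser.train_ids))
        assert 1 <= n_trains <= 2
        for tid in np.unique(laser.train_ids):
            sel = laser.train_ids == tid
            assert sel.sum() == 1200
            assert np.allclose(laser.durations_ms[sel], 10.0)
            assert np.allclose(np.diff(laser.onsets_s[sel]), 0.1)

    def test_closed_loop_without_rem_is_empty(self):
        cfg = SimConfig(
            duration_s=300.0, transition_matrix=np.eye(4),
            initial_state="N", laser_mode="closed_loop",
        )
        with pytest.warns(UserWarning):
            cfg.validate()
        hyp = simulate_hypnogram(cfg)
        assert len(synth_laser(hyp, cfg)) == 0

    def test_brief_pulse_count_matches_renewal_process(self):
        cfg = SimConfig(duration_s=7200.0, seed=8, laser_mode="brief_pulse")
        hyp = simulate_hypnogram(cfg)
        laser = synth_laser(hyp, cfg)
        # renewal process with U(10, 60) gaps: mean 35 s, var 2500/12
        mean_gap, var_gap = 35.0, 2500.0 / 12
        expect = 7200.0 / mean_gap
        sd = np.sqrt(7200.0 * var_gap / mean_gap**3)
        assert abs(len(laser) - expect) <= 3 * sd
        assert np.all((laser.durations_ms >= 10.0) & (laser.durations_ms <= 20.0))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="laser_mode"):
            SimConfig(laser_mode="strobe")


class TestSessionLevel:
    def test_bit_identical_under_same_seed(self):
        cfg = SimConfig(duration_s=300.0, seed=17, laser_mode="brief_pulse")
        rec1, gt1 = simulate_session(cfg)
        rec2, gt2 = simulate_session(cfg)
        for name in rec1.channels:
            assert np.array_equal(rec1[name].data, rec2[name].data), name
        assert np.array_equal(gt1.pwave_times, gt2.pwave_times)
        assert np.array_equal(gt1.laser.onsets_s, gt2.laser.onsets_s)

    def test_seed_changes_output(self):
        rec1, _ = simulate_session(SimConfig(duration_s=300.0, seed=1))
        rec2, _ = simulate_session(SimConfig(duration_s=300.0, seed=2))
        assert not np.array_equal(rec1["emg"].data, rec2["emg"].data)

    def test_state_band_power_ordering(self, short_session):
        from pwavekit.spectral import band, band_power, spectrogram, theta_delta_ratio

        cfg, rec, gt = short_session
        spec = spectrogram(rec["eeg_parietal"].data, cfg.rate_ephys_hz, preset="hypnogram")
        td = theta_delta_ratio(spec)
        delta = band_power(spec, band("delta"))
        n = min(len(gt.hypnogram), td.size)
        labels = gt.hypnogram.labels[:n]
        assert np.median(td[labels == "R"]) > np.median(td[labels == "N"])
        assert np.median(delta[labels == "N"]) == max(
            np.median(delta[labels == s]) for s in "WNIR" if (labels == s).any()
        )
        from pwavekit.spectral import emg_amplitude

        _, amp = emg_amplitude(rec["emg"].data, cfg.rate_ephys_hz, "state")
        amp = amp[:n]
        assert np.median(amp[labels == "W"]) > 2 * np.median(amp[labels != "W"])

    def test_per_state_rates_conserved(self, default_session):
        from pwavekit.pwave import PWaveSet, rate_by_state

        cfg, rec, gt = default_session
        spont = gt.pwave_times[gt.pwave_provenance == "spontaneous"]
        ps = PWaveSet.from_arrays(spont, np.ones(spont.size), np.full(spont.size, 30.0))
        rates = rate_by_state(ps, gt.hypnogram)
        lo, hi = cfg.cluster_extra_range
        mean_extra = (lo + hi) / 2
        # clustered companions make counts over-dispersed relative to Poisson
        overdisp = (1 - cfg.cluster_prob) + cfg.cluster_prob * np.mean(
            [(1 + k) ** 2 for k in range(lo, hi + 1)]
        )
        base_factor = 1 + cfg.cluster_prob * mean_extra
        for s in STATES:
            T = (gt.hypnogram.labels == s).sum() * cfg.epoch_s
            lam = cfg.pwave_rates[s]
            if T < 300:
                continue
            se = np.sqrt(lam / base_factor * overdisp / T)
            assert abs(rates[s] - lam) <= 3 * se + 0.01, s
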