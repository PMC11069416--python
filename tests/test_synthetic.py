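"""Synthetic dyadic session generator: determinism, spectral content,
forward/inverse consistency and coupling-to-coherence behaviour."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from nirsync.coherence import band_by_name, band_average, extract_trial, wtc
from nirsync.preprocess import (
    intensity_to_od,
    od_to_concentration,
    preprocess_to_activation,
)
from nirsync.synthetic import (
    SimulationConfig,
    _nominal_channel_rois,
    inject_motion_artifacts,
    simulate_cohort,
    simulate_session,
)

FS = 8.33


def _roi_channel(config, roi):
    hits = [
        ch for ch, hit in _nominal_channel_rois(config).items()
        if hit is not None and hit[0] == roi and hit[1] > 0.99
    ]
    return hits[0]


class TestConfigValidation:
    def test_rejects_unknown_band(self):
        with pytest.raises(ValueError, match="unknown band"):
            SimulationConfig(coupling={"video1": {"theta": 0.5}})

    def test_rejects_unknown_phase_and_roi(self):
        with pytest.raises(ValueError, match="unknown phase"):
            SimulationConfig(coupling={"rest": {"high": 0.5}})
        with pytest.raises(ValueError, match="ROI"):
            SimulationConfig(coupling={"video1": {"high": {"TPJ_X": 0.5}}})

    def test_rejects_out_of_range_coupling(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            SimulationConfig(coupling={"video1": {"high": 1.5}})

    def test_rejects_bad_rates(self):
        with pytest.raises(ValueError):
            SimulationConfig(fs=0)
        with pytest.raises(ValueError):
            SimulationConfig(phase_durations=(120.0, 0.0, 120.0))


class TestDeterminism:
    def test_session_bit_identical(self, small_config):
        s1, t1 = simulate_session(small_config, 1)
        s2, t2 = simulate_session(small_config, 1)
        for role in ("A", "B"):
            np.testing.assert_array_equal(s1.raw[role].values, s2.raw[role].values)
            np.testing.assert_array_equal(
                s1.geometry[role].optodes[["mni_x", "mni_y", "mni_z"]].to_numpy(),
                s2.geometry[role].optodes[["mni_x", "mni_y", "mni_z"]].to_numpy(),
            )
        assert t1.coupling == t2.coupling

    def test_cohort_meta_identical(self, small_config):
        m1 = simulate_cohort(small_config).meta
        m2 = simulate_cohort(small_config).meta
        assert m1.equals(m2)


class TestCohort:
    def test_counterbalance_four_dyads(self, small_config):
        meta = simulate_cohort(small_config).meta
        counts = meta["video_order"].value_counts()
        assert sorted(counts) == [2, 2]

    def test_counterbalance_27_dyads_splits_14_13(self):
        cfg = SimulationConfig(n_dyads=27, phase_durations=(5.0, 5.0, 5.0), seed=0)
        # only the metadata matters here; use the cheapest valid phases
        orders = ["order0" if i % 2 == 0 else "order1" for i in range(27)]
        meta_counts = {o: orders.count(o) for o in set(orders)}
        assert sorted(meta_counts.values()) == [13, 14]
        # and the generator follows the same alternation
        sess, _ = simulate_session(cfg, 0)
        sess2, _ = simulate_session(cfg, 1)
        assert sess.meta.video_order != sess2.meta.video_order

    def test_events_mark_three_phases(self, small_session):
        session, _ = small_session
        ev = session.events
        assert list(ev["phase_label"]) == ["video1", "conversation", "video2"]
        assert ev["onset_s"].iloc[0] == 0.0
        assert ev["onset_s"].iloc[2] == pytest.approx(140.0)

    def test_needs_two_dyads(self, small_config):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_cohort(dataclasses.replace(small_config, n_dyads=1))


class TestSpectralContent:
    def test_heartbeat_peak_in_raw_intensity(self, small_session):
        session, _ = small_session
        raw = session.raw["A"]
        cfg_freq = 1.1
        for c in (0, 10, 25):
            x = raw.values[c, :, 0]
            x = x / x.mean() - 1.0
            f, psd = sps.welch(x, fs=FS, nperseg=1024)
            sel = (f > 0.6) & (f < 2.0)
            peak = f[sel][np.argmax(psd[sel])]
            assert abs(peak - cfg_freq) < 0.2


class TestForwardInverse:
    def test_mbll_roundtrip_through_intensity(self, clean_config):
        # noise, drift, heartbeat and artifacts disabled: OD -> MBLL recovers
        # the latent concentrations exactly, up to the temporal-mean offset
        session, _ = simulate_session(clean_config, 0)
        raw = session.raw["A"]
        conc = od_to_concentration(intensity_to_od(raw))
        # reconstruct the latent HbO for an ROI channel from a second run
        # of the generator (determinism) via the stored raw of participant A
        hbo = conc.hbo - conc.hbo.mean(axis=1, keepdims=True)
        hbr = conc.hbr - conc.hbr.mean(axis=1, keepdims=True)
        # forward-map back to OD and compare against measured OD
        od = intensity_to_od(raw)
        from nirsync.preprocess import mbll_matrix

        A = mbll_matrix()
        od_hat = np.einsum("wk,kct->ctw", A, np.stack([hbo, hbr]))
        od_c = od.values - od.values.mean(axis=1, keepdims=True)
        scale = np.abs(od_c).max()
        assert np.abs(od_hat - od_c).max() < 1e-6 * scale


class TestCouplingToCoherence:
    def test_zero_coupling_matches_independent_participants(self):
        # with no dyad coupling and no stimulus, within-dyad coherence is
        # indistinguishable from across-dyad coherence
        cfg = SimulationConfig(
            n_dyads=4,
            phase_durations=(120.0, 20.0, 120.0),
            stimulus_coupling={},
            seed=31,
        )
        ch = _roi_channel(cfg, "TPJ_R")
        within, across = [], []
        acts = []
        for d in range(4):
            session, _ = simulate_session(cfg, d)
            acts.append({r: preprocess_to_activation(session.raw[r]) for r in "AB"})
            ev = session.events
        band = band_by_name("medium")
        for d in range(4):
            a = extract_trial(acts[d]["A"].channel(ch), ev, "video1", FS)
            b = extract_trial(acts[d]["B"].channel(ch), ev, "video1", FS)
            within.append(band_average(wtc(a, b, FS), band).value)
        for d in range(3):
            a = extract_trial(acts[d]["A"].channel(ch), ev, "video1", FS)
            b = extract_trial(acts[d + 1]["B"].channel(ch), ev, "video1", FS)
            across.append(band_average(wtc(a, b, FS), band).value)
        # same null distribution: no gross separation between the two sets
        assert abs(np.mean(within) - np.mean(across)) < 3 * np.std(within + across, ddof=1)

    def test_full_coupling_identity_in_band(self, clean_config):
        # coupling 1 everywhere with all noise off: the two participants'
        # ROI signals coincide and in-band coherence is ~1
        bands = {b: 1.0 for b in ("high", "medium", "low")}
        cfg = dataclasses.replace(
            clean_config,
            coupling={ph: bands for ph in ("video1", "conversation", "video2")},
        )
        session, _ = simulate_session(cfg, 0)
        ch = _roi_channel(cfg, "TPJ_R")
        acts = {r: preprocess_to_activation(session.raw[r]) for r in "AB"}
        a = extract_trial(acts["A"].channel(ch), session.events, "video1", FS)
        b = extract_trial(acts["B"].channel(ch), session.events, "video1", FS)
        np.testing.assert_allclose(a, b, atol=1e-9 * np.abs(a).max())
        spec = wtc(a, b, FS)
        assert spec.r2[spec.in_coi_mask()].min() > 0.99
        assert band_average(spec, band_by_name("high")).value > 0.99

    def test_band_coherence_monotone_in_coupling(self):
        """Mean medium-band coherence is non-decreasing over c in
        {0, 0.3, 0.6, 0.9} (30 paired seeds per level, common random
        numbers) and strictly higher at 0.9 than at 0.

        Expected coherence scales as c^4, so adjacent low-coupling gaps are
        tiny; non-decrease is asserted on paired differences within two
        standard errors."""
        levels = (0.0, 0.3, 0.6, 0.9)
        n_seeds = 30
        vals = {c: [] for c in levels}
        for c in levels:
            for seed in range(n_seeds):
                cfg = SimulationConfig(
                    n_dyads=2,
                    phase_durations=(120.0, 10.0, 10.0),
                    n_channels_per_hemisphere=7,
                    coupling={"video1": {"medium": c}},
                    seed=500 + seed,
                )
                session, _ = simulate_session(cfg, 0)
                ch = _roi_channel(cfg, "TPJ_R")
                acts = {r: preprocess_to_activation(session.raw[r]) for r in "AB"}
                a = extract_trial(acts["A"].channel(ch), session.events, "video1", FS)
                b = extract_trial(acts["B"].channel(ch), session.events, "video1", FS)
                vals[c].append(band_average(wtc(a, b, FS), band_by_name("medium")).value)
        for c_lo, c_hi in zip(levels, levels[1:]):
            diff = np.asarray(vals[c_hi]) - np.asarray(vals[c_lo])
            se = diff.std(ddof=1) / np.sqrt(n_seeds)
            assert diff.mean() >= -2 * se, (c_lo, c_hi, diff.mean(), se)
        top = np.asarray(vals[0.9]) - np.asarray(vals[0.0])
        assert top.mean() > 2 * top.std(ddof=1) / np.sqrt(n_seeds)


class TestMotionArtifacts:
    def test_zero_rate_identity(self, rng):
        x = rng.standard_normal(500)
        out, events = inject_motion_artifacts(x, 0.0, seed=1, fs=FS)
        np.testing.assert_array_equal(out, x)
        assert events == []

    def test_poisson_event_count(self):
        # rate 6/min on a 120 s signal: expected 12 events per draw
        n = int(120 * FS)
        counts = []
        for seed in range(200):
            x = np.zeros(n)
            _, events = inject_motion_artifacts(x + 1.0, 6.0, seed=seed, fs=FS)
            counts.append(len(events))
        mean = np.mean(counts)
        se = np.sqrt(12.0 / 200)
        assert abs(mean - 12.0) < 3 * se

    def test_truth_list_bookkeeping(self, rng):
        x = rng.standard_normal(1000)
        out, events = inject_motion_artifacts(x, 2.0, seed=4, fs=FS)
        assert len(out) == len(x)
        for ev in events:
            assert 0 <= ev["sample"] < len(x)
            if ev["kind"] == "spike":
                assert abs(ev["amplitude_sd"]) >= 5.0
                assert ev["width_s"] * 6 < 2.0  # +/-3 SD support under 2 s
                # the corrupted series is visibly perturbed at the event
                assert abs(out[ev["sample"]] - x[ev["sample"]]) > 2 * x.std()

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            inject_motion_artifacts(rng.standard_normal(10), -1.0, seed=0)


class TestGroundTruth:
    def test_truth_records_coupling_and_artifacts(self, small_config):
        cfg = dataclasses.replace(
            small_config, coupling={"video2": {"high": {"TPJ_R": 0.7}}}
        )
        session, truth = simulate_session(cfg, 2)
        assert truth.coupling[("video2", "high", "TPJ_R")] == 0.7
        assert truth.coupling[("video1", "high", "TPJ_R")] == 0.0
        assert set(truth.artifacts) == {"A", "B"}
        n_events = sum(len(v) for v in truth.artifacts["A"].values())
        assert n_events > 0  # default artifact rate over a 160 s session
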