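"""ERP pipeline: re-referencing, filtering, epoching, rejection, amplitudes."""

import numpy as np
import pandas as pd
import pytest

import aslkit as ak
from aslkit.erp import (COMPONENTS, ContinuousEEG, ROIS,
                        window_sample_indices)
from aslkit.montage import BIOSEMI64, MASTOIDS


def small_eeg(data, channels=("Cz", "FCz", "Fz") + MASTOIDS, **kw):
    return ContinuousEEG(np.asarray(data, float), channels, **kw)


def _events_for(n_words, word_ms=900.0, start_ms=500.0):
    rows = []
    for i in range(n_words):
        rows.append(dict(onset_ms=start_ms + i * word_ms, event_kind="word_onset",
                         word_id=f"W{i % 2}", predictability="high" if i % 2 else "low",
                         block=1 + (2 * i) // n_words, token_index=i,
                         syllable_position=None, syllable=None,
                         chirp_interval_position=None))
    return pd.DataFrame(rows)


def test_rereference_shift_and_idempotence():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(5, 100))
    data[3] = 5.0  # M1
    data[4] = 5.0  # M2
    eeg = small_eeg(data)
    ref = ak.rereference_mastoids(eeg)
    assert np.allclose(ref.data[:3], data[:3] - 5.0)
    assert np.allclose(ref.data[3:], 0.0)
    again = ak.rereference_mastoids(ref)
    assert np.allclose(again.data, ref.data)
    # zero mastoids leave data untouched
    data2 = rng.normal(size=(5, 50))
    data2[3:] = 0.0
    assert np.allclose(ak.rereference_mastoids(small_eeg(data2)).data, data2)


def test_rereference_requires_mastoids():
    eeg = ContinuousEEG(np.zeros((2, 10)), ("Cz", "Fz"))
    with pytest.raises(ValueError, match="mastoid"):
        ak.rereference_mastoids(eeg)


def _probe_gain(freq, fs=512.0, seconds=30):
    """Amplitude gain at a probe frequency (projection, transient-immune)."""
    t = np.arange(int(seconds * fs)) / fs
    x = np.cos(2 * np.pi * freq * t)
    eeg = small_eeg(np.tile(x, (5, 1)), sfreq=fs)
    y = ak.bandpass(eeg).data[0]
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    a = 2 * np.mean(y[mid] * np.exp(-2j * np.pi * freq * t[mid]))
    return a


def test_bandpass_passes_10hz_with_zero_phase():
    a = _probe_gain(10.0)
    assert abs(a) == pytest.approx(1.0, abs=0.02)
    assert np.angle(a) == pytest.approx(0.0, abs=0.02)  # forward-backward


def test_bandpass_removes_dc_and_attenuates_line_noise():
    fs = 512.0
    dc = small_eeg(np.full((5, int(8 * fs)), 3.0), sfreq=fs)
    y = ak.bandpass(dc).data[0]
    mid = slice(len(y) // 4, 3 * len(y) // 4)
    assert np.abs(y[mid]).max() < 0.3  # 0.1 Hz highpass strips the offset
    assert abs(_probe_gain(60.0)) < 0.1   # >= 20 dB at 60 Hz
    assert abs(_probe_gain(50.0)) < 0.15  # 50 Hz line strongly attenuated


def test_bandpass_rejects_bad_cutoffs():
    eeg = small_eeg(np.zeros((5, 100)), sfreq=100.0)
    with pytest.raises(ValueError):
        ak.bandpass(eeg, 0.1, 60.0)  # above Nyquist


def test_epoching_counts_baseline_and_length():
    fs = 512.0
    ev = _events_for(8)
    n = int((0.5 + 8 * 0.9 + 1.5) * fs)
    data = np.full((5, n), 7.0)
    eeg = small_eeg(data, sfreq=fs)
    ep = ak.epoch_and_baseline(eeg, ev)
    assert ep.data.shape == (8, 5, 768)  # 1.5 s at 512 Hz
    assert np.allclose(ep.data, 0.0)  # constant channel nulled by baseline
    assert sorted(ep.labels["half"].unique()) == [1, 2]
    assert (ep.labels.groupby(["predictability", "half"]).size() == 2).all()


def test_epochs_near_edges_are_dropped():
    fs = 512.0
    ev = _events_for(4, start_ms=100.0)  # first onset has < 300 ms history
    n = int(4 * 0.9 * fs)  # last onset has < 1200 ms of future
    eeg = small_eeg(np.zeros((5, n)), sfreq=fs)
    with pytest.warns(UserWarning, match="dropped"):
        ep = ak.epoch_and_baseline(eeg, ev)
    assert ep.n_epochs == 2


def test_default_stream_epoch_counts(design, events):
    fs = 512.0
    n = int((0.5 + 480 * 0.9 + 1.5) * fs)
    eeg = ContinuousEEG(np.zeros((len(ROIS["central"].channels) + 2, n)),
                        ROIS["central"].channels + MASTOIDS, sfreq=fs,
                        events_offset_s=0.5)
    ep = ak.epoch_and_baseline(eeg, events)
    assert ep.n_epochs == 480
    cells = ep.labels.groupby(["predictability", "half"]).size()
    assert (cells == 120).all()


def test_rejection_threshold_and_oracle():
    rng = np.random.default_rng(1)
    data = rng.normal(scale=10, size=(20, 5, 100))
    data[3, 1, 50] = 150.0  # blink-sized deflection
    ep = ak.EpochSet(data, ("Cz", "FCz", "Fz") + MASTOIDS,
                     np.arange(100) / 512, _labels(20), 512.0)
    rej = ak.reject_artifacts(ep, 100.0)
    # oracle: brute-force max-abs scan over scalp channels
    oracle = np.abs(data[:, :3, :]).max(axis=(1, 2)) > 100.0
    assert np.array_equal(rej.rejected, oracle)
    assert rej.rejected[3]
    # all-zero epochs are all retained
    quiet = ak.EpochSet(np.zeros((4, 5, 50)), ("Cz", "FCz", "Fz") + MASTOIDS,
                        np.arange(50) / 512, _labels(4), 512.0)
    assert not ak.reject_artifacts(quiet, 100.0).rejected.any()


def test_rejection_monotone_in_threshold():
    rng = np.random.default_rng(2)
    data = rng.normal(scale=60, size=(50, 5, 64))
    ep = ak.EpochSet(data, ("Cz", "FCz", "Fz") + MASTOIDS,
                     np.arange(64) / 512, _labels(50), 512.0)
    last = 51
    for thr in (50, 100, 150, 200):
        n = ak.reject_artifacts(ep, thr).rejected.sum()
        assert n <= last
        last = n


def test_mastoid_amplitudes_do_not_reject():
    data = np.zeros((5, 5, 50))
    data[:, 3, :] = 500.0  # mastoid channel only
    ep = ak.EpochSet(data, ("Cz", "FCz", "Fz") + MASTOIDS,
                     np.arange(50) / 512, _labels(5), 512.0)
    assert not ak.reject_artifacts(ep, 100.0).rejected.any()


def _labels(n):
    return pd.DataFrame(dict(
        subject=["S1"] * n, group=["TLD"] * n, task=["implicit"] * n,
        predictability=["high", "low"] * (n // 2) + ["high"] * (n % 2),
        half=[1] * n, word_id=["W"] * n, block=[1] * n))


def _full_epochset(n_ep=8, value=None, rng=None):
    channels = BIOSEMI64 + MASTOIDS
    times = (np.arange(768) - 154) / 512.0
    if value is not None:
        data = np.full((n_ep, len(channels), 768), float(value))
    else:
        data = rng.normal(size=(n_ep, len(channels), 768))
    return ak.EpochSet(data, channels, times, _labels(n_ep), 512.0)


def test_window_sample_count_closed_interval():
    times = (np.arange(768) - 154) / 512.0
    idx = window_sample_indices(512.0, (80.0, 120.0), times)
    assert len(idx) == 21
    idx400 = window_sample_indices(512.0, (350.0, 450.0), times)
    assert len(idx400) == 51


def test_mean_amplitude_constant_and_oracle():
    ep = _full_epochset(4, value=-3.0)
    out = ak.mean_amplitude(ep, "N400", by=("task",))
    assert out["mean_amplitude_uv"].iloc[0] == pytest.approx(-3.0)
    # brute-force triple mean over epochs x ROI channels x window samples
    rng = np.random.default_rng(3)
    ep = _full_epochset(6, rng=rng)
    comp = COMPONENTS["N100"]
    got = ak.mean_amplitude(ep, comp, by=("task",))["mean_amplitude_uv"].iloc[0]
    ch_idx = [ep.channels.index(c) for c in comp.roi.channels]
    t_idx = window_sample_indices(512.0, comp.window_ms, ep.times)
    acc = []
    for e in range(6):
        for c in ch_idx:
            for t in t_idx:
                acc.append(ep.data[e, c, t])
    assert got == pytest.approx(np.mean(acc), rel=1e-12)


def test_mean_amplitude_empty_cell_flagged():
    ep = _full_epochset(4, value=1.0)
    ep.rejected[:] = True
    out = ak.mean_amplitude(ep, "N400", by=("task",))
    assert out["n_epochs_retained"].iloc[0] == 0
    assert np.isnan(out["mean_amplitude_uv"].iloc[0])


def test_pipeline_linearity(design, small_events):
    from aslkit.simulate import NoiseSpec, EffectMap, simulate_subject_eeg

    em = EffectMap.zero()
    for k in em.amplitudes:
        em.amplitudes[k] = -1.0
    eeg = simulate_subject_eeg(small_events, em, NoiseSpec(5.0, 1.0, 0, 0, 400, 1.0),
                               subject_seed=5, channels="roi")
    amp1 = ak.subject_amplitudes(eeg, small_events)
    eeg3 = eeg.copy_with(eeg.data * 3.0)
    amp3 = ak.subject_amplitudes(eeg3, small_events)
    assert np.allclose(amp3["mean_amplitude_uv"], 3 * amp1["mean_amplitude_uv"])


def test_grand_average_single_and_symmetric():
    ep = _full_epochset(4, value=2.0)
    ga = ak.grand_average([ep], by=("task",))
    assert np.allclose(ga[("implicit",)], 2.0)
    neg = _full_epochset(4, value=-2.0)
    ga2 = ak.grand_average([ep, neg], by=("task",))
    assert np.allclose(ga2[("implicit",)], 0.0)


def test_eeg_io_roundtrip(tmp_path):
    rng = np.random.default_rng(4)
    eeg = ContinuousEEG(rng.normal(size=(5, 200)),
                        ("Cz", "FCz", "Fz") + MASTOIDS, 512.0, "S07",
                        "explicit", "DLD", events_offset_s=0.25)
    ak.erp.save_eeg(eeg, tmp_path / "rec")
    back = ak.erp.load_eeg(tmp_path / "rec")
    assert back.channels == eeg.channels
    assert back.subject_id == "S07" and back.task == "explicit"
    assert back.events_offset_s == 0.25
    assert np.allclose(back.data, eeg.data, atol=1e-4)  # float32 on disk
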