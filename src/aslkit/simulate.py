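"""Forward simulation of cohort EEG and behavior for the stream paradigm.

The generator produces what the analysis pipeline assumes it is given:
continuous 512-Hz EEG in which every word token evokes an N100 and an N400
component (Hanning-bump temporal templates inside the analysis windows,
Gaussian spatial topographies peaking over the component's ROI) with
condition-dependent target amplitudes, superimposed on 1/f background
noise, sensor white noise, and frontal blink artifacts large enough to
exercise the +/-100 uV rejection path. Behavioral 2-AFC responses are
Bernoulli draws from a per-condition accuracy table whose defaults are the
group-level accuracies the paradigm typically yields (chance-level
performance in all cells); click-detection counts come from per-task hit
rates.

Component templates are calibrated against the exact window/ROI averaging
arithmetic of the ERP pipeline, so a noise-free subject analyzed without
filtering returns the injected amplitudes to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import erp
from .erp import COMPONENTS, ContinuousEEG
from .montage import BIOSEMI64, MASTOIDS, spatial_weights
from .stream import StreamPlan

__all__ = [
    "TemporalTemplate", "EffectMap", "NoiseSpec", "SimConfig",
    "default_effect_map", "roi_channel_set", "simulate_subject_eeg",
    "simulate_cohort", "cohort_amplitude_table", "simulate_behavior",
    "CohortDataset",
]

GROUPS = ("DLD", "TLD")
TASKS = ("implicit", "explicit")

#: Frontal channels carrying blink artifacts (those present in the montage).
BLINK_CHANNELS = ("Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8")


@dataclass(frozen=True)
class TemporalTemplate:
    """A Hanning bump: peak latency and full width, support within [0, 600] ms
    so it never leaks into the baseline of the following epoch."""

    peak_ms: float
    width_ms: float

    def waveform(self, sfreq: float, n: int) -> np.ndarray:
        """Template sampled on the post-onset grid (samples 0..n-1)."""
        t = np.arange(n) / sfreq * 1000.0
        lo = self.peak_ms - self.width_ms / 2.0
        w = np.zeros(n)
        inside = (t >= lo) & (t <= lo + self.width_ms)
        w[inside] = 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - lo) / self.width_ms))
        return w


DEFAULT_TEMPLATES = {
    "N100": TemporalTemplate(peak_ms=100.0, width_ms=80.0),
    "N400": TemporalTemplate(peak_ms=400.0, width_ms=300.0),
}


@dataclass
class EffectMap:
    """Target mean amplitudes (uV) per (group, task, predictability, half, component).

    The target is what the pipeline's ROI/window mean should measure for
    that cell; negative values are the normal polarity for N100/N400.
    """

    amplitudes: dict[tuple[str, str, str, int, str], float]
    templates: dict[str, TemporalTemplate] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES))
    spatial_sigma: float = 0.45

    def amplitude(self, group, task, predictability, half, component) -> float:
        return self.amplitudes[(group, task, predictability, half, component)]

    @classmethod
    def zero(cls) -> "EffectMap":
        amps = {(g, t, p, h, c): 0.0
                for g in GROUPS for t in TASKS for p in ("high", "low")
                for h in (1, 2) for c in COMPONENTS}
        return cls(amps)


def default_effect_map() -> EffectMap:
    """Default map encoding the qualitative condition effects of the paradigm.

    N100: a length-of-exposure effect — larger (more negative) amplitude in
    the second half than the first, in both groups and tasks. N400: a task
    effect (explicit > implicit) restricted to the TLD group, expressed for
    low-TP words in the first half and high-TP words in the second half,
    plus a weak high-TP advantage for TLD in the first half of the implicit
    task. Magnitudes are plausible child-ERP values of a few uV.
    """
    amps: dict[tuple, float] = {}
    for g in GROUPS:
        for t in TASKS:
            for p in ("high", "low"):
                for h in (1, 2):
                    amps[(g, t, p, h, "N100")] = -1.5 if h == 1 else -2.5
                    amps[(g, t, p, h, "N400")] = -1.5
    # TLD-only explicit-task enhancement (low-TP early, high-TP late)
    for p, h in (("low", 1), ("high", 2)):
        amps[("TLD", "explicit", p, h, "N400")] = -3.5
    amps[("TLD", "explicit", "high", 1, "N400")] = -2.2
    amps[("TLD", "explicit", "low", 2, "N400")] = -2.2
    # weak implicit high-TP group difference, first half
    amps[("TLD", "implicit", "high", 1, "N400")] = -2.2
    return EffectMap(amps)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: 1/f^beta background, white sensor noise, blinks."""

    background_rms_uv: float = 10.0
    beta: float = 1.0
    blink_rate_per_min: float = 6.0
    blink_amplitude_uv: float = 120.0
    blink_width_ms: float = 400.0
    white_rms_uv: float = 2.0

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(0.0, 1.0, 0.0, 0.0, 400.0, 0.0)


#: Per-condition 2-AFC accuracies (group, task, predictability); defaults are
#: the chance-level group means typically observed with preschool cohorts.
DEFAULT_ACCURACY = {
    ("DLD", "implicit", "high"): 0.51, ("DLD", "implicit", "low"): 0.48,
    ("DLD", "explicit", "high"): 0.53, ("DLD", "explicit", "low"): 0.53,
    ("TLD", "implicit", "high"): 0.52, ("TLD", "implicit", "low"): 0.44,
    ("TLD", "explicit", "high"): 0.55, ("TLD", "explicit", "low"): 0.54,
}

#: Per (group, task) click-detection hit rates (fraction of chirps detected).
DEFAULT_HIT_RATES = {
    ("DLD", "implicit"): 0.907, ("DLD", "explicit"): 0.881,
    ("TLD", "implicit"): 0.949, ("TLD", "explicit"): 0.922,
}


@dataclass
class SimConfig:
    """Cohort-level simulation settings.

    ``n_per_group`` defaults to 15, giving 30 analyzed subjects and the
    between-cells error df of 28 in the 2x2x2x2 mixed ANOVA.
    """

    n_per_group: int = 15
    seed: int = 0
    between_sd_uv: float = 1.0
    accuracy: dict = field(default_factory=lambda: dict(DEFAULT_ACCURACY))
    trials_per_condition: int = 8
    n_chirps_per_task: int = 144
    hit_rates: dict = field(default_factory=lambda: dict(DEFAULT_HIT_RATES))
    false_alarm_mean: float = 2.0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for v in self.accuracy.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("accuracies must lie in [0, 1]")


def roi_channel_set() -> tuple[str, ...]:
    """Reduced montage: the union of analysis ROI channels plus mastoids."""
    roi = []
    for comp in COMPONENTS.values():
        for c in comp.roi.channels:
            if c not in roi:
                roi.append(c)
    return tuple(roi) + MASTOIDS


def _pink_noise(rng, n_ch, n_samp, sfreq, rms, beta):
    """FFT-shaped Gaussian noise with power spectrum ~ 1/f^beta."""
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    spec = (rng.standard_normal((n_ch, len(freqs)))
            + 1j * rng.standard_normal((n_ch, len(freqs)))) * shape
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    cur = x.std(axis=1, keepdims=True)
    cur[cur == 0] = 1.0
    return x / cur * rms


def simulate_subject_eeg(events: pd.DataFrame, effect_map: EffectMap,
                         noise: NoiseSpec, subject_seed: int,
                         group: str = "TLD", task: str = "implicit",
                         subject_id: str = "S00",
                         channels: tuple[str, ...] | str = "full",
                         sfreq: float = 512.0,
                         subject_offsets: dict | None = None,
                         lead_in_s: float = 0.5,
                         plan: StreamPlan = StreamPlan()) -> ContinuousEEG:
    """Simulate one continuous recording for a subject performing one task.

    Word-onset-locked component templates with condition-appropriate target
    amplitudes (plus optional per-subject amplitude offsets) are added to
    1/f background noise, white sensor noise, and Poisson blink artifacts.
    Mastoid channels carry only sensor noise. The recording starts
    ``lead_in_s`` before the stream so that the first epoch's baseline is
    inside the recording. Reproducible per seed.
    """
    if channels == "full":
        ch = BIOSEMI64 + MASTOIDS
    elif channels == "roi":
        ch = roi_channel_set()
    else:
        ch = tuple(channels)
    rng = np.random.default_rng(subject_seed)
    onsets = events[events["event_kind"] == "word_onset"]
    n_blocks = int(onsets["block"].max())
    half_split = n_blocks // 2
    end_ms = onsets["onset_ms"].max() + plan.word_duration_ms
    n_samp = int(round((end_ms / 1000.0 + lead_in_s + 1.3) * sfreq))
    data = np.zeros((len(ch), n_samp))

    n_post = int(round(0.7 * sfreq))  # template support fits in 600 ms
    times = np.arange(int(round(1.5 * sfreq))) - int(round(0.3 * sfreq))
    epoch_times = times / sfreq
    for name, comp in COMPONENTS.items():
        template = effect_map.templates[name].waveform(sfreq, n_post)
        weights = spatial_weights(ch, comp.roi.channels, effect_map.spatial_sigma)
        # calibration: what the pipeline's window/ROI mean measures per unit
        w_idx = erp.window_sample_indices(
            sfreq, comp.window_ms, epoch_times)
        rel = times[w_idx]  # sample offsets from onset within the window
        window_mean = template[rel].mean()
        roi_idx = [ch.index(c) for c in comp.roi.channels]
        roi_weight = weights[roi_idx].mean()
        unit = window_mean * roi_weight
        if unit == 0:
            raise ValueError("degenerate template: zero response in window")
        offs = (subject_offsets or {}).get(name, 0.0)
        profile = np.outer(weights, template)
        for onset_ms, pred, block in zip(onsets["onset_ms"].to_numpy(),
                                         onsets["predictability"].to_numpy(),
                                         onsets["block"].to_numpy()):
            half = 1 if block <= half_split else 2
            amp = effect_map.amplitude(group, task, pred, half, name) + offs
            if amp == 0.0:
                continue
            start = int(round((onset_ms / 1000.0 + lead_in_s) * sfreq))
            seg = min(n_post, n_samp - start)
            data[:, start:start + seg] += (amp / unit) * profile[:, :seg]

    scalp = [i for i, c in enumerate(ch) if c not in MASTOIDS]
    if noise.background_rms_uv > 0:
        data[scalp] += _pink_noise(rng, len(scalp), n_samp, sfreq,
                                   noise.background_rms_uv, noise.beta)
    if noise.white_rms_uv > 0:
        data += rng.standard_normal(data.shape) * noise.white_rms_uv
    if noise.blink_rate_per_min > 0 and noise.blink_amplitude_uv > 0:
        dur_min = n_samp / sfreq / 60.0
        n_blinks = rng.poisson(noise.blink_rate_per_min * dur_min)
        blink_n = int(round(noise.blink_width_ms / 1000.0 * sfreq))
        bump = np.hanning(blink_n)
        topo = np.array([1.0 if c in BLINK_CHANNELS else 0.0 for c in ch])
        if topo.sum() == 0:  # reduced montages: hit the frontal-most ROI row
            topo = np.array([1.0 if c.startswith("F") else 0.0 for c in ch])
        for _ in range(n_blinks):
            start = rng.integers(0, max(1, n_samp - blink_n))
            data[:, start:start + blink_n] += (
                noise.blink_amplitude_uv * np.outer(topo, bump))
    return ContinuousEEG(data, ch, sfreq, subject_id, task, group,
                         events_offset_s=lead_in_s)


@dataclass
class CohortDataset:
    """Simulated cohort: per-subject recordings plus the shared designs."""

    recordings: list  # of (ContinuousEEG, events DataFrame)
    events_by_task: dict[str, pd.DataFrame]
    config: SimConfig
    manifest: pd.DataFrame  # subject, group, task, seed


def simulate_cohort(config: SimConfig, effect_map: EffectMap,
                    noise: NoiseSpec,
                    events_by_task: dict[str, pd.DataFrame],
                    channels="full") -> CohortDataset:
    """Simulate EEG for ``n_per_group`` subjects per group on both tasks.

    Per-subject seeds and between-subject amplitude offsets fan out
    deterministically from ``config.seed``; the same master seed yields an
    identical dataset.
    """
    master = np.random.SeedSequence(config.seed)
    recs, manifest = [], []
    subj_seeds = master.spawn(2 * config.n_per_group)
    i = 0
    for group in GROUPS:
        for k in range(config.n_per_group):
            ss = subj_seeds[i]
            i += 1
            sid = f"{group}{k + 1:02d}"
            srng = np.random.default_rng(ss)
            offsets = {c: srng.normal(0.0, config.between_sd_uv)
                       for c in COMPONENTS}
            for task in TASKS:
                seed = int(srng.integers(0, 2 ** 31))
                eeg = simulate_subject_eeg(
                    events_by_task[task], effect_map, noise, seed,
                    group=group, task=task, subject_id=sid,
                    channels=channels, subject_offsets=offsets)
                recs.append((eeg, events_by_task[task]))
                manifest.append(dict(subject=sid, group=group, task=task,
                                     seed=seed))
    return CohortDataset(recs, dict(events_by_task), config,
                         pd.DataFrame(manifest))


def cohort_amplitude_table(dataset: CohortDataset,
                           min_retained_fraction: float = 0.5,
                           **preprocess_kwargs) -> pd.DataFrame:
    """Run the ERP pipeline over a cohort and assemble the amplitude table.

    Subjects whose retained-epoch fraction falls below
    ``min_retained_fraction`` in any condition cell are excluded (the
    artifact-rejection exclusion rule), with an ``excluded`` marker column
    on the returned table's attrs.
    """
    rows = []
    for eeg, events in dataset.recordings:
        rows.append(erp.subject_amplitudes(eeg, events, **preprocess_kwargs))
    table = pd.concat(rows, ignore_index=True)
    presented = _presented_per_cell(dataset)
    table = table.merge(presented, on=["task", "predictability", "half"])
    # exclusion: any cell below the retained-fraction floor drops the subject
    frac = table["n_epochs_retained"] / table["n_presented"]
    bad = set(table.loc[frac < min_retained_fraction, "subject"])
    table.attrs["excluded_subjects"] = sorted(bad)
    return table[~table["subject"].isin(bad)].reset_index(drop=True)


def _presented_per_cell(dataset: CohortDataset) -> pd.DataFrame:
    """Tokens presented per (task, predictability, half) cell."""
    frames = []
    for task, ev in dataset.events_by_task.items():
        onsets = ev[ev["event_kind"] == "word_onset"].copy()
        half_split = int(onsets["block"].max()) // 2
        onsets["half"] = np.where(onsets["block"] <= half_split, 1, 2)
        g = (onsets.groupby(["predictability", "half"]).size()
             .rename("n_presented").reset_index())
        g["task"] = task
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def simulate_behavior(config: SimConfig, seed: int | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate 2-AFC and click-detection tables for a cohort.

    2-AFC: per subject x task x predictability, Bernoulli(accuracy) over
    ``trials_per_condition`` trials. Click detection: Binomial hits over
    the task's chirps plus Poisson false alarms.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    afc_rows, click_rows = [], []
    for group in GROUPS:
        for k in range(config.n_per_group):
            sid = f"{group}{k + 1:02d}"
            for task in TASKS:
                for pred in ("high", "low"):
                    acc = config.accuracy[(group, task, pred)]
                    n = config.trials_per_condition
                    correct = int(rng.binomial(n, acc))
                    afc_rows.append(dict(subject=sid, group=group, task=task,
                                         predictability=pred, n_trials=n,
                                         n_correct=correct,
                                         proportion_correct=correct / n))
                hits = int(rng.binomial(config.n_chirps_per_task,
                                        config.hit_rates[(group, task)]))
                fas = int(rng.poisson(config.false_alarm_mean))
                click_rows.append(dict(subject=sid, group=group, task=task,
                                       n_chirps=config.n_chirps_per_task,
                                       hits=hits, false_alarms=fas))
    return pd.DataFrame(afc_rows), pd.DataFrame(click_rows)
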