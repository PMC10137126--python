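"""Render generative design specs into trial-epoched EEG and behavior tables.

Each trial is the sum of three independently seeded parts:

* evoked components — Gaussian-windowed monophasic deflections with optional
  trial-to-trial amplitude and latency jitter;
* oscillatory components — fixed-frequency cosines whose per-trial phase at
  the locking stimulus is drawn from a von Mises distribution (kappa = 0 is
  uniform phase, i.e. no phase locking), gated by a Gaussian-edged envelope;
* 1/f background noise, synthesized by shaping a white-noise spectrum.

Randomness is routed through one named stream per (subject, cell, role,
component), derived from ``numpy.random.SeedSequence``, so adding a component
or a cell never perturbs the draws of existing ones, and identical
``(spec, subject_id, seed)`` always yields bit-identical output.
"""
from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import CellSpec, DesignSpec, OscComponent
from .epochs import BehaviorTable, EpochSet, TRIAL_COLUMNS

# role indices for stream derivation; fixed forever
_ROLE_EVOKED = 0
_ROLE_OSC = 1
_ROLE_NOISE = 2
_ROLE_BEHAVIOR = 3

#: Gaussian SD of the oscillation envelope edge ramp (seconds).
ENVELOPE_EDGE_SD_S = 0.020


def _subject_key(subject_id) -> int:
    return zlib.crc32(str(subject_id).encode("utf-8"))


def _stream(seed: int, subject_key: int, cell_index: int, role: int,
            comp_index: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, subject_key, cell_index, role, comp_index])
    return np.random.default_rng(ss)


def _channel_gains(weights, channels) -> np.ndarray:
    return np.array([float(weights.get(ch, 0.0)) for ch in channels])


def _smooth_gate(times: np.ndarray, onset: float, offset: float,
                 edge_sd: float = ENVELOPE_EDGE_SD_S) -> np.ndarray:
    """Boxcar over [onset, offset] with Gaussian-cdf edges (no splatter)."""
    return (sps.norm.cdf(times, loc=onset, scale=edge_sd)
            * sps.norm.cdf(-times, loc=-offset, scale=edge_sd))


def one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                     sampling_rate: float, sd: float,
                     exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with power ~ 1/f**exponent along the last axis.

    The spectral shaping filter is normalized to unit RMS gain, so ``sd`` is
    the nominal broadband standard deviation of the output.
    """
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if exponent == 0:
        return sd * white
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    # unit RMS gain: sum over the two-sided spectrum / n
    two_sided = np.concatenate([gain, gain[-2:0:-1]]) if n % 2 == 0 else \
        np.concatenate([gain, gain[:0:-1]])
    gain /= np.sqrt(np.mean(two_sided[:n] ** 2))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * gain, n=n, axis=-1)
    # irfft of shaped white noise keeps unit variance thanks to Parseval
    return sd * shaped


def draw_phases(rng: np.random.Generator, n: int, mu: float,
                kappa: float) -> np.ndarray:
    """Per-trial phases: von Mises around ``mu``; kappa = 0 means uniform."""
    if kappa == 0:
        return rng.uniform(-np.pi, np.pi, size=n)
    return rng.vonmises(mu, kappa, size=n)


def render_cell_epochs(cell: CellSpec, spec: DesignSpec, n_trials: int,
                       streams: dict[int, list[np.random.Generator]]
                       ) -> np.ndarray:
    """Render one cell's (n_trials, n_channels, n_samples) tensor."""
    times = spec.times()
    n_ch = len(spec.channels)
    n_samp = spec.n_samples
    out = np.zeros((n_trials, n_ch, n_samp))

    for k, comp in enumerate(cell.evoked):
        rng = streams[_ROLE_EVOKED][k]
        lock = spec.first_stim_offset_s if comp.locking == "first" else 0.0
        amps = comp.amplitude_uv + (
            rng.normal(0.0, comp.amplitude_jitter_sd_uv, n_trials)
            if comp.amplitude_jitter_sd_uv > 0 else np.zeros(n_trials))
        lats = lock + comp.peak_latency_s + (
            rng.normal(0.0, comp.latency_jitter_sd_s, n_trials)
            if comp.latency_jitter_sd_s > 0 else np.zeros(n_trials))
        gains = _channel_gains(comp.channel_weights, spec.channels)
        # (trials, samples) Gaussian templates
        waves = np.exp(-0.5 * ((times[None, :] - lats[:, None])
                               / comp.width_s) ** 2) * amps[:, None]
        out += waves[:, None, :] * gains[None, :, None]

    for k, comp in enumerate(cell.oscillations):
        rng = streams[_ROLE_OSC][k]
        lock = spec.first_stim_offset_s if comp.locking == "first" else 0.0
        phases = draw_phases(rng, n_trials, comp.locked_phase_rad,
                             comp.phase_concentration_kappa)
        gate = _smooth_gate(times - lock, *comp.envelope)
        carrier = np.cos(2 * np.pi * comp.center_freq_hz
                         * (times[None, :] - lock) + phases[:, None])
        gains = _channel_gains(comp.channel_weights, spec.channels)
        waves = comp.amplitude_uv * gate[None, :] * carrier
        out += waves[:, None, :] * gains[None, :, None]

    noise_rng = streams[_ROLE_NOISE][0]
    out += one_over_f_noise(noise_rng, (n_trials, n_ch, n_samp),
                            spec.sampling_rate, cell.noise.noise_sd_uv,
                            cell.noise.one_over_f_exponent)
    return out


def _draw_behavior(rng: np.random.Generator, behavior, n_trials: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    correct = rng.random(n_trials) < behavior.accuracy_prob
    if behavior.rt_sd_s == 0:
        rts = np.full(n_trials, max(behavior.rt_mean_s, behavior.rt_floor_s))
    else:
        a = (behavior.rt_floor_s - behavior.rt_mean_s) / behavior.rt_sd_s
        rts = sps.truncnorm.rvs(a, np.inf, loc=behavior.rt_mean_s,
                                scale=behavior.rt_sd_s, size=n_trials,
                                random_state=rng)
    return correct, rts


def _cell_streams(seed: int, skey: int, cell_index: int, cell: CellSpec
                  ) -> dict[int, list[np.random.Generator]]:
    return {
        _ROLE_EVOKED: [_stream(seed, skey, cell_index, _ROLE_EVOKED, k)
                       for k in range(len(cell.evoked))],
        _ROLE_OSC: [_stream(seed, skey, cell_index, _ROLE_OSC, k)
                    for k in range(len(cell.oscillations))],
        _ROLE_NOISE: [_stream(seed, skey, cell_index, _ROLE_NOISE,
                              cell.noise.stream_id)],
        _ROLE_BEHAVIOR: [_stream(seed, skey, cell_index, _ROLE_BEHAVIOR)],
    }


def generate_subject_epochs(spec: DesignSpec, subject_id, seed: int
                            ) -> EpochSet:
    """Generate one subject's full epoch set (all MA x TP cells).

    Deterministic: identical ``(spec, subject_id, seed)`` gives bit-identical
    tensors and trial tables.
    """
    spec.validate()
    skey = _subject_key(subject_id)
    blocks, info_rows = [], []
    for cell_index, (ma, tp) in enumerate(spec.cell_order()):
        cell = spec.cells[(ma, tp)]
        streams = _cell_streams(seed, skey, cell_index, cell)
        blocks.append(render_cell_epochs(cell, spec, spec.n_trials_per_cell,
                                         streams))
        correct, rts = _draw_behavior(streams[_ROLE_BEHAVIOR][0],
                                      cell.behavior, spec.n_trials_per_cell)
        for t in range(spec.n_trials_per_cell):
            info_rows.append((str(subject_id), ma, tp, t,
                              bool(correct[t]), float(rts[t])))
    trial_info = pd.DataFrame(info_rows, columns=TRIAL_COLUMNS)
    return EpochSet(data=np.concatenate(blocks, axis=0),
                    sampling_rate=spec.sampling_rate,
                    t0_index=spec.t0_index,
                    channels=list(spec.channels),
                    trial_info=trial_info)


def generate_dataset(spec: DesignSpec, seed: int,
                     subject_ids=None) -> dict[str, EpochSet]:
    """Generate every subject of the design; returns {subject_id: EpochSet}."""
    if subject_ids is None:
        subject_ids = [f"S{i + 1:02d}" for i in range(spec.n_subjects)]
    return {sid: generate_subject_epochs(spec, sid, seed)
            for sid in subject_ids}


def generate_behavior_table(spec: DesignSpec, n_subjects: int | None = None,
                            seed: int = 0) -> BehaviorTable:
    """Long behavioral table for ``n_subjects`` simulated subjects.

    Uses the same per-(subject, cell) behavior streams as
    :func:`generate_subject_epochs`, so the rows agree with the trial info of
    generated epoch sets for the same seed and subject labels.
    """
    spec.validate()
    if n_subjects is None:
        n_subjects = spec.n_subjects
    rows = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        skey = _subject_key(sid)
        for cell_index, (ma, tp) in enumerate(spec.cell_order()):
            cell = spec.cells[(ma, tp)]
            rng = _stream(seed, skey, cell_index, _ROLE_BEHAVIOR)
            correct, rts = _draw_behavior(rng, cell.behavior,
                                          spec.n_trials_per_cell)
            for t in range(spec.n_trials_per_cell):
                rows.append((sid, ma, tp, t, bool(correct[t]),
                             float(rts[t])))
    return BehaviorTable(frame=pd.DataFrame(rows, columns=TRIAL_COLUMNS))


def generate_null_measure_table(n_subjects: int, n_trials_per_cell: int,
                                rng: np.random.Generator,
                                ma_levels=("attended", "unattended"),
                                tp_levels=("NTP", "MTP", "VTP"),
                                sigma_subject: float = 1.0,
                                sigma_trial: float = 1.0,
                                measure: str = "measure") -> pd.DataFrame:
    """A measure table under the global null: no MA, TP or interaction effect.

    Each subject gets a random intercept; each cell value is the mean of
    ``n_trials_per_cell`` iid trial-level draws around that intercept.  Used
    for type-I-error simulation of the gated testing scheme.
    """
    rows = []
    for i in range(n_subjects):
        intercept = rng.normal(0.0, sigma_subject)
        for ma in ma_levels:
            for tp in tp_levels:
                value = intercept + rng.normal(
                    0.0, sigma_trial / np.sqrt(n_trials_per_cell))
                rows.append((f"S{i + 1:02d}", ma, tp, measure, value))
    return pd.DataFrame(rows, columns=["subject", "ma", "tp",
                                       "measure", "value"])


def oscillation_phase_estimates(e: EpochSet, comp: OscComponent,
                                first_stim_offset_s: float = -0.4,
                                channel: str | None = None) -> np.ndarray:
    """Per-trial phase (at the locking time) of an oscillatory component.

    Projects each trial onto a complex exponential at the component frequency
    over the flat interior of the envelope — a direct circular-statistics
    probe that does not go through the wavelet decomposition.
    """
    lock = first_stim_offset_s if comp.locking == "first" else 0.0
    times = e.times
    onset, offset = comp.envelope
    lo = lock + onset + 3 * ENVELOPE_EDGE_SD_S
    hi = lock + offset - 3 * ENVELOPE_EDGE_SD_S
    sel = (times >= lo) & (times <= hi)
    ch = e.channel_indices([channel])[0] if channel else 0
    seg = e.data[:, ch, sel]
    probe = np.exp(-2j * np.pi * comp.center_freq_hz * (times[sel] - lock))
    return np.angle(seg @ probe)
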