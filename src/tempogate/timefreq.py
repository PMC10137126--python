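"""Morlet time-frequency decomposition, inter-trial coherence and ERSP.

The decomposition convolves each trial with unit-energy complex Morlet
wavelets.  The number of cycles grows linearly from 3 (at and below 3 Hz)
to 8 at 40 Hz — the conventional trade-off between temporal and spectral
resolution for event-related EEG — and is capped per frequency so the
truncated wavelet (support +/- 3 sigma_t) fits inside the epoch.  Time bins
closer than the wavelet half-support to either epoch edge are flagged
invalid and excluded from all aggregations rather than silently returned.

From the complex coefficients ``F_i(f, t)`` (trial i) the two statistics are

* inter-trial coherence, the magnitude of the mean unit-normalized
  coefficient across trials::

      ITC(f, t) = | (1/N) sum_i F_i(f, t) / |F_i(f, t)| |

  which is 1 for perfectly phase-locked trials and tends to
  sqrt(pi) / (2 sqrt(N)) for uniform phases;

* event-related spectral perturbation, mean power expressed in dB relative
  to a pre-first-stimulus baseline::

      ERSP(f, t) = 10 log10( P(f, t) / B(f) ),   P = (1/N) sum_i |F_i|^2

  with ``B(f)`` the mean of ``P`` over the baseline window.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .epochs import EpochSet
from .erp import window_sample_mask
from .errors import EmptyCellError, ParameterError

#: Canonical frequency bands (Hz), inclusive of both edges.
BANDS: Mapping[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (15.0, 30.0),
}

#: Wavelet truncation half-support, in units of the temporal SD sigma_t.
_SUPPORT_SIGMAS = 3.0


@dataclass
class TFDecomposition:
    """Complex coefficients (trials, channels, freqs, times) + validity."""

    coeffs: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    channels: list[str]
    valid: np.ndarray  # (freqs, times) bool: wavelet support inside epoch
    method_meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    def channel_indices(self, names) -> list[int]:
        missing = [ch for ch in names if ch not in self.channels]
        if missing:
            raise ParameterError(f"channels: unknown channel(s) {missing}")
        return [self.channels.index(ch) for ch in names]


@dataclass(frozen=True)
class BandWindow:
    """A frequency band crossed with a temporal window (zero-point time)."""

    band: str
    window_s: tuple[float, float]

    @property
    def band_range_hz(self) -> tuple[float, float]:
        if self.band not in BANDS:
            raise ParameterError(
                f"band: {self.band!r} not one of {sorted(BANDS)}")
        return BANDS[self.band]


def default_cycles(freqs_hz: np.ndarray) -> np.ndarray:
    """Cycles rising linearly from 3 at <= 3 Hz to 8 at 40 Hz."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    return np.clip(3.0 + 5.0 * (freqs_hz - 3.0) / 37.0, 3.0, 8.0)


def morlet_wavelet(freq_hz: float, n_cycles: float, sampling_rate: float
                   ) -> np.ndarray:
    """Zero-mean, unit-energy complex Morlet wavelet, truncated at 3 sigma."""
    sigma_t = n_cycles / (2 * np.pi * freq_hz)
    half = int(round(_SUPPORT_SIGMAS * sigma_t * sampling_rate))
    t = (np.arange(2 * half + 1) - half) / sampling_rate
    gauss = np.exp(-0.5 * (t / sigma_t) ** 2)
    # subtracting the DC term keeps the wavelet zero-mean at low cycle counts
    dc = np.exp(-0.5 * (2 * np.pi * freq_hz * sigma_t) ** 2)
    w = (np.exp(2j * np.pi * freq_hz * t) - dc) * gauss
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / sampling_rate)
    return w


def morlet_decompose(e: EpochSet, freqs_hz, n_cycles=None,
                     channels=None) -> TFDecomposition:
    """Complex Morlet decomposition of every trial and channel.

    ``n_cycles`` may be a scalar or per-frequency array; it defaults to
    :func:`default_cycles` and is capped so the wavelet support fits the
    epoch.  Raises :class:`ParameterError` if even a one-cycle wavelet at the
    lowest requested frequency cannot fit.
    """
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if np.any(freqs_hz <= 0) or np.any(freqs_hz >= e.sampling_rate / 2):
        raise ParameterError("freqs_hz: must lie in (0, Nyquist)")
    if n_cycles is None:
        n_cycles = default_cycles(freqs_hz)
    n_cycles = np.broadcast_to(np.asarray(n_cycles, dtype=float),
                               freqs_hz.shape).copy()
    duration = e.n_samples / e.sampling_rate
    # cap so the truncated wavelet (2 * 3 sigma_t) fits in the epoch
    sigma_max = duration / (2 * _SUPPORT_SIGMAS) * 0.999
    cap = 2 * np.pi * freqs_hz * sigma_max
    if np.any(cap < 1.0):
        fmin = freqs_hz[np.argmin(cap)]
        need = 2 * _SUPPORT_SIGMAS / (2 * np.pi * fmin)
        raise ParameterError(
            f"freqs_hz: epoch of {duration:g} s is too short for {fmin:g} Hz;"
            f" at least {need:g} s is required for a one-cycle wavelet")
    n_cycles = np.minimum(n_cycles, cap)

    if channels is not None:
        picks = e.channel_indices(channels)
        data = e.data[:, picks, :]
        chan_labels = list(channels)
    else:
        data = e.data
        chan_labels = list(e.channels)

    n_trials, n_ch, n_samp = data.shape
    coeffs = np.empty((n_trials, n_ch, len(freqs_hz), n_samp),
                      dtype=np.complex128)
    valid = np.zeros((len(freqs_hz), n_samp), dtype=bool)
    idx = np.arange(n_samp)
    for k, (f, nc) in enumerate(zip(freqs_hz, n_cycles)):
        w = morlet_wavelet(f, nc, e.sampling_rate)
        half = (len(w) - 1) // 2
        coeffs[:, :, k, :] = fftconvolve(data, w[None, None, :],
                                         mode="same", axes=-1)
        valid[k] = (idx >= half) & (idx <= n_samp - 1 - half)
    return TFDecomposition(
        coeffs=coeffs, freqs_hz=freqs_hz, times_s=e.times.copy(),
        channels=chan_labels, valid=valid,
        method_meta={"n_cycles": n_cycles.tolist(),
                     "support_sigmas": _SUPPORT_SIGMAS,
                     "sampling_rate": e.sampling_rate})


def itc(tf: TFDecomposition) -> np.ndarray:
    """Inter-trial coherence map (channels, freqs, times) in [0, 1].

    Trials whose coefficient magnitude is exactly zero at a bin are excluded
    from that bin's average (their phase is undefined).
    """
    if tf.n_trials < 2:
        raise ParameterError("coeffs: ITC requires at least 2 trials")
    mags = np.abs(tf.coeffs)
    nonzero = mags > 0
    unit = np.where(nonzero, tf.coeffs / np.where(nonzero, mags, 1.0), 0.0)
    counts = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.abs(unit.sum(axis=0)) / counts
    out[counts == 0] = 0.0
    return out


def ersp(tf: TFDecomposition, baseline_window_s: tuple[float, float]
         ) -> np.ndarray:
    """ERSP map (channels, freqs, times) in dB relative to baseline power."""
    power = np.mean(np.abs(tf.coeffs) ** 2, axis=0)  # (ch, f, t)
    fs = tf.method_meta.get("sampling_rate",
                            1.0 / np.median(np.diff(tf.times_s)))
    sel = window_sample_mask(tf.times_s, baseline_window_s, fs)
    baseline = np.empty(power.shape[:2])
    for k in range(len(tf.freqs_hz)):
        use = sel & tf.valid[k]
        if not use.any():
            raise ParameterError(
                f"baseline_window_s: no valid bins at "
                f"{tf.freqs_hz[k]:g} Hz (wavelet edge contamination)")
        baseline[:, k] = power[:, k, use].mean(axis=-1)
    if np.any(baseline == 0):
        k = int(np.argwhere(baseline == 0)[0][1])
        raise ParameterError(
            f"baseline_window_s: zero baseline power at "
            f"{tf.freqs_hz[k]:g} Hz")
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(power / baseline[:, :, None])


def band_window_mean(values: np.ndarray, tf: TFDecomposition,
                     bw: BandWindow, channels=None) -> float:
    """Unweighted mean of a (channels, freqs, times) map over a band-window.

    Only valid (non-edge-contaminated) bins contribute; raises if the
    band-window contains none.
    """
    lo, hi = bw.band_range_hz
    fsel = (tf.freqs_hz >= lo - 1e-9) & (tf.freqs_hz <= hi + 1e-9)
    if not fsel.any():
        raise ParameterError(
            f"band: {bw.band!r} ({lo:g}-{hi:g} Hz) has no frequencies on "
            "the decomposition grid")
    fs = tf.method_meta.get("sampling_rate",
                            1.0 / np.median(np.diff(tf.times_s)))
    tsel = window_sample_mask(tf.times_s, bw.window_s, fs)
    use = tf.valid[fsel][:, tsel]  # (nf_in_band, nt_in_window)
    if not use.any():
        raise ParameterError(
            f"window_s: band-window ({bw.band}, {bw.window_s}) is fully "
            "edge-contaminated")
    cidx = (tf.channel_indices(channels) if channels is not None
            else slice(None))
    block = values[cidx][:, fsel][:, :, tsel]
    return float(block[:, use].mean())


# ---------------------------------------------------------------------------
# Measure-table construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TFMeasure:
    """One band-window statistic to extract per subject and cell."""

    name: str
    kind: str  # 'itc' | 'ersp'
    band: str
    window_s: tuple[float, float]
    channels: tuple[str, ...]
    baseline_window_s: tuple[float, float] = (-0.5, -0.4)

    def __post_init__(self) -> None:
        if self.kind not in ("itc", "ersp"):
            raise ParameterError(f"kind: {self.kind!r} must be itc or ersp")


def default_tf_measures(modality: str = "visual") -> list[TFMeasure]:
    """The standard band-window statistics of the short-interval analysis."""
    from .erp import AUDITORY_CHANNELS, VISUAL_CHANNELS

    if modality == "visual":
        ch = VISUAL_CHANNELS
        return [
            TFMeasure("visual_alpha_itc_pre", "itc", "alpha",
                      (-0.300, -0.150), ch),
            TFMeasure("visual_theta_itc_100_200", "itc", "theta",
                      (0.100, 0.200), ch),
            TFMeasure("visual_theta_itc_200_300", "itc", "theta",
                      (0.200, 0.300), ch),
            TFMeasure("visual_alpha_ersp_pre", "ersp", "alpha",
                      (-0.200, -0.100), ch),
            TFMeasure("visual_theta_ersp_100_200", "ersp", "theta",
                      (0.100, 0.200), ch),
            TFMeasure("visual_beta_ersp_200_400", "ersp", "beta",
                      (0.200, 0.400), ch),
        ]
    if modality == "auditory":
        ch = AUDITORY_CHANNELS
        return [
            TFMeasure("auditory_delta_itc_pre", "itc", "delta",
                      (-0.300, -0.150), ch),
            TFMeasure("auditory_theta_itc_100_200", "itc", "theta",
                      (0.100, 0.200), ch),
            TFMeasure("auditory_delta_itc_200_400", "itc", "delta",
                      (0.200, 0.400), ch),
            TFMeasure("auditory_alpha_ersp_pre", "ersp", "alpha",
                      (-0.200, -0.100), ch),
            TFMeasure("auditory_theta_ersp_100_200", "ersp", "theta",
                      (0.100, 0.200), ch),
            TFMeasure("auditory_beta_ersp_200_400", "ersp", "beta",
                      (0.200, 0.400), ch),
        ]
    raise ParameterError(f"modality: {modality!r} must be visual or auditory")


def _needed_freqs(measures) -> np.ndarray:
    freqs: set[float] = set()
    for m in measures:
        lo, hi = BandWindow(m.band, m.window_s).band_range_hz
        freqs.update(np.arange(np.ceil(lo), np.floor(hi) + 1).tolist())
    return np.array(sorted(freqs))


def build_tf_measure_table(epochs_by_subject: dict[str, EpochSet],
                           measures: list[TFMeasure],
                           freq_step_hz: float = 1.0) -> pd.DataFrame:
    """Long table: one row per subject x MA x TP x measure.

    Each subject x cell is decomposed once over the union of needed channels
    and integer frequencies; all band-window statistics are then read off
    that single decomposition.
    """
    if not measures:
        raise ParameterError("measures: empty list")
    all_channels: list[str] = []
    for m in measures:
        for ch in m.channels:
            if ch not in all_channels:
                all_channels.append(ch)
    freqs = _needed_freqs(measures)
    rows = []
    for subject, e in epochs_by_subject.items():
        cells = list(e.trial_info[["ma", "tp"]].drop_duplicates()
                     .itertuples(index=False))
        for ma, tp in cells:
            sub = e.select_trials(e.cell_mask(ma, tp))
            if sub.n_trials == 0:
                raise EmptyCellError(f"cell ({ma}, {tp}) empty for "
                                     f"subject {subject}")
            tf = morlet_decompose(sub, freqs, channels=all_channels)
            maps: dict[tuple, np.ndarray] = {}
            for m in measures:
                key = (m.kind, m.baseline_window_s if m.kind == "ersp"
                       else None)
                if key not in maps:
                    maps[key] = (itc(tf) if m.kind == "itc"
                                 else ersp(tf, m.baseline_window_s))
                value = band_window_mean(
                    maps[key], tf, BandWindow(m.band, m.window_s),
                    channels=m.channels)
                rows.append((subject, ma, tp, m.name, value))
    return pd.DataFrame(rows,
                        columns=["subject", "ma", "tp", "measure", "value"])
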