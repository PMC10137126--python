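"""Signal conditioning and trial qualification for epoch sets.

The pipeline applies, in order: a zero-phase linear-phase (Type-I) FIR
low-pass at 40 Hz, integer-factor downsampling to 200 Hz (with anti-alias
filtering and the zero point kept on a sample), qualification of trials
(correct response, reaction time at or above the 80 ms anticipation floor),
and window-mean baseline correction.  Filtering is applied forward-backward
so component latencies are not shifted.

Ocular-artifact removal is exposed as :func:`reject_ocular_artifacts`, a
pass-through hook: simulated data carry no ocular artifacts, and the hook
marks where an ICA-based cleaning step would slot into a real-data pipeline.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochSet
from .errors import ParameterError

#: Hamming-window FIR design: approximate transition width is 3.3 / numtaps
#: in normalized frequency.
_HAMMING_TRANSITION = 3.3


@dataclass(frozen=True)
class PreprocessConfig:
    lowpass_hz: float = 40.0
    target_rate_hz: float = 200.0
    anticipation_floor_s: float = 0.080
    require_correct: bool = True

    def __post_init__(self) -> None:
        if not self.lowpass_hz < self.target_rate_hz / 2:
            raise ParameterError(
                "lowpass_hz: must be below the target Nyquist "
                f"({self.target_rate_hz / 2:g} Hz)")


def design_lowpass(sampling_rate: float, cutoff_hz: float,
                   transition_hz: float = 10.0) -> np.ndarray:
    """Odd-length (Type-I) Hamming-window FIR low-pass taps."""
    if cutoff_hz >= sampling_rate / 2:
        raise ParameterError(
            f"cutoff_hz: {cutoff_hz:g} Hz is not below Nyquist "
            f"({sampling_rate / 2:g} Hz)")
    numtaps = int(np.ceil(_HAMMING_TRANSITION * sampling_rate / transition_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, cutoff_hz, fs=sampling_rate,
                         window="hamming")


def _filtfilt(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    padlen = min(3 * len(taps), data.shape[-1] - 1)
    return signal.filtfilt(taps, 1.0, data, axis=-1, padlen=padlen)


def fir_lowpass(e: EpochSet, cutoff_hz: float,
                transition_hz: float = 10.0) -> EpochSet:
    """Zero-phase low-pass filter; trial count and labels are untouched."""
    taps = design_lowpass(e.sampling_rate, cutoff_hz, transition_hz)
    return e.copy_with(data=_filtfilt(e.data, taps))


def downsample(e: EpochSet, target_rate_hz: float) -> EpochSet:
    """Integer-factor decimation with anti-alias filtering.

    The decimation offset is chosen so the zero point stays exactly on a
    sample of the new grid.
    """
    ratio = e.sampling_rate / target_rate_hz
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ParameterError(
            f"target_rate_hz: {e.sampling_rate:g} -> {target_rate_hz:g} Hz "
            "is not an integer decimation factor")
    if q == 1:
        return e.copy_with()
    # anti-alias low-pass at 80% of the new Nyquist
    cutoff = 0.4 * target_rate_hz
    transition = 0.2 * target_rate_hz / 2
    taps = design_lowpass(e.sampling_rate, cutoff, transition)
    filtered = _filtfilt(e.data, taps)
    offset = e.t0_index % q
    data = filtered[..., offset::q]
    return e.copy_with(data=np.ascontiguousarray(data),
                       sampling_rate=target_rate_hz,
                       t0_index=(e.t0_index - offset) // q)


def qualification_mask(trial_info: pd.DataFrame,
                       cfg: PreprocessConfig) -> np.ndarray:
    """Qualified = correct response and RT at or above the anticipation floor.

    RTs below the floor are treated as anticipations (responses launched
    before the stimulus could have been discriminated) and rejected.
    """
    mask = trial_info["rt_s"].to_numpy() >= cfg.anticipation_floor_s
    if cfg.require_correct:
        mask &= trial_info["correct"].to_numpy()
    return mask


def select_qualified_trials(e: EpochSet, cfg: PreprocessConfig | None = None
                            ) -> EpochSet:
    """Keep qualified trials; warns (not errors) if a cell ends up empty."""
    cfg = cfg or PreprocessConfig()
    mask = qualification_mask(e.trial_info, cfg)
    kept = e.select_trials(mask)
    counts = kept.trial_info.groupby(["ma", "tp"]).size()
    for (ma, tp) in e.trial_info[["ma", "tp"]].drop_duplicates().itertuples(
            index=False):
        if (ma, tp) not in counts.index:
            warnings.warn(f"cell ({ma}, {tp}) has no qualified trials",
                          stacklevel=2)
    return kept


def qualification_counts(e: EpochSet, cfg: PreprocessConfig | None = None
                         ) -> pd.DataFrame:
    """Per-cell total and qualified trial counts."""
    cfg = cfg or PreprocessConfig()
    info = e.trial_info.copy()
    info["qualified"] = qualification_mask(info, cfg)
    out = info.groupby(["ma", "tp"], sort=False).agg(
        n_total=("qualified", "size"), n_qualified=("qualified", "sum"))
    return out.reset_index()


def baseline_correct(e: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean amplitude over ``window``."""
    start, end = window
    times = e.times
    if start >= end:
        raise ParameterError("window: start must precede end")
    eps = 0.25 / e.sampling_rate
    if start < times[0] - eps or end > times[-1] + eps:
        raise ParameterError(
            f"window: ({start:g}, {end:g}) s outside epoch "
            f"({times[0]:g}, {times[-1]:g}) s")
    sel = (times >= start - eps) & (times <= end + eps)
    if not sel.any():
        raise ParameterError("window: contains no samples")
    means = e.data[..., sel].mean(axis=-1, keepdims=True)
    return e.copy_with(data=e.data - means)


def reject_ocular_artifacts(e: EpochSet) -> EpochSet:
    """Pass-through hook where ICA-based ocular cleaning would run."""
    return e
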