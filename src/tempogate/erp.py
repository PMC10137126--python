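"""Condition-average ERPs and per-subject window-mean amplitudes.

Evoked components are quantified as the mean amplitude inside a fixed
temporal window of the condition-average waveform, then averaged (unweighted)
across the component's electrode set: occipital O1/OZ/O2 for visual
components, frontal F1/FZ/F2 for auditory ones.  Window endpoints are
inclusive at both ends; a sample belongs to the window if its timestamp lies
within a quarter sample period of it.

Components locked to the first stimulus use a 100 ms baseline immediately
before the first stimulus; second-locked components use the 100 ms before
time zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .errors import EmptyCellError, ParameterError
from .preprocess import baseline_correct

VISUAL_CHANNELS = ("O1", "OZ", "O2")
AUDITORY_CHANNELS = ("F1", "FZ", "F2")


@dataclass(frozen=True)
class ComponentWindow:
    """A named measurement window, in zero-point (second-stimulus) time."""

    name: str
    window_s: tuple[float, float]
    channels: tuple[str, ...]
    modality: str = "visual"
    locking: str = "second"

    def __post_init__(self) -> None:
        if not self.window_s[0] < self.window_s[1]:
            raise ParameterError(
                f"window_s: start must precede end for {self.name!r}")

    @classmethod
    def from_stimulus_relative(cls, name: str, window_rel_s: tuple[float, float],
                               locking: str, channels, modality: str = "visual",
                               first_stim_offset_s: float = -0.4
                               ) -> "ComponentWindow":
        """Build from a window stated relative to its locking stimulus."""
        shift = first_stim_offset_s if locking == "first" else 0.0
        return cls(name=name,
                   window_s=(window_rel_s[0] + shift, window_rel_s[1] + shift),
                   channels=tuple(channels), modality=modality,
                   locking=locking)


def default_component_windows(first_stim_offset_s: float = -0.4
                              ) -> list[ComponentWindow]:
    """The six standard component windows of the short-interval analysis.

    Visual first-stimulus N1 is defined stimulus-relative (140-200 ms after
    the first flash) and converted to zero-point time; the remaining windows
    are zero-point-relative as stated.
    """
    return [
        ComponentWindow.from_stimulus_relative(
            "visual_N1_first", (0.140, 0.200), "first", VISUAL_CHANNELS,
            "visual", first_stim_offset_s),
        ComponentWindow("visual_N1_second", (0.120, 0.190), VISUAL_CHANNELS,
                        "visual", "second"),
        ComponentWindow("visual_N2_second", (0.200, 0.300), VISUAL_CHANNELS,
                        "visual", "second"),
        ComponentWindow("auditory_P2_first", (-0.230, -0.180),
                        AUDITORY_CHANNELS, "auditory", "first"),
        ComponentWindow("auditory_P2_second", (0.110, 0.250),
                        AUDITORY_CHANNELS, "auditory", "second"),
    ]


def condition_average(e: EpochSet, ma: str, tp: str) -> np.ndarray:
    """Arithmetic mean across a cell's trials -> (channels, samples)."""
    mask = e.cell_mask(ma, tp)
    if not mask.any():
        raise EmptyCellError(f"cell ({ma}, {tp}) contains no trials")
    return e.data[mask].mean(axis=0)


def window_sample_mask(times: np.ndarray, window_s: tuple[float, float],
                       sampling_rate: float) -> np.ndarray:
    """Closed-interval sample selection with a quarter-sample tolerance."""
    eps = 0.25 / sampling_rate
    sel = (times >= window_s[0] - eps) & (times <= window_s[1] + eps)
    if not sel.any():
        raise ParameterError(
            f"window_s: ({window_s[0]:g}, {window_s[1]:g}) s contains no "
            "samples")
    return sel


def window_mean_amplitude(waveform: np.ndarray, times: np.ndarray,
                          channels: list[str], cw: ComponentWindow,
                          sampling_rate: float) -> float:
    """Mean over window samples, then unweighted mean over cw.channels."""
    missing = [ch for ch in cw.channels if ch not in channels]
    if missing:
        raise ParameterError(f"channels: missing channel(s) {missing} "
                             f"for component {cw.name!r}")
    if cw.window_s[0] < times[0] or cw.window_s[1] > times[-1]:
        raise ParameterError(
            f"window_s: {cw.window_s} outside epoch for {cw.name!r}")
    sel = window_sample_mask(times, cw.window_s, sampling_rate)
    idx = [channels.index(ch) for ch in cw.channels]
    return float(waveform[np.ix_(idx, np.flatnonzero(sel))].mean())


def _baseline_window(locking: str, first_stim_offset_s: float
                     ) -> tuple[float, float]:
    if locking == "first":
        return (first_stim_offset_s - 0.100, first_stim_offset_s)
    return (-0.100, 0.0)


def build_erp_measure_table(epochs_by_subject: dict[str, EpochSet],
                            windows: list[ComponentWindow],
                            first_stim_offset_s: float = -0.4
                            ) -> pd.DataFrame:
    """Long measure table: one row per subject x MA x TP x component.

    Baseline correction is applied per component locking (100 ms before the
    locking stimulus) before averaging and window measurement.
    """
    rows = []
    for subject, e in epochs_by_subject.items():
        cells = (e.trial_info[["ma", "tp"]].drop_duplicates()
                 .itertuples(index=False))
        cells = list(cells)
        for locking in ("first", "second"):
            locked = [cw for cw in windows if cw.locking == locking]
            if not locked:
                continue
            eb = baseline_correct(
                e, _baseline_window(locking, first_stim_offset_s))
            for ma, tp in cells:
                avg = condition_average(eb, ma, tp)
                for cw in locked:
                    value = window_mean_amplitude(
                        avg, eb.times, eb.channels, cw, eb.sampling_rate)
                    rows.append((subject, ma, tp, cw.name, value))
    return pd.DataFrame(rows,
                        columns=["subject", "ma", "tp", "measure", "value"])
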