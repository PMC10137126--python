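"""Generative design specifications for the simulated two-factor timing experiment.

The experiment simulated here is a within-subject 2 x 3 design: *modality
attention* (MA: attended vs. unattended) crossed with *timing prediction*
(TP: NTP = no prediction, MTP = the stimulus arrives at the predicted moment,
VTP = the stimulus violates the prediction).  Each trial contains two stimuli;
every epoch is time-locked to the **second** stimulus (time zero), with the
first stimulus at a fixed negative offset (-400 ms for the analyzed
short-interval trials).

A :class:`DesignSpec` is a complete generative description of one such
dataset: the epoch geometry, the channel montage, and — per MA x TP cell — the
evoked components (Gaussian-windowed monophasic deflections), phase-locked
oscillations (von Mises phase concentration), 1/f background noise, and the
behavioral response distribution.  The simulator in
:mod:`tempogate.simulate` renders these specs into epoched EEG.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import SpecValidationError

MA_DEFAULT = ("attended", "unattended")
TP_DEFAULT = ("NTP", "MTP", "VTP")

_LOCKINGS = ("first", "second")


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise SpecValidationError(f"{field_name}: {message}")


@dataclass(frozen=True)
class EvokedComponent:
    """A Gaussian-windowed monophasic deflection (e.g. an N1, N2 or P2).

    ``amplitude_uv`` is signed: negative values model negativities.  The peak
    latency is expressed relative to the component's locking stimulus; the
    simulator shifts first-locked components by the first-stimulus offset.
    """

    label: str
    peak_latency_s: float
    width_s: float
    amplitude_uv: float
    channel_weights: Mapping[str, float]
    locking: str = "second"
    amplitude_jitter_sd_uv: float = 0.0
    latency_jitter_sd_s: float = 0.0

    def validate(self, channels: Iterable[str]) -> None:
        name = f"EvokedComponent[{self.label}]"
        _require(self.width_s > 0, f"{name}.width_s", "must be > 0")
        _require(bool(self.channel_weights), f"{name}.channel_weights",
                 "must be nonempty")
        _require(self.locking in _LOCKINGS, f"{name}.locking",
                 f"must be one of {_LOCKINGS}")
        _require(self.amplitude_jitter_sd_uv >= 0,
                 f"{name}.amplitude_jitter_sd_uv", "must be >= 0")
        _require(self.latency_jitter_sd_s >= 0,
                 f"{name}.latency_jitter_sd_s", "must be >= 0")
        chans = set(channels)
        for ch, w in self.channel_weights.items():
            _require(ch in chans, f"{name}.channel_weights",
                     f"unknown channel {ch!r}")
            _require(0.0 <= w <= 1.0, f"{name}.channel_weights",
                     f"gain for {ch!r} must be in [0, 1]")


@dataclass(frozen=True)
class OscComponent:
    """A band-limited oscillation with von Mises phase locking.

    ``phase_concentration_kappa`` controls trial-to-trial phase concentration
    at the locking stimulus: kappa = 0 draws uniform phases (no phase
    locking), large kappa approaches perfect locking.  The expected
    inter-trial resultant length is I1(kappa)/I0(kappa).  The amplitude
    envelope is a boxcar over ``envelope`` with Gaussian-smoothed edges.
    """

    center_freq_hz: float
    amplitude_uv: float
    phase_concentration_kappa: float
    envelope: tuple[float, float]
    channel_weights: Mapping[str, float]
    locked_phase_rad: float = 0.0
    locking: str = "second"

    def validate(self, channels: Iterable[str], sampling_rate: float) -> None:
        name = f"OscComponent[{self.center_freq_hz:g}Hz]"
        _require(0 < self.center_freq_hz < sampling_rate / 2,
                 f"{name}.center_freq_hz", "must be in (0, Nyquist)")
        _require(self.phase_concentration_kappa >= 0,
                 f"{name}.phase_concentration_kappa", "must be >= 0")
        _require(self.envelope[0] < self.envelope[1], f"{name}.envelope",
                 "onset must precede offset")
        _require(self.locking in _LOCKINGS, f"{name}.locking",
                 f"must be one of {_LOCKINGS}")
        _require(bool(self.channel_weights), f"{name}.channel_weights",
                 "must be nonempty")
        chans = set(channels)
        for ch, w in self.channel_weights.items():
            _require(ch in chans, f"{name}.channel_weights",
                     f"unknown channel {ch!r}")
            _require(0.0 <= w <= 1.0, f"{name}.channel_weights",
                     f"gain for {ch!r} must be in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """1/f background noise: power ~ 1/f**exponent, broadband SD per channel."""

    noise_sd_uv: float = 0.0
    one_over_f_exponent: float = 1.0
    stream_id: int = 0

    def validate(self) -> None:
        _require(self.noise_sd_uv >= 0, "NoiseSpec.noise_sd_uv", "must be >= 0")
        _require(self.one_over_f_exponent >= 0,
                 "NoiseSpec.one_over_f_exponent", "must be >= 0")


@dataclass(frozen=True)
class BehaviorSpec:
    """Per-cell behavioral response distribution.

    RT is the interval between the second-stimulus onset (time zero) and the
    button press, drawn from a normal distribution truncated at
    ``rt_floor_s``; ``accuracy_prob`` is the per-trial probability of a
    correct response.
    """

    accuracy_prob: float = 1.0
    rt_mean_s: float = 0.4
    rt_sd_s: float = 0.06
    rt_floor_s: float = 0.0

    def validate(self) -> None:
        _require(0.0 <= self.accuracy_prob <= 1.0,
                 "BehaviorSpec.accuracy_prob", "must be in [0, 1]")
        _require(self.rt_sd_s >= 0, "BehaviorSpec.rt_sd_s", "must be >= 0")
        _require(self.rt_floor_s >= 0, "BehaviorSpec.rt_floor_s",
                 "must be >= 0")


@dataclass(frozen=True)
class CellSpec:
    """The generative content of one MA x TP cell; all lists may be empty."""

    evoked: tuple[EvokedComponent, ...] = ()
    oscillations: tuple[OscComponent, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)

    def validate(self, channels: Iterable[str], sampling_rate: float) -> None:
        for ev in self.evoked:
            ev.validate(channels)
        for osc in self.oscillations:
            osc.validate(channels, sampling_rate)
        self.noise.validate()
        self.behavior.validate()


@dataclass(frozen=True)
class DesignSpec:
    """Full generative description of a simulated dataset.

    Geometry defaults mirror the analyzed short-interval trials: 200 Hz
    sampling, epochs from -1.0 s to +0.8 s around the second stimulus, the
    first stimulus 400 ms earlier, six channels (three occipital, three
    frontal), 38 trials per cell.
    """

    cells: Mapping[tuple[str, str], CellSpec]
    ma_levels: tuple[str, ...] = MA_DEFAULT
    tp_levels: tuple[str, ...] = TP_DEFAULT
    n_subjects: int = 27
    n_trials_per_cell: int = 38
    sampling_rate: float = 200.0
    epoch_window: tuple[float, float] = (-1.0, 0.8)
    first_stim_offset_s: float = -0.4
    channels: tuple[str, ...] = ("O1", "OZ", "O2", "F1", "FZ", "F2")

    def __post_init__(self) -> None:
        self.validate()

    # -- geometry -----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        start, end = self.epoch_window
        return int(round((end - start) * self.sampling_rate))

    @property
    def t0_index(self) -> int:
        return int(round(-self.epoch_window[0] * self.sampling_rate))

    def times(self):
        import numpy as np

        n = self.n_samples
        return (np.arange(n) - self.t0_index) / self.sampling_rate

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        start, end = self.epoch_window
        _require(start < self.first_stim_offset_s < 0.0 < end,
                 "DesignSpec.epoch_window",
                 "must satisfy start < first_stim_offset_s < 0 < end")
        _require(self.sampling_rate > 0, "DesignSpec.sampling_rate",
                 "must be > 0")
        _require(self.n_subjects >= 1, "DesignSpec.n_subjects", "must be >= 1")
        _require(self.n_trials_per_cell >= 1, "DesignSpec.n_trials_per_cell",
                 "must be >= 1")
        _require(len(self.ma_levels) >= 1, "DesignSpec.ma_levels", "empty")
        _require(len(self.tp_levels) >= 1, "DesignSpec.tp_levels", "empty")
        _require(len(set(self.channels)) == len(self.channels),
                 "DesignSpec.channels", "labels must be unique")
        # the zero point must fall exactly on a sample
        frac = abs(start * self.sampling_rate - round(start * self.sampling_rate))
        _require(frac < 1e-6, "DesignSpec.epoch_window",
                 "start must be an integer number of samples before time zero")
        expected = {(ma, tp) for ma in self.ma_levels for tp in self.tp_levels}
        got = set(self.cells)
        missing = expected - got
        extra = got - expected
        _require(not missing, "DesignSpec.cells",
                 f"missing cell(s) {sorted(missing)}")
        _require(not extra, "DesignSpec.cells",
                 f"unknown cell(s) {sorted(extra)}")
        for key, cell in self.cells.items():
            cell.validate(self.channels, self.sampling_rate)

    def cell_order(self) -> list[tuple[str, str]]:
        return [(ma, tp) for ma in self.ma_levels for tp in self.tp_levels]

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "ma_levels": list(self.ma_levels),
            "tp_levels": list(self.tp_levels),
            "n_subjects": self.n_subjects,
            "n_trials_per_cell": self.n_trials_per_cell,
            "sampling_rate": self.sampling_rate,
            "epoch_window": list(self.epoch_window),
            "first_stim_offset_s": self.first_stim_offset_s,
            "channels": list(self.channels),
            "cells": {},
        }
        for (ma, tp), cell in self.cells.items():
            cd = asdict(cell)
            cd["evoked"] = [dict(e, channel_weights=dict(e["channel_weights"]))
                            for e in cd["evoked"]]
            for o in cd["oscillations"]:
                o["channel_weights"] = dict(o["channel_weights"])
                o["envelope"] = list(o["envelope"])
            d["cells"][f"{ma}/{tp}"] = cd
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignSpec":
        cells = {}
        for key, cd in d["cells"].items():
            ma, tp = key.split("/", 1)
            evoked = tuple(EvokedComponent(**e) for e in cd.get("evoked", []))
            oscs = tuple(
                OscComponent(**{**o, "envelope": tuple(o["envelope"])})
                for o in cd.get("oscillations", [])
            )
            noise = NoiseSpec(**cd.get("noise", {}))
            behavior = BehaviorSpec(**cd.get("behavior", {}))
            cells[(ma, tp)] = CellSpec(evoked=evoked, oscillations=oscs,
                                       noise=noise, behavior=behavior)
        return cls(
            cells=cells,
            ma_levels=tuple(d["ma_levels"]),
            tp_levels=tuple(d["tp_levels"]),
            n_subjects=int(d["n_subjects"]),
            n_trials_per_cell=int(d["n_trials_per_cell"]),
            sampling_rate=float(d["sampling_rate"]),
            epoch_window=tuple(d["epoch_window"]),
            first_stim_offset_s=float(d["first_stim_offset_s"]),
            channels=tuple(d["channels"]),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "DesignSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Packaged scenarios
# ---------------------------------------------------------------------------

_OCC = {"O1": 1.0, "OZ": 1.0, "O2": 1.0}
_FRONT = {"F1": 1.0, "FZ": 1.0, "F2": 1.0}


def _visual_cell(ma: str, tp: str, noise_sd: float) -> CellSpec:
    """One visual-modality MA x TP cell of the default scenario.

    Attended cells carry the programmed pattern: a violated prediction (VTP)
    shrinks the second-stimulus N1, enlarges the N2, and reduces theta phase
    concentration; unattended cells show no TP differences and a globally
    smaller N1 (attentional enhancement of N1 in attended cells).
    """
    attended = ma == "attended"
    n1_amp = {"NTP": -5.0, "MTP": -5.0, "VTP": -3.5}[tp] if attended else -3.0
    n2_amp = {"NTP": -1.0, "MTP": -1.0, "VTP": -3.0}[tp] if attended else -1.0
    theta_kappa = ({"NTP": 2.0, "MTP": 2.0, "VTP": 0.7}[tp]
                   if attended else 1.0)
    alpha_kappa = 1.2 if attended else 0.5
    beta_amp = ({"NTP": 2.5, "MTP": 2.5, "VTP": 1.2}[tp]
                if attended else 2.0)
    evoked = (
        EvokedComponent("N1_first", peak_latency_s=0.170, width_s=0.020,
                        amplitude_uv=-4.0, channel_weights=_OCC,
                        locking="first", amplitude_jitter_sd_uv=0.5,
                        latency_jitter_sd_s=0.008),
        EvokedComponent("N1_second", peak_latency_s=0.155, width_s=0.020,
                        amplitude_uv=n1_amp, channel_weights=_OCC,
                        locking="second", amplitude_jitter_sd_uv=0.5,
                        latency_jitter_sd_s=0.008),
        EvokedComponent("N2_second", peak_latency_s=0.250, width_s=0.030,
                        amplitude_uv=n2_amp, channel_weights=_OCC,
                        locking="second", amplitude_jitter_sd_uv=0.5,
                        latency_jitter_sd_s=0.010),
    )
    oscillations = (
        # theta phase reset after the second flash; kappa carries the TP
        # effect; amplitude sized so band-window ITC spans ~0.3-0.5 against
        # the 1/f background, the range seen in comparable recordings.
        # The locked phase makes the theta mean integrate to ~0 over the
        # 120-190 ms N1 window, so the N1 amplitude effect and the theta
        # phase-locking effect express in their own measures.
        OscComponent(center_freq_hz=6.0, amplitude_uv=6.0,
                     phase_concentration_kappa=theta_kappa,
                     locked_phase_rad=-1.131,
                     envelope=(0.03, 0.35), channel_weights=_OCC,
                     locking="second"),
        # alpha phase locking after the first flash; attention effect only
        OscComponent(center_freq_hz=10.0, amplitude_uv=2.0,
                     phase_concentration_kappa=alpha_kappa,
                     envelope=(0.05, 0.30), channel_weights=_OCC,
                     locking="first"),
        # induced (non-phase-locked) beta burst, 200-400 ms post-stimulus
        OscComponent(center_freq_hz=22.0, amplitude_uv=beta_amp,
                     phase_concentration_kappa=0.0,
                     envelope=(0.20, 0.40), channel_weights=_OCC,
                     locking="second"),
    )
    rt = {"NTP": 0.29195, "MTP": 0.44228, "VTP": 0.60658}[tp]
    acc = {"NTP": 0.999, "MTP": 0.982, "VTP": 0.912}[tp]
    behavior = BehaviorSpec(accuracy_prob=acc, rt_mean_s=rt, rt_sd_s=0.060,
                            rt_floor_s=0.080)
    return CellSpec(evoked=evoked, oscillations=oscillations,
                    noise=NoiseSpec(noise_sd_uv=noise_sd), behavior=behavior)


def _auditory_cell(ma: str, tp: str, noise_sd: float) -> CellSpec:
    """One auditory-modality cell: the matched prediction (MTP) enlarges the
    second-stimulus P2 and delta phase concentration in attended cells only."""
    attended = ma == "attended"
    p2_amp = {"NTP": 2.0, "MTP": 3.5, "VTP": 2.0}[tp] if attended else 2.0
    delta_kappa = ({"NTP": 0.8, "MTP": 1.8, "VTP": 0.8}[tp]
                   if attended else 0.8)
    theta_kappa = ({"NTP": 0.9, "MTP": 1.5, "VTP": 0.9}[tp]
                   if attended else 0.9)
    evoked = (
        EvokedComponent("P2_first", peak_latency_s=0.195, width_s=0.018,
                        amplitude_uv=3.0, channel_weights=_FRONT,
                        locking="first", amplitude_jitter_sd_uv=0.4,
                        latency_jitter_sd_s=0.008),
        EvokedComponent("P2_second", peak_latency_s=0.180, width_s=0.040,
                        amplitude_uv=p2_amp, channel_weights=_FRONT,
                        locking="second", amplitude_jitter_sd_uv=0.4,
                        latency_jitter_sd_s=0.010),
    )
    oscillations = (
        # the 1/f background is strongest at low frequencies, so the delta
        # component needs a large amplitude for paper-range ITC levels
        OscComponent(center_freq_hz=2.5, amplitude_uv=8.0,
                     phase_concentration_kappa=delta_kappa,
                     envelope=(0.10, 0.45), channel_weights=_FRONT,
                     locking="second"),
        OscComponent(center_freq_hz=6.0, amplitude_uv=5.0,
                     phase_concentration_kappa=theta_kappa,
                     envelope=(0.05, 0.25), channel_weights=_FRONT,
                     locking="second"),
    )
    rt = {"NTP": 0.30040, "MTP": 0.43548, "VTP": 0.56644}[tp]
    acc = {"NTP": 0.9996, "MTP": 0.9783, "VTP": 0.9383}[tp]
    behavior = BehaviorSpec(accuracy_prob=acc, rt_mean_s=rt, rt_sd_s=0.060,
                            rt_floor_s=0.080)
    return CellSpec(evoked=evoked, oscillations=oscillations,
                    noise=NoiseSpec(noise_sd_uv=noise_sd), behavior=behavior)


def paper_like_design(modality: str = "visual", n_subjects: int = 27,
                      n_trials_per_cell: int = 38,
                      noise_sd_uv: float = 10.0,
                      channels: tuple[str, ...] | None = None) -> DesignSpec:
    """The packaged default scenario with attention-gated TP effects.

    ``modality`` selects which programmed pattern the cells carry: ``visual``
    (N1 reduced / N2 enhanced / theta dephased under violated prediction,
    attended only) or ``auditory`` (P2 and delta phase concentration enlarged
    under matched prediction, attended only).
    """
    builder = {"visual": _visual_cell, "auditory": _auditory_cell}
    if modality not in builder:
        raise SpecValidationError(
            f"modality: must be 'visual' or 'auditory', got {modality!r}")
    cells = {(ma, tp): builder[modality](ma, tp, noise_sd_uv)
             for ma in MA_DEFAULT for tp in TP_DEFAULT}
    kwargs = {} if channels is None else {"channels": tuple(channels)}
    return DesignSpec(cells=cells, n_subjects=n_subjects,
                      n_trials_per_cell=n_trials_per_cell, **kwargs)


def null_design(n_subjects: int = 12, n_trials_per_cell: int = 20,
                noise_sd_uv: float = 10.0) -> DesignSpec:
    """A global-null scenario: all six cells are generatively identical."""
    evoked = (
        EvokedComponent("N1_second", peak_latency_s=0.155, width_s=0.020,
                        amplitude_uv=-4.0, channel_weights=_OCC,
                        locking="second", amplitude_jitter_sd_uv=0.5,
                        latency_jitter_sd_s=0.008),
    )
    oscillations = (
        OscComponent(center_freq_hz=6.0, amplitude_uv=3.0,
                     phase_concentration_kappa=1.0, envelope=(0.03, 0.35),
                     channel_weights=_OCC, locking="second"),
    )
    cell = CellSpec(evoked=evoked, oscillations=oscillations,
                    noise=NoiseSpec(noise_sd_uv=noise_sd_uv),
                    behavior=BehaviorSpec(accuracy_prob=0.97, rt_mean_s=0.40,
                                          rt_sd_s=0.060, rt_floor_s=0.080))
    cells = {(ma, tp): cell for ma in MA_DEFAULT for tp in TP_DEFAULT}
    return DesignSpec(cells=cells, n_subjects=n_subjects,
                      n_trials_per_cell=n_trials_per_cell)
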