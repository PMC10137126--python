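import numpy as np
import pandas as pd
import pytest

from tempogate.design import (CellSpec, DesignSpec, EvokedComponent,
                              NoiseSpec)
from tempogate.epochs import EpochSet, TRIAL_COLUMNS


def make_design(cell: CellSpec, n_trials: int = 8, channels=("O1",),
                n_subjects: int = 1, **kwargs) -> DesignSpec:
    """A design with the same CellSpec in every MA x TP cell."""
    cells = {(ma, tp): cell
             for ma in ("attended", "unattended")
             for tp in ("NTP", "MTP", "VTP")}
    return DesignSpec(cells=cells, n_subjects=n_subjects,
                      n_trials_per_cell=n_trials, channels=tuple(channels),
                      **kwargs)


def make_epochs(data: np.ndarray, sampling_rate: float = 200.0,
                t0_index: int | None = None, channels=None,
                ma: str = "attended", tp: str = "NTP") -> EpochSet:
    """Wrap a raw (trials, channels, samples) array in an EpochSet."""
    n_trials, n_ch, n_samp = data.shape
    if t0_index is None:
        t0_index = n_samp // 2
    if channels is None:
        channels = [f"C{i}" for i in range(n_ch)]
    info = pd.DataFrame(
        [("S01", ma, tp, t, True, 0.3) for t in range(n_trials)],
        columns=TRIAL_COLUMNS)
    return EpochSet(data=data, sampling_rate=sampling_rate,
                    t0_index=t0_index, channels=list(channels),
                    trial_info=info)


def sinusoid_epochs(freq_hz: float, n_trials: int, sampling_rate: float,
                    n_samples: int, rng: np.random.Generator,
                    amplitude=1.0, random_phase: bool = True) -> EpochSet:
    """Trials of a pure sinusoid, optionally with random phase per trial."""
    t = np.arange(n_samples) / sampling_rate
    phases = (rng.uniform(-np.pi, np.pi, n_trials) if random_phase
              else np.zeros(n_trials))
    amp = np.broadcast_to(np.asarray(amplitude, dtype=float),
                          (n_samples,))
    data = amp[None, None, :] * np.cos(
        2 * np.pi * freq_hz * t[None, None, :] + phases[:, None, None])
    return make_epochs(data, sampling_rate=sampling_rate)


@pytest.fixture
def rng():
    return np.random.default_rng(20230403)


@pytest.fixture
def quiet_cell():
    """One noise-free evoked component on a single channel."""
    comp = EvokedComponent("N1", peak_latency_s=0.155, width_s=0.020,
                           amplitude_uv=-5.0, channel_weights={"O1": 1.0})
    return CellSpec(evoked=(comp,), noise=NoiseSpec(noise_sd_uv=0.0))


def random_measure_table(rng: np.random.Generator, n_subjects: int,
                         ma_levels=("attended", "unattended"),
                         tp_levels=("NTP", "MTP", "VTP")) -> pd.DataFrame:
    rows = [(f"S{i:02d}", ma, tp, "m", rng.normal())
            for i in range(n_subjects) for ma in ma_levels
            for tp in tp_levels]
    return pd.DataFrame(rows, columns=["subject", "ma", "tp", "measure",
                                       "value"])
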