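"""ERSP: event-related spectral perturbation in dB against baseline.

A programmed doubling of post-stimulus power in the beta band should read
out as +10*log10(2) = +3.01 dB relative to the pre-first-stimulus baseline.
"""
import numpy as np
import pandas as pd

from tempogate import BandWindow, band_window_mean, ersp, morlet_decompose
from tempogate.epochs import EpochSet, TRIAL_COLUMNS

rng = np.random.default_rng(11)
fs, n_samp, n_trials = 200.0, 400, 24
t = (np.arange(n_samp) - n_samp // 2) / fs
gate = 1.0 + (np.sqrt(2) - 1.0) * ((t > 0.15) & (t < 0.45))  # power x 2
phases = rng.uniform(-np.pi, np.pi, n_trials)
data = gate[None, None, :] * np.cos(2 * np.pi * 20.0 * t[None, None, :]
                                    + phases[:, None, None])
info = pd.DataFrame([("S01", "attended", "NTP", k, True, 0.3)
                     for k in range(n_trials)], columns=TRIAL_COLUMNS)
e = EpochSet(data=data, sampling_rate=fs, t0_index=n_samp // 2,
             channels=["O1"], trial_info=info)

tf = morlet_decompose(e, np.arange(15.0, 31.0))
maps = ersp(tf, baseline_window_s=(-0.5, -0.4))
got = band_window_mean(maps, tf, BandWindow("beta", (0.25, 0.35)))
print(f"beta ERSP in the doubled window: {got:+.3f} dB "
      f"(expected {10 * np.log10(2):+.3f} dB)")
pre = band_window_mean(maps, tf, BandWindow("beta", (-0.30, -0.20)))
print(f"beta ERSP before the stimulus:   {pre:+.3f} dB (expected +0 dB)")
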