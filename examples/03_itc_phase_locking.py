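"""Inter-trial coherence recovers the programmed phase concentration.

Phases are drawn von Mises with concentration kappa; the expected resultant
length — and hence the asymptotic ITC at the oscillation's frequency — is
I1(kappa)/I0(kappa).
"""
import numpy as np
from scipy.special import i0, i1

from tempogate import BandWindow, band_window_mean, itc, morlet_decompose
from tempogate.design import (CellSpec, DesignSpec, NoiseSpec, OscComponent)
from tempogate.simulate import generate_subject_epochs

for kappa in (0.5, 2.0, 8.0):
    osc = OscComponent(center_freq_hz=6.0, amplitude_uv=2.0,
                       phase_concentration_kappa=kappa,
                       envelope=(0.03, 0.35), channel_weights={"O1": 1.0})
    cell = CellSpec(oscillations=(osc,), noise=NoiseSpec(noise_sd_uv=0.0))
    cells = {(ma, tp): cell for ma in ("attended", "unattended")
             for tp in ("NTP", "MTP", "VTP")}
    spec = DesignSpec(cells=cells, n_subjects=1, n_trials_per_cell=400,
                      channels=("O1",))
    e = generate_subject_epochs(spec, "S01", seed=3)
    sub = e.select_trials(e.cell_mask("attended", "NTP"))
    tf = morlet_decompose(sub, np.arange(4.0, 9.0))
    got = band_window_mean(itc(tf), tf, BandWindow("theta", (0.10, 0.28)))
    expected = i1(kappa) / i0(kappa)
    print(f"kappa = {kappa:4.1f}:  measured ITC = {got:.3f},  "
          f"I1/I0 = {expected:.3f}")

print("\nMeasured band-window ITC tracks the Bessel ratio; small deviations "
      "are the\nfinite-trial resultant bias (~sqrt(pi)/(2 sqrt(N)) floor).")
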