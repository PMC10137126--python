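"""Generate one subject's trial-epoched EEG and inspect its structure.

The packaged scenario is a 2 x 3 within-subject design — modality attention
(attended / unattended) crossed with timing prediction (NTP / MTP / VTP) —
with epochs locked to the second stimulus of each trial (time zero) and the
first stimulus 400 ms earlier.
"""
from tempogate import paper_like_design, generate_subject_epochs

spec = paper_like_design("visual", n_subjects=1, n_trials_per_cell=10)
epochs = generate_subject_epochs(spec, "S01", seed=42)

print(f"tensor: {epochs.data.shape} (trials x channels x samples)")
print(f"sampling rate: {epochs.sampling_rate:g} Hz, "
      f"epoch {epochs.times[0]:+.3f} .. {epochs.times[-1]:+.3f} s, "
      f"zero point at sample {epochs.t0_index}")
print(f"channels: {epochs.channels}")
print("\ntrials per cell:")
print(epochs.trial_info.groupby(["ma", "tp"]).size())

cell = epochs.select_trials(epochs.cell_mask("attended", "MTP"))
erp_peak = cell.data[:, 1, :].mean(axis=0).min()
print(f"\nattended-MTP average at OZ, most negative value: "
      f"{erp_peak:.2f} uV")
print("(the programmed second-stimulus N1 is -5 uV at the template peak; "
      "the average also carries theta/alpha activity and residual noise)")
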