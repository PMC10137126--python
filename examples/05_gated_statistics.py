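"""The interaction-gated testing scheme on theta-band ITC.

The full chain: simulate the attention-gated scenario, extract the 200-300 ms
theta band-window ITC per subject and condition, then run the gated
repeated-measures analysis — interaction first, simple effects of timing
prediction per attention level when it is significant, Bonferroni pairs.
"""
from tempogate.experiments import theta_itc_gated_run

outcome = theta_itc_gated_run(seed=12, n_subjects=12, n_trials_per_cell=20)
print(outcome.report.format())
print()
if outcome.attended_only_pattern:
    print("Pattern recovered: TP modulates theta ITC only when the "
          "modality is attended\n(interaction significant; simple effect "
          "present in attended, absent in unattended).")
else:
    print("Pattern not fully recovered in this run (see the report above).")
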