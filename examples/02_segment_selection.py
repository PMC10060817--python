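"""Cut ictal / interictal / control windows from annotated recordings.

Shows the three selection rules at work: the 5 s window centred on each
qualifying (>10 s) discharge, the 30 s window centred in each clean span
of at least 90 s, and the two earliest 30 s control windows.
"""

import dmnmeg as dm

config = dm.SyntheticConfig(
    n_patients=1, n_controls=1, epoch_length=60.0, n_epochs_per_subject=5, seed=11
)

for rec in dm.iter_cohort(config):
    rec = dm.notch_filter(rec)  # zero-phase 50 Hz (+harmonics) powerline removal
    if rec.group == "patient":
        ictal = dm.select_ictal(rec)
        interictal = dm.select_interictal(rec)
        print(f"{rec.subject_id} (patient): {len(rec.events('SWD'))} discharges")
        for seg in ictal + interictal:
            s, e = seg.source_span
            print(f"  {seg.condition:10s} [{s:7.1f}, {e:7.1f}) s  ({seg.duration:.0f} s)")
    else:
        print(f"{rec.subject_id} (control):")
        for seg in dm.select_control(rec):
            s, e = seg.source_span
            print(f"  {seg.condition:10s} [{s:7.1f}, {e:7.1f}) s  ({seg.duration:.0f} s)")
# Interictal windows keep > 30 s to the nearest discharge on both sides;
# control subjects contribute exactly two windows each (52 for 26 subjects).
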