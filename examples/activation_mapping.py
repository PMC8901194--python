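"""Estimate task activation with and without short-channel regression.

Processes one simulated run (motion correction, modified Beer-Lambert law,
0.015-0.35 Hz band-pass) and fits the GLM twice per channel: unregressed
(NR) and with all quality-passing short channels as non-negative nuisance
regressors (SCR).  Prints the ROI-averaged t-values — the activation map.
"""

import warnings

from nirscr import SimConfig, SubjectProfile, simulate_recording
from nirscr.pipeline import analyze_recording

warnings.filterwarnings("ignore")

cfg = SimConfig(seed=1)
profile = SubjectProfile(1, "strong", amplitude_uM=0.40,
                         mw_amplitude=1.0, raw_mean_intensity_v=0.25)
rec, truth = simulate_recording(profile, cfg, 1, 1)
result = analyze_recording(rec)

table = result["channel_table"]
o2 = table[table.chromophore == "o2hb"]
print("O2Hb t-values per ROI (rows: processing, columns: ROI 1..8):")
for cond in ("right", "left"):
    print(f"-- {cond} hand grasping --")
    for tag in ("NR", "SCR"):
        sub = o2[(o2.tag == tag) & (o2.condition == cond)]
        roi_t = sub.groupby("roi")["t"].mean()
        print(f"  {tag:3s}: " + " ".join(f"{roi_t[r]:7.1f}" for r in range(1, 9)))

print()
print("The contralateral M1 (ROI 1 for the right hand, ROI 5 for the left)")
print("shows the maximum; removing the shared scalp signal (SCR) raises t")
print("because the Mayer-wave and drift variance leaves the residuals.")
amp_est = o2[(o2.tag == "SCR") & (o2.condition == "right") & (o2.roi == 1)]["beta"].mean()
print(f"recovered ROI-1 amplitude: {amp_est:.3f} uM "
      f"(ground truth {truth['amplitudes']['right'][1]:.3f} uM)")
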