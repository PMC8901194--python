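"""Raw-signal screening and physiology metrics for two simulated subjects.

A subject with good optode coupling passes the 0.06 V screening threshold;
a subject with weak coupling (hair, placement) falls below it and the
detector noise dominates the hemoglobin estimates.  Both are screened with
the same report: mean raw intensity, SNR, short-channel cardiac quality and
the Mayer-wave amplitude.
"""

import warnings

from nirscr import (SimConfig, SubjectProfile, quality_report,
                    simulate_recording)
from nirscr.preprocess import intensity_to_od, od_to_hemoglobin

warnings.filterwarnings("ignore")

cfg = SimConfig(seed=2)
profiles = {
    "good optics": SubjectProfile(1, "strong", 0.40, 1.0, 0.25),
    "weak optics": SubjectProfile(2, "weak", 0.10, 1.0, 0.04),
}
for label, prof in profiles.items():
    rec, _ = simulate_recording(prof, cfg, 1, 1)
    hemo = od_to_hemoglobin(intensity_to_od(rec))
    rep = quality_report(rec, hemo)
    long_idx = rec.montage.long_indices
    print(f"{label}:")
    print(f"  mean raw intensity {rep.mean_intensity_v[long_idx].mean():.3f} V "
          f"-> screening {'PASS' if rep.screening_pass else 'FAIL'} "
          f"(0.06 V threshold); rest-window SNR "
          f"{rep.snr_db[long_idx].mean():.1f} dB incl. physiology")
    print(f"  short channels passing the 12 dB cardiac check: "
          f"{100 * rep.short_pass_rate:.0f}%")
    print(f"  Mayer-wave amplitude (0.07-0.14 Hz / 0.6-2 Hz power): "
          f"{rep.mayer_amplitude:.2f}")
print("Subjects failing the screening are expected to show weak activation;")
print("the band-power ratio flags strong ~0.1 Hz systemic oscillations.")
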