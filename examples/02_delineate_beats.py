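"""Wavelet R-peak detection and fiducial delineation of one record.

Shows the two-signal convention: the baseline-corrected signal drives
delineation (its zero level anchors the J/I zero-crossing searches), the
lightly filtered signal is what levels are measured on.
"""

import numpy as np

from cardiosense import (NoiseConfig, detect_r_peaks, generate_record,
                         heart_rate, locate_fiducials, preprocess)

rec = generate_record("NORMAL", 15, noise=NoiseConfig(seed=2),
                      mean_bpm=72, rr_jitter=0.04)
x = preprocess(rec.samples, rec.fs)
r = detect_r_peaks(x, rec.fs)
truth = np.array([a.sample_index for a in rec.annotations])

print(f"detected {len(r)} of {len(truth)} beats; "
      f"worst R localization error "
      f"{1000 * np.max(np.abs(r - truth)) / rec.fs:.1f} ms")
print(f"heart rate {heart_rate(r, rec.fs):.1f} bpm (generator used 72)")

fids = locate_fiducials(x, rec.fs, r)
fid = next(f for f in fids if f.complete)
ms = lambda i: 1000 * (i - fid.r) / rec.fs  # noqa: E731
print("one beat, fiducials in ms relative to R "
      "(P-H-I before the QRS, J-K the ST segment, T the repolarization peak):")
print("  " + "  ".join(f"{name}={ms(getattr(fid, name)):+.0f}"
                       for name in "phiqsjkt"))
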