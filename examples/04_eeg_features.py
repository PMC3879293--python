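"""EEG feature extraction: band-pass, one-vs-rest CSP, and band PSD.

Builds synthetic 4-class, 22-channel oscillatory trials, runs the
motor-imagery feature recipe (5-30 Hz band-pass, OVR-CSP with 3 filters
per end), and the 8-channel PSD recipe (8-30 Hz, 2 Hz bins, last second).
"""

import numpy as np

from evicomb import (TrialSet, butterworth_bandpass, csp_features,
                     fit_csp_ovr, make_synthetic_trials, psd_features)

trials, truth = make_synthetic_trials(
    n_classes=4, n_channels=22, fs=250.0, duration_s=2.0,
    n_trials_per_class=8, seed=0)
trials = butterworth_bandpass(trials, 5.0, 30.0, order=6)
model = fit_csp_ovr(trials, m=3)
feats = csp_features(model, trials.trials[0])
print(f"CSP: {model.filters.shape[0]} spatial filters "
      f"({len(model.classes)} classes x 2m, m={model.m}) -> "
      f"{len(feats)}-dimensional feature vector per trial")

rng = np.random.default_rng(0)
psd_trials = TrialSet(rng.standard_normal((3, 8, 1024)), fs=512.0,
                      labels=np.array([1, 2, 3]))
psd = psd_features(psd_trials, band=(8.0, 30.0), resolution_hz=2.0,
                   window_s=1.0)
print(f"PSD: 8 channels x 12 bins -> {psd.shape[1]}-dimensional vector")
# 24 CSP features and 96 PSD dimensions are the standard sizes for the
# 4-class motor-imagery and 3-class centroparietal recipes respectively.
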