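"""Label a window by the three-way ground-truth assessment.

Combines three observers' 0/1/2 scores, an EEG drowsiness ratio
(P_alpha + P_theta) / P_beta computed from a synthetic single-channel
recording, and a Stanford Sleepiness Scale self-report.  The window enters
the ground-truth set only when all three assessments agree.
"""

import numpy as np

from drowsefuse.assessment import (
    EEGWindow,
    ObserverScores,
    consensus,
    eeg_classify,
    observer_consensus,
    sss_classify,
)

fs = 128.0
t = np.arange(int(20 * fs)) / fs
# drowsy EEG: strong theta (6 Hz) and alpha (10 Hz), weak beta (18 Hz)
eeg = 3 * np.sin(2 * np.pi * 6 * t) + 3 * np.sin(2 * np.pi * 10 * t) \
    + 0.5 * np.sin(2 * np.pi * 18 * t)

obs = observer_consensus(ObserverScores((2, 2, 2)))
ratio, eeg_state = eeg_classify(EEGWindow(eeg, fs))
sss = sss_classify(6)

print(f"observer consensus : {obs.name}  (scores 2,2,2 -> floor(6/3) = 2)")
print(f"EEG ratio          : {ratio:.1f} -> {eeg_state.name}  (>= 4 means SF)")
print(f"self-report SSS 6  : {sss.name}")
label = consensus(obs, eeg_state, sss)
print("window label       :", label.name if label else "removed (no unanimity)")
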