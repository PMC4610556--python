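"""Extract the eight windowed fatigue features from raw synthetic streams.

Builds a 5-minute synthetic driving session (camera frames + vehicle
samples), cuts it into 60 s recognition windows, and prints the feature
table.  Fractions (bf, ecd, yf, pns, fald) lie in [0, 1]; meol is the mean
eyelid aperture in pixels; sdsa/sdvs are population SDs in degrees / km/h.
"""

from drowsefuse.synthetic_data import SimConfig, generate_session

session = generate_session(SimConfig(seed=42, session_windows=5))
print(session.feature_table.round(3).to_string(index=False))
print()
print("true states per window:", [s.name for s in session.states])
print("higher bf/ecd/yf/pns/fald and lower meol/sdsa indicate deeper fatigue.")
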