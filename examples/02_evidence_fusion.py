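"""Fuse two pieces of fatigue evidence with the conflict-gated Dempster rule.

Replays the published worked-example sample 3: the raw outputs of the facial
and vehicle fuzzy networks are normalised into basic probability assignments
over {NF, MF, SF}, their conflict degree K is computed, and they are fused.
Low K keeps the plain Dempster rule; K at or above the gate (default 0.9)
would trigger belief-factor discounting toward total ignorance first.
"""

from drowsefuse.evidence_fusion import bpa_from_outputs, combine_with_correction
from drowsefuse.synthetic_data import fixtures

wx = fixtures()
facial_raw, vehicle_raw = wx.network_outputs[2]  # worked-example sample 3

m1 = bpa_from_outputs(facial_raw)
m2 = bpa_from_outputs(vehicle_raw)
print("facial evidence  m1 =", tuple(round(v, 3) for v in m1.singletons))
print("vehicle evidence m2 =", tuple(round(v, 3) for v in m2.singletons))

fused, report = combine_with_correction(m1, m2)
print(f"conflict degree K = {report.K:.3f}  (corrected: {report.corrected})")
print("fused mass (NF, MF, SF) =", tuple(round(float(v), 3) for v in fused.singletons))
print()
print("the fused MF mass exceeds both inputs' MF masses: agreement between")
print("sources sharpens the assignment, which is what Dempster's rule does.")
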