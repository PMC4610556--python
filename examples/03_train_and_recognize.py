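"""Train both fuzzy networks and recognize a full synthetic session.

Trains the 3-input facial and 4-input vehicle networks on a 360-row
per-state Gaussian feature table (subtractive clustering fixes the rule
count, particle-swarm optimisation fits centers/widths/weights), then runs
the recursive two-level fusion over a 20-window session and compares the
decisions with the generator's ground truth.  Takes ~10 s.
"""

import numpy as np

from drowsefuse.recognizer import FatigueState, run_session, train_bundle
from drowsefuse.synthetic_data import SimConfig, generate_session, generate_training_table
from drowsefuse.tsfnn import TrainConfig

table, targets = generate_training_table(120, SimConfig(seed=7))
bundle = train_bundle(table, targets, train_cfg=TrainConfig(seed=3, max_iters=2000))
for name, model in (("facial", bundle.facial_model), ("vehicle", bundle.vehicle_model)):
    meta = model.train_meta
    print(f"{name}: {model.structure.m} rules, "
          f"fitness {meta['final_fitness']:.2e} after {meta['iterations']} iterations")

session = generate_session(SimConfig(seed=11, session_windows=20))
result = run_session(session.feature_table, bundle)
truth = [FatigueState(int(s)).name for s in session.feature_table["state"]]
acc = np.mean([a == b for a, b in zip(result["decision"], truth)])
print()
print(result[["window_start", "m_nf", "m_mf", "m_sf", "K_first", "decision"]]
      .round(3).to_string(index=False))
print()
print(f"decisions match the generator's true state in {acc:.0%} of windows;")
print("disagreements cluster at state transitions, where the temporal fusion")
print("holds the previous decision for one window.")
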