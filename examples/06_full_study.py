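"""The full pipeline on the scaled study replica (runs ~3-4 minutes).

Simulates 12 responders + 9 non-responders x 3 sessions with opposite
alpha/beta connectivity changes and differently timed coarse-scale
complexity decreases, runs group PLS-SVD (omnibus + per-group follow-ups),
individual non-rotated PLS, and prints the group-to-individual similarity
summary.
"""

import json

import eegpls as e
from eegpls.pipeline import scaled_study_config

res = e.run_study(scaled_study_config(seed=1))
j = res["json"]

print("group analyses (omnibus LV1):")
for name, block in j["group"].items():
    omni = block["omnibus_lv1"]
    print(f"  {name}: p = {omni['p']:.4f}, PCCE = {omni['pcce']:.1f}%, "
          f"interaction gate = {block['gate']}")
    for g, fu in block["followups"].items():
        print(f"    follow-up {g}: p = {fu['lv1']['p']:.4f} "
              f"(significant at .025: {fu['significant']})")

print()
print("group-to-individual similarity (percent of participants):")
print(json.dumps(j["similarity"], indent=1))
print()
print("'moderate_strong' = individual singular image correlates r >= .4 with"
      " the own-group pattern;")
print("'own_only' = rule-based rating matched the own group's criteria"
      " exclusively.")
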