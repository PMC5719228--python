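"""Construct the case/control cohort from ADT data and the event stream.

Finds floor-to-ICU transfers, applies the five unplanned-transfer criteria
and the CDE window, enforces the 8 h / 24 h floor-time filters, and samples
age/diagnosis-matched controls at roughly 1:5.
"""

import icuward as iw

cfg = iw.GeneratorConfig(n_case_encounters=40, n_control_encounters=250,
                         seed=11)
encounters, events, _ = iw.generate(cfg)

candidates = iw.extract_candidate_transfers(encounters.adt)
cohort = iw.build_cohort(encounters, events, ratio=5.0, seed=11)

cases = cohort[cohort["label"] == "case"]
controls = cohort[cohort["label"] == "control"]
print(f"candidate floor->ICU transfers: {len(candidates)}")
print(f"cases (>=1 criterion fired):    {len(cases)}")
print(f"  CDE subgroup:                 {int(cases['cde'].sum())}")
print("  criterion counts:",
      {c: int(cases[c].sum()) for c in ("c1", "c2", "c3", "c4", "c5")})
print(f"controls selected:              {len(controls)} "
      f"(ratio {len(controls) / len(cases):.1f}:1)")
# c1..c5 = respiratory support, vasopressor, fluid bolus >= 20 mL/kg,
# emergent procedure, ICU-only medication, all in [transfer-2h, +12h].
# Candidates without any intervention are planned transfers and drop out.
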