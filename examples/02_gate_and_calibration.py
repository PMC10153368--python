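"""Screening gate: defaults, calibration from a reference panel, ranking.

Generates a synthetic 15-drug reference panel (6 acceptable, mimicking the
calibration input of the screen), calibrates gate thresholds from the
acceptable subset, then gates and ranks a handful of synthetic candidates.
"""

from bpascreen import (
    SimConfig,
    apply_gate,
    calibrate,
    default_candidate_gate,
    gen_reference_panel,
    rank_candidates,
)

panel = gen_reference_panel(SimConfig(seed=20230420))
print(f"reference panel: {len(panel)} drugs, {int(panel['acceptable'].sum())} acceptable")

thresholds = calibrate(panel, quantile_policy="range")
print(f"calibrated gate: hERG<{thresholds.herg_max:.2f}  -logS<{thresholds.neg_logs_max:.2f}  "
      f"MPO>{thresholds.cns_mpo_min:.2f}  BBB in [{thresholds.bbb_min:.2f},{thresholds.bbb_max:.2f}]")

default = default_candidate_gate()
print(f"published gate:  hERG<{default.herg_max}  -logS<{default.neg_logs_max}  "
      f"MPO>{default.cns_mpo_min}  BBB in [{default.bbb_min},{default.bbb_max}]  "
      f"MPA<{default.mpa_max}")

candidates = [
    {"compound_id": "lead", "herg_pic50": 5.0, "neg_logs": 6.8, "cns_mpo": 3.71,
     "bbb_score": 4.5, "mpa": 55.0},
    {"compound_id": "cardiotoxic", "herg_pic50": 5.8, "neg_logs": 6.0, "cns_mpo": 3.5,
     "bbb_score": 4.2, "mpa": 50.0},
    {"compound_id": "bulky", "herg_pic50": 5.0, "neg_logs": 6.0, "cns_mpo": 3.2,
     "bbb_score": 4.1, "mpa": 65.0},
]
results = [apply_gate(c, default) for c in candidates]
ranked = rank_candidates(results, {c["compound_id"]: c for c in candidates})
print("\nranked verdicts (pass first, by CNS-MPO then BBB):")
print(ranked[["compound_id", "verdict", "cns_mpo", "bbb_score"]].to_string(index=False))
print("\n'cardiotoxic' fails only the hERG bound, 'bulky' only the MPA bound;"
      "\nimproving any single criterion can never flip a pass into a fail.")
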