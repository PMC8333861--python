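"""Deterministic base case: discounted totals, increments and dominance.

Loads the packaged parameter sheet (10 annual cycles, 5% discount on
costs and QALYs, calibrated starting HD/PD split), traces both treatment
strategies through the cohort model and prints the incremental
comparison.  A "dominant" classification means the intervention is both
cheaper and more effective, so no cost-per-QALY ratio is meaningful.
"""

from shpt_cea import paper_fixture, run_base_case

config = paper_fixture()
result = run_base_case(config)

print(f"intervention ({result.intervention_label}):")
print(f"  total discounted cost : {result.cost_intervention:14.3f} yuan")
print(f"  total discounted QALYs: {result.qalys_intervention:14.4f}")
print(f"comparator ({result.comparator_label}):")
print(f"  total discounted cost : {result.cost_comparator:14.3f} yuan")
print(f"  total discounted QALYs: {result.qalys_comparator:14.4f}")
print(f"incremental cost        : {result.delta_cost:14.3f} yuan (negative = saving)")
print(f"incremental QALYs       : {result.delta_qalys:14.4f}")
print(f"classification          : {result.dominance}")
print(f"iNMB at WTP {result.wtp:.0f}  : {result.inmb:14.2f} yuan")
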