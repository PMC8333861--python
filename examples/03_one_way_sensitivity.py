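"""One-way sensitivity analysis (tornado ordering).

Each parameter with a published range is set to its low and high bound
in turn, the deterministic pipeline is re-run, and the incremental net
monetary benefit at the configured willingness-to-pay is recorded.  The
spread |high - low| ranks parameters by influence; the top bar is the
cinacalcet price, whose -52% tender-rule lower bound moves the
comparator's drug bill the most.
"""

from shpt_cea import paper_fixture, run_owsa, tornado_frame

config = paper_fixture()
entries = run_owsa(config, outcome="inmb")

df = tornado_frame(entries)[["parameter_id", "outcome_at_low",
                             "outcome_at_high", "spread"]]
print(df.to_string(index=False, float_format=lambda v: f"{v:12.1f}"))
print(f"\nmost influential parameter: {entries[0].parameter_id}")
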