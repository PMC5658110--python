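"""Base case: lifetime cost and QALYs of each arm for one cohort.

Builds the bundled mid-50s scenario (printed unit costs, reconstructed
clinical probabilities), runs both treatment arms over the 16-year likely
horizon, and compares them.
"""

from mddcea import PHARMA, RTMS, ScenarioSpec, compare_strategies, generate_parameter_set, run_strategy

ps = generate_parameter_set(ScenarioSpec(seed=0, cohort="mid-50s"))

for label in (RTMS, PHARMA):
    o = run_strategy(ps, label)
    print(f"{label:16s} lifetime cost ${o.cost:10,.0f}   lifetime QALYs {o.qaly:5.2f}")

res = compare_strategies(ps)
print(f"\nincrement (rTMS - pharmacotherapy): dC = ${res.delta_cost:+,.0f}, "
      f"dQ = {res.delta_qaly:+.2f} QALYs -> {res.dominance}")
print("A negative dC with positive dQ would mean rTMS saves money AND adds "
      "quality-adjusted life years (dominance); a positive/positive pair is a "
      "trade-off priced by the ICER.")
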