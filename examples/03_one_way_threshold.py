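"""One-way sensitivity analysis with threshold finding.

Varies one parameter at a time over its declared range and locates the
value at which the preferred (less costly, at willingness-to-pay 0)
strategy flips, by bisection on the net-monetary-benefit difference.
"""

from mddcea import ScenarioSpec, generate_parameter_set, one_way_threshold

ps = generate_parameter_set(ScenarioSpec(seed=0, cohort="mid-50s"))

for name in ("cost_per_rtms_session", "drug_cost_monthly", "rtms_sessions_per_year"):
    p = ps.parameters[name]
    res = one_way_threshold(ps, name)
    where = f"{res.threshold:,.1f}" if res.threshold is not None else "no flip"
    print(f"{name:25s} range [{p.low:g}, {p.high:g}] {p.units:22s} "
          f"threshold = {where}  ({res.direction})")

print("\nBelow the per-session threshold (or above the monthly drug-cost "
      "threshold) rTMS is the less costly lifetime strategy for this cohort.")
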