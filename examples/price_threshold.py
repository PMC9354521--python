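"""How deep a price cut would make the immunotherapy cost-effective?

Searches for the smallest multiplicative reduction of the nivolumab and
ipilimumab per-cycle acquisition costs that brings the ICER down to the
willingness-to-pay threshold, then shows the tornado's most influential
parameters from the one-way sensitivity analysis.
"""

from mesocea import base_case, default_parameter_specs, one_way_sweep

model = base_case()

r, icer_at_r = model.find_price_threshold()
print(f"price reduction needed: {r:.1%}")
print(f"ICER at that price:     ${icer_at_r:,.2f} per QALY "
      f"(threshold ${model.wtp.wtp_per_qaly:,.0f})")

print("\ntop one-way sensitivity drivers (ICER spread over +-20% swings):")
for e in one_way_sweep(default_parameter_specs(model), model)[:5]:
    print(f"  {e.parameter:42s} spread ${e.spread:>12,.0f}")
# Each spread is |ICER(high) - ICER(low)|: how far that single input can move
# the decision statistic while everything else stays at base value.
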