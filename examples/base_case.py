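"""Run the base-case cost-effectiveness comparison.

Builds the shipped decision model (nivolumab + ipilimumab vs
platinum-pemetrexed chemotherapy, 3-week cycles over 10 years, 3% annual
discount) and prints discounted totals per arm plus the incremental
comparison against the $207,659/QALY willingness-to-pay threshold.
"""

from mesocea import WTPContext, base_case, is_cost_effective

model = base_case()
out = model.run()

for arm in (out.comparator, out.intervention):
    print(
        f"{arm.name:22s} cost ${arm.cost:>12,.2f}   "
        f"LY {arm.ly:.4f}   QALY {arm.qaly:.4f}"
    )

inc = out.incremental
print(f"\nincremental cost  ${inc.delta_cost:,.2f}")
print(f"incremental QALYs  {inc.delta_qaly:.4f}")
print(f"ICER              ${inc.icer_per_qaly:,.2f} per QALY")

wtp = WTPContext()
verdict = "IS" if is_cost_effective(inc, wtp) else "is NOT"
print(
    f"\nAt ${wtp.wtp_per_qaly:,.0f}/QALY the immunotherapy combination "
    f"{verdict} cost-effective."
)
# The ICER is the extra spend per quality-adjusted life-year gained; it is
# compared with the willingness-to-pay threshold to reach the verdict.
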