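"""Probabilistic sensitivity analysis with an acceptability curve.

Redraws every uncertain input (costs ~ gamma, probabilities/utilities ~
beta, all moment-matched to base value +- 20% SD) 2,000 times, re-runs both
arms per draw, and reports the probability the immunotherapy combination is
cost-effective across willingness-to-pay values.
"""

import numpy as np

from mesocea import WTPContext, base_case, ceac_curve, default_parameter_specs, psa_run

model = base_case()
psa = psa_run(default_parameter_specs(model), model, n=2000, seed=7)

wtp = WTPContext()
p_ce = psa.nmb_positive_fraction(wtp)
print(f"P(cost-effective at ${wtp.wtp_per_qaly:,.0f}/QALY) = {p_ce:.4f}")
print(f"mean incremental cost ${psa.delta_cost.mean():,.0f}, "
      f"mean incremental QALYs {psa.delta_qaly.mean():.4f}")

print("\nacceptability curve:")
for w, p in ceac_curve(psa, np.arange(0.0, 4.5e6, 0.5e6)):
    print(f"  WTP ${w:>12,.0f}  P(cost-effective) = {p:.3f}")
# The curve reports, at each threshold, the fraction of parameter draws in
# which paying that much per QALY would favour the immunotherapy arm.
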