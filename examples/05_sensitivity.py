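"""Uncertainty: one-way tornado and probabilistic sensitivity analysis.

The tornado re-runs the model at each parameter's published low/high bound;
the PSA draws 1,000 parameter vectors (beta for utilities/rates, lognormal
for costs/HRs) and summarises decision uncertainty as acceptability curves.
"""
import numpy as np

import oncocea as oc

config = oc.load_table1()

tornado = oc.one_way_dsa(config, ("atezolizumab", "nivolumab"))
print("tornado (atezolizumab vs nivolumab), widest bars first:")
print(tornado.head(6).to_string(index=False))

spec = oc.default_psa_spec(config, n_draws=1000, seed=7)
psa = oc.run_psa(config, spec)
grid = np.linspace(0, 200_000, 21)
curves = oc.ceac(psa.costs, psa.qalys, grid, psa.strategies)
at_wtp = oc.ceac(psa.costs, psa.qalys, [config.wtp_threshold], psa.strategies)

print("\nCEAC (probability each strategy is optimal):")
print(curves.to_frame().to_string(index=False, float_format=lambda x: f"{x:.3f}"))
p = float(at_wtp.probabilities["nivolumab"].iloc[0])
print(
    f"\nAt ${config.wtp_threshold:,.0f}/QALY nivolumab is optimal in {p:.1%} of "
    "draws: the hazard-ratio and cost uncertainty is nowhere near large enough "
    "to overturn the base-case ranking at the Chinese threshold."
)
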