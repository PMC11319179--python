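"""Generate a synthetic parameter bundle, write it to disk and reload it.

The bundle holds everything one setting (urban or rural) needs: prevalence
of undiagnosed type 2 diabetes, the three screening tests' accuracy and
per-test costs, age-banded transition probabilities, annual state costs,
utility weights, hazard ratios, discounting and the WTP threshold.
"""

from screencea import load_parameters, write_parameters
from screencea.synthetic import SyntheticSpec, generate_parameter_set

params = generate_parameter_set(SyntheticSpec(seed=1, setting="urban"))
write_parameters(params, "/tmp/urban_params.json")
reloaded = load_parameters("/tmp/urban_params.json")
assert reloaded == params  # files round-trip exactly

print(f"setting:     {params.setting.label}")
print(f"prevalence:  {params.setting.prevalence:.4f}  (undiagnosed T2DM)")
for s in params.strategies:
    print(f"{s.name:14s} Se={s.sensitivity:.3f} Sp={s.specificity:.3f} "
          f"per-test ${s.cost_per_test:.2f}")
print(f"transitions: {len(params.transitions.entries)} entries over "
      f"{params.transitions.n_bands} age bands")
print(f"WTP:         ${params.wtp.value:,.0f}/QALY "
      f"({params.wtp.multiplier} x ${params.wtp.gdp_per_capita:,.0f} GDP per capita)")
# Each strategy line shows how well the test separates diabetic from
# non-diabetic screenees and what one administration costs society.
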