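"""Run the three-strategy base case on a synthetic trial and print ICERs.

Generates a synthetic digitized trial (chemotherapy and nivolumab+
ipilimumab arms; the combination arm derived through hazard ratios),
calibrates, simulates the lifetime cohort, and prints the comparison
table: discounted cost, life-years, QALYs and frontier ICERs per arm.
"""
import nsclc_cea as m

spec = m.SyntheticTrialSpec(arms=m.scenario_curves("all"), enrollment=1000,
                            mode="exact", seed=1)
trial = m.gen_trial(spec)
config, _ = m.gen_param_set()

result = m.run_base_case(config, trial)
table = result.comparison.to_frame()
print(table.to_string(index=False, float_format=lambda x: f"{x:,.2f}"))
# total_cost is discounted USD per patient; ly/qaly are discounted
# life-years and quality-adjusted life-years.  icer_per_qaly is the cost of
# one additional QALY moving up the efficient frontier; a dominance label
# replaces it for strategies off the frontier.
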