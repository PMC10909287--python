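"""Catchment-level July vs January comparison with spatial statistics.

Runs the vacation scenario (July outflow from the urban core to the
coastal ring, Poisson observation noise) and prints per-level catchment
differences, Moran's I clustering tests and the ANOVA/Tukey comparison
between hospital levels.
"""

from dynaccess import run_pipeline
from dynaccess.config import PipelineConfig, vacation_scenario

result = run_pipeline(PipelineConfig(simulate=vacation_scenario(seed=1), seed=1))

for (month, hour), summ in sorted(result.catchment_summaries.items()):
    name = {1: "January", 7: "July"}[month]
    means = summ.groupby("level")["diff_pct"].mean().round(1).to_dict()
    print(f"{name} {hour}:00  mean catchment diff_pct by ED level: {means}")

for (month, hour), mres in sorted(result.moran.items()):
    name = {1: "January", 7: "July"}[month]
    print(f"{name}: Moran's I = {mres.I:.2f} "
          f"(expected {mres.expected:.3f}), permutation p = {mres.p_permutation:.3f}")

ares = result.anova[(7, 13)]
print(f"July ANOVA across ED levels: F({ares.df_between},{ares.df_within}) "
      f"= {ares.F:.2f}, p = {ares.p:.2g}")
for pair in result.tukey[(7, 13)]:
    print(f"  Tukey level {pair.group_a} vs {pair.group_b}: "
          f"{pair.difference:+.1f} ± {pair.half_width:.1f} pct points, "
          f"p = {pair.p_adjusted:.3f}")

print("\nPositive diff_pct = residential data overestimate the share present")
print("(urban catchments in July); negative = underestimate (coastal ones).")
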