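"""Travel shares and distances from a synthetic birth registry.

Generates a small two-year scenario, computes municipal access summaries
and aggregates them birth-weighted to state and national level.
"""

from natalflow import ScenarioConfig, aggregate, muni_access, simulate_scenario

scenario = simulate_scenario(ScenarioConfig(n_munis=80, n_states=4, seed=42))
print(f"{len(scenario.births)} births, {len(scenario.munis)} municipalities\n")

table = muni_access(scenario.births, scenario.dmat)
national = aggregate(table, "national")
print("National access summaries (F = share of travelers, C = km conditional")
print("on traveling, D = F x C = unconditional km over all births):\n")
print(national[["year", "n_births", "f", "c", "d"]].round(3).to_string(index=False))

states = aggregate(table, "state", scenario.region_map)
year = scenario.config.years[-1]
print(f"\nPer-state, {year} (note D = F x C holds exactly at every level):\n")
print(
    states[states["year"] == year][["unit", "n_births", "f", "c", "d"]]
    .round(3)
    .to_string(index=False)
)
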