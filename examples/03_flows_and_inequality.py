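"""Referral flows, health-region exits and distance inequality.

Origin-destination flows reveal the hub-and-spoke referral network; the
departure and arrival shares use different denominators (resident births
vs births occurring in the town); the Gini index summarises how unequal
municipal trip lengths are within each state.
"""

from natalflow import (
    ScenarioConfig,
    gini_conditional_distance,
    muni_access,
    muni_flow_stats,
    od_flows,
    region_exit_share,
    simulate_scenario,
)

scenario = simulate_scenario(ScenarioConfig(n_munis=80, n_states=4, seed=42))
year = scenario.config.years[-1]

flows = od_flows(scenario.births, year=year)
top = flows[~flows["is_self"]].nlargest(5, "count")
print("Five busiest origin->destination referral flows:")
print(top[["origin", "destination", "count", "share_of_origin"]]
      .round(3).to_string(index=False))

stats = muni_flow_stats(flows)
receivers = stats.nlargest(3, "arrivals")
print("\nBiggest receiving hubs (arrival share = imported deliveries /")
print("deliveries occurring there):")
print(receivers[["muni", "births_occurring", "arrivals", "arrival_share"]]
      .round(3).to_string(index=False))

exits = region_exit_share(scenario.births, scenario.region_map, year=year)
print("\nShare of travelers leaving their health region, by state:")
print(exits.round(3).to_string(index=False))

table = muni_access(scenario.births, scenario.dmat)
gini = gini_conditional_distance(table, scenario.region_map)
print("\nGini of municipal conditional distance (0 = every municipality's")
print("travelers go equally far; larger = distance burden is concentrated):")
print(gini[gini["year"] == year].round(3).to_string(index=False))
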