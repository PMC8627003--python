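"""Gut-community succession: two rearing sources converging over time.

Simulates a two-source experiment (species-poor flow-through vs species-rich
biofloc guts) that converges toward a shared recirculating-system community,
then runs the community statistics: rarefaction, alpha diversity, PERMANOVA,
SIMPER and the persistent core.
"""

from rearlegacy import (
    CommunityScenario,
    alpha_diversity,
    bray_curtis,
    core_membership,
    filter_and_rarefy,
    permanova,
    simper,
    simulate_asv_experiment,
)

scenario = CommunityScenario(
    n_asvs=80, fts_richness=30, bfs_richness=60, ras_richness=50,
    depth_range=(1000, 2500), fish_per_tank={15: 4, 63: 4, 105: 4},
    tanks_per_treatment=3, kappa={15: 0.0, 63: 0.75, 105: 0.9}, seed=5,
)
table, truth = simulate_asv_experiment(scenario)
depth = int(table.depths().min())
rarefied = filter_and_rarefy(table, min_depth=depth, target_depth=depth, seed=1)
print(f"{rarefied.n_samples} gut samples rarefied to {depth} reads\n")

cores = []
for t in (15, 63, 105):
    sub = rarefied.where(timepoint=t)
    alpha = alpha_diversity(sub)
    mean_rich = alpha.groupby(sub.metadata["system"])["richness"].mean()
    res = permanova(bray_curtis(sub), sub.grouping("system"), n_perm=999, seed=t)
    sim = simper(sub, "system")
    cores.append(core_membership(sub, "system").shared())
    print(f"day {t:3d}:  richness FTS {mean_rich['FTS']:5.1f}  BFS {mean_rich['BFS']:5.1f}"
          f"  | PERMANOVA p = {res.table['p_value'].iloc[0]:.3f}"
          f"  | SIMPER dissimilarity = {sim.overall:5.1f} %")

persistent = frozenset.intersection(*cores)
print(f"\nbetween-source dissimilarity falls as the communities converge;")
print(f"persistent core across all timepoints: {len(persistent)} ASVs "
      f"(planted: {len(truth.core_asvs)})")
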