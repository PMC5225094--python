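"""Simulate three weeks of rosette growth with the source-sink model.

Uses the default growth-chamber environment (8 h light at 350 umol
m^-2 s^-1, 21/18 degC) and prints the leaf count and the largest leaf
areas at the end of the run, plus the biomass budget.
"""

from rosettrack import Environment, GrowthParams, simulate

env = Environment.constant_photoperiod(21 * 24)
params = GrowthParams()
sim = simulate(params, env)

final = sim.hours[-1]
print(f"after {final} h: {sim.leaf_count(final)} leaves")
for rank in range(1, sim.leaf_count(final) + 1):
    print(f"  leaf {rank:2d}: {sim.area_at(rank, final):6.3f} cm^2")
total = sim.biomass[:, -1].sum()
print(f"total biomass {total:.4g} g "
      f"(= seed {params.seed_biomass:g} g + production "
      f"{sim.produced.sum():.4g} g)")
# Leaf areas are biomass / leaf-mass-per-area; the sum of all leaf
# biomasses equals the seed biomass plus every hour's production, a
# conservation identity of the allocation rule.
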