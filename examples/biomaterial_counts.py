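"""Cell counts around an implanted biomaterial (foreign body reaction).

Runs two 7-day simulations of a frozen PIM = 20 implant (14x14 pixels,
smoothed rim) with no resident macrophages, then counts macrophages and
fibroblasts in the twelve 3x3 collection areas stacked outward from the
implant (rank 1 farthest, rank 3 nearest), averaged over the runs.
"""

from mff import CountingGeometry, builtin_scenario, count_cells_in_areas, run
from mff.engine import ensemble_seeds

cfg = builtin_scenario("validation_biomat")   # 7 days by default
geometry = CountingGeometry(grid_n=cfg.params.grid_n,
                            implant_extent=cfg.pim_stimulus.extent)
tables = [count_cells_in_areas(run(cfg, s).final_state, geometry)
          for s in ensemble_seeds(3, 2)]
mean = sum(tables) / len(tables)
print(mean.round(1).to_string())
print("\nEach row sums the four same-rank areas (36 pixels). The "
      "implant vicinity (rank 3)\nstays nearly empty while cells "
      "populate the outer tissue; over 28 days fibroblasts\ntake the "
      "outer areas over, the in-silico fibrotic capsule.")
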