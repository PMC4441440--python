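"""Grow a small accretion epithelium and census its polygon classes.

Builds a sphere sized for 14 mature cells, lets cells arrive and grow to
99% coverage, and prints the neighbor-class census.  In a complete
accretion tissue the classes concentrate on 5-7 neighbors with hexagons
the most common shape.
"""
from epigrain import SimulationConfig, run_simulation

config = SimulationConfig(scenario="accretion", target_cell_count=14,
                          cell_limit=14, accretion_n_seed=8, rng_seed=7,
                          max_stages=200)
result = run_simulation(config, progress=True)

print(f"\ncells: {result.n_cells}   coverage: {result.coverage:.3f}")
print(f"census (neighbors -> cells): {dict(sorted(result.census.counts.items()))}")
print(f"hexagon frequency: {result.hexagon_frequency():.2f}")
print("Each cell's 'shape' is its number of touching neighbors; the sphere's")
print("topology forces the average below six, so pentagons must appear.")
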