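"""Analytic spherical tilings and the Euler pentagon constraint.

Goldberg polyhedra (duals of subdivided icosahedra) tile the sphere with
exactly 12 pentagons and otherwise hexagons; every closed 3-valent tiling
satisfies sum(6 - class) = 12.
"""
from epigrain import goldberg_fixture, shape_census, euler_balance
from epigrain.topology import pentagon_hexagon_partition

for m in (1, 2, 3):
    graph, _ = goldberg_fixture(m)
    census = shape_census(graph)
    print(f"subdivision {m}: {graph.number_of_nodes()} cells, "
          f"census {dict(sorted(census.counts.items()))}, "
          f"Euler balance {euler_balance(census)}")

pent, hexa = pentagon_hexagon_partition(60)
print(f"\nA complete 60-cell tiling of pentagons and hexagons must have "
      f"{pent} pentagons and {hexa} hexagons -> {100*hexa/60:.0f}% hexagons.")
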