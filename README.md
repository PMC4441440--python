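# epigrain

Discrete-element simulation of epithelial morphogenesis on a sphere, with
polygon-class (neighbour-count) censuses and joint binomial
likelihood-ratio statistics for comparing cell-shape distributions.

## The problem

Epithelial monolayers tile surfaces with polygonal cells, and the
distribution of polygon classes — how many cells have 4, 5, 6, 7, …
neighbours — is a fingerprint of how the tissue was built.  The follicular
cell layer covering ascidian oocytes is a rare *non-proliferative*
epithelium: a fixed number of cells (60 in *Ciona intestinalis*) arrive
sequentially on the spherical oocyte surface and grow until the sphere is
covered, with no mitosis or apoptosis — morphogenesis by **accretion**.
Such epithelia show a narrow class range (5–7 neighbours, hexagons
dominant), whereas proliferative epithelia (cultured COS monolayers,
*Drosophila* imaginal discs) show a broad 4–10 range with far fewer
hexagons.

`epigrain` implements a granular ("divided media") simulator that builds
both kinds of tissue from the same mechanical ingredients.  Every cell is
a set of solid spherical grains constrained to the support sphere:
internal grains (cytoplasm, stiff in compression only) inside an ordered
ring of peripheral grains linked by tension-only cables (the membrane).
Cells grow by adding grains, membranes remodel by splitting/removing
cables, permanent cadherin-like junctions form between touching cells,
and the whole assembly relaxes by damped RK4 dynamics between biological
"stages".  Two scenarios share the machinery:

* **accretion** — cells arrive at random collision-free positions (two
  per stage at most) and grow to a mature size of 41 grains; no division,
  no death;
* **proliferation** — seeded cells grow, then 7 % of mature cells divide
  per stage (contractile filament through the barycentre, shortest
  diameter) and a fixed ratio (1/3, 1/5 or 0) of apoptoses per mitosis
  gradually remove cells.

Both run until the tissue covers 99 % of the sphere.  The package also
provides the topological toolkit (neighbour graphs, censuses, coverage,
Euler-balance checks, Goldberg-polyhedron fixtures) and the statistics
used to compare shape distributions: the multinomial census is reduced to
a trinomial response (hexagons / second-most-common class / rest) and
fitted by two nested binomial likelihood-ratio tests whose G statistics
add, giving `2(n−1)` degrees of freedom for `n` conditions.

## Worked example

The topological skeleton of the "~80 % hexagons" observation costs
nothing to compute: a closed tiling of a sphere by pentagons and hexagons
always carries exactly 12 pentagons.

```bash
$ python examples/goldberg_euler.py
subdivision 1: 12 cells, census {5: 12}, Euler balance 12
subdivision 2: 42 cells, census {5: 12, 6: 30}, Euler balance 12
subdivision 3: 92 cells, census {5: 12, 6: 80}, Euler balance 12

A complete 60-cell tiling of pentagons and hexagons must have 12 pentagons and 48 hexagons -> 80% hexagons.
```

A small accretion tissue, grown end to end (about half a minute):

```bash
$ python examples/accretion_census.py
...
cells: 14   coverage: 0.990
census (neighbors -> cells): {4: 1, 5: 4, 6: 9}
hexagon frequency: 0.64
```

The sphere closed at 99 % coverage with all 14 cells placed; the census
is unimodal at six neighbours, and because the mean class of a closed
14-cell tiling must be 6 − 12/14 ≈ 5.1, sub-hexagonal cells necessarily
appear.

Comparing a narrow (accretion-like) and a broad (proliferation-like)
shape distribution with the joint binomial LR test:

```bash
$ python examples/compare_shape_distributions.py
trinomial counts (hex, second=5, rest):
  accretion-like: [1199, 191, 110]
  proliferation-like: [652, 342, 506]
LR chi-square = 483.33, df = 2, p = 1.11e-105
```

The same operations are available from the shell:

```bash
epigrain simulate --preset ciona-accretion --seed 1 --out runs/acc1
epigrain census --snapshot runs/acc1/final_state.json --cap 0.8 --out cap.csv
epigrain stats compare --census a.csv --census b.csv --out lr.json
```

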