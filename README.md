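# phylogeokit

Distance-based phylogeography for vicariant lineages: a tested, reusable
pipeline for asking how geography structured the genetic variation of a
low-dispersal species sampled across historically isolated regions
("basins"), and when those regions diverged.

The package targets the classic mitochondrial-phylogeography workflow used
for lowland island faunas: sequence several mtDNA loci for ~170 individuals
from sites grouped into putative basins, then test vicariance, isolation by
distance, and founder-effect hypotheses against each other.  It is aimed at
population geneticists and phylogeographers who want these analyses
scriptable, seeded, and verifiable against ground truth rather than locked
inside GUI tools.

## What it computes

- **Genetic distances** (`gendist`): Kimura two-parameter distances
  separating transitions P from transversions Q,
  d = −½ ln(1−2P−Q) − ¼ ln(1−2Q), and the Jin–Nei gamma-rate variant
  d = (α/2)[(1−2P−Q)^(−1/α) − 1] + (α/4)[(1−2Q)^(−1/α) − 1] (default
  α = 0.68); group means and Nei's net divergence
  d_A = d_xy − (d_x + d_y)/2.
- **Divergence dating** (`clockdate`): T = d_A / rate under a strict clock,
  default 2.1% ± 0.1% between-lineage divergence per Myr (the standard
  passerine mtDNA calibration).
- **Population structure** (`popstruct`): Excoffier-style AMOVA from the
  distance matrix — Φ_CT (among basins), Φ_SC (among sites within basins),
  Φ_ST (overall) with three permutation schemes; pairwise Φ_ST; nucleotide
  diversity π with Tajima's SD; transition/transversion substitution counts;
  Tajima's D; Fu's F_s via exact Ewens probabilities.
- **Haplotype networks** (`hapnet`): deterministic median-joining networks
  (minimum spanning network plus quasi-median Steiner vectors, ε-relaxed).
- **Landscape resistance** (`landscape`): friction grids from a DEM with the
  exponential cost model y = 1.4142 e^(0.0035·elevation) capped at an
  impassable 2300 m; least-cost (Dijkstra) effective geographic distances;
  Mantel tests; within- vs between-basin isolation-by-distance slopes.
- **Dispersal evolution** (`dispersal`): nonparametric rate smoothing to a
  fixed-root-age chronogram; 2-D Brownian-motion diffusion of tip locations
  with per-branch-class rates σ²_c (REML via phylogenetic contrasts);
  likelihood-ratio tests between nested class models; per-generation
  dispersal distance ψ_c = √(σ²_c·g) and its correlation with √(range area).
- **Synthetic truth** (`synthgen`): a vicariance-scenario generator —
  censored coalescent inside a dated basin tree, K2P sequence evolution with
  continuous gamma site rates, geographic sampling, and a DEM whose ridges
  separate basins — used for all recovery and calibration tests.
- **Orchestration** (`pipeline`, `cli`): a YAML-configured `run_all` plus a
  `phylogeokit` command with subcommands `simulate`, `haplotypes`,
  `distances`, `amova`, `diversity`, `network`, `dates`, `ibd`, `dispersal`,
  `all`.

## Worked example

Simulate the default seven-basin vicariance scenario (splits between 0.5
and 5 Myr, 168 mtDNA sequences of 572 bp over three loci) and run the core
analyses:

```python
import numpy as np
from phylogeokit import synthgen, gendist, popstruct, clockdate

scenario = synthgen.default_scenario()
config = synthgen.SimulationConfig(seed=1)
dataset = synthgen.generate_dataset(scenario, config)

dm = gendist.distance_matrix(dataset.alignment)          # gamma-K2P, alpha = 0.68
table = dataset.sample_table
groups = {b: table.loc[table.basin == b, "sample_id"].tolist()
          for b in scenario.basins}
net, within = gendist.net_divergence_table(dm, groups)
date = clockdate.divergence_time(net.get("MB", "SRB"))
print(f"net divergence MB-SRB: {net.get('MB', 'SRB'):.4f}")
print(f"clock date: {date.time:.2f} Myr  (interval {date.lower:.2f}-{date.upper:.2f})")

part = popstruct.PopulationPartition.from_table(table)
res = popstruct.amova3(dm, part, nperm=999, seed=1)
print(f"AMOVA: {res.pct_a:.1f}% of variance among basins "
      f"(Phi_CT = {res.phi_ct:.2f}, p = {res.p_ct:.3f})")
```

Output:

```
net divergence MB-SRB: 0.0468
clock date: 2.23 Myr  (interval 2.13-2.34)
AMOVA: 97.9% of variance among basins (Phi_CT = 0.98, p = 0.001)
```

The two northern basins (MB, SRB) split 2 Myr ago in the generating
scenario; the corrected divergence of 0.0468 at the 2.1%/Myr clock dates
the split at 2.23 Myr, and nearly all molecular variance lies among basins,
as expected when barriers predate within-basin coalescence.  The same
analyses run from the shell via `phylogeokit simulate|distances|amova|...`,
or end-to-end with `phylogeokit all --config run.yaml`.

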