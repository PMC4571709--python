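# trophoweb

Topological analysis of marine food webs for ecologists studying how
community change — in particular the poleward shift of boreal generalist
fish into arctic shelf seas — reorganizes trophic network structure.

The package takes a regional *meta-web* (the pooled directed graph of
trophospecies and feeding links, prey → predator) together with regional
species occurrence lists, and provides every stage of a regional
comparison:

* **Sub-web induction** — regional webs are the subgraphs induced by the
  species present in each region, assuming co-occurring species interact
  wherever the meta-web says they do; an "updated" web adds incoming
  species the same way.
* **Structural metrics** — species count S, links L, linkage density
  LD = L/S, connectance C = L/S², % omnivores, % cannibals (self-links),
  % of species in loops (strongly connected components of size ≥ 2),
  mean path length and mean clustering (undirected projection), mean
  short-weighted trophic level (SWTL, the average of shortest-chain and
  prey-averaged trophic level), and cumulative in/out-degree
  distributions with exponential-rate fits.
* **Modularity** — for a partition into modules *s*,

      M = Σ_s [ I_s / L − (d_s / 2L)² ]

  with I_s the within-module link count, d_s the summed degree and L the
  undirected link count. Partitions are found by simulated annealing
  (single-node moves plus merge/split collective moves, followed by a
  greedy refinement pass), and significance is assessed against
  degree-preserving randomized networks (double-edge swaps).
* **Species roles** — within-module degree z = (k_is − mean_s)/SD_s and
  participation coefficient PC = 1 − Σ_t (k_it/k_i)², summarized over
  annealing replicates and classified into four role regions at z = 2.5
  and PC = 0.625: peripheral, connector, module hub, network hub
  (super-generalist).
* **Module–trait association** — a permutation discriminant test of
  whether modules segregate by habitat (benthic/pelagic/benthopelagic)
  and trophic level.
* **Spatial degree centrality** — station-wise mean meta-web degree of
  focal taxa (e.g. fish), aggregated on a regular 50 km grid.
* **Synthetic webs** — a niche-model generator, planted-module
  benchmarks, and a full synthetic meta-web (~233 trophospecies, ~2100
  links, habitat-structured modules, two overlapping regional pools, a
  few planted super-generalist fish, survey stations) so the entire
  pipeline runs and is tested without any data download.

## Worked example

The numbered scripts under `analysis/` run the full comparison on the
synthetic meta-web. `python analysis/01_simulate_metaweb.py` writes the
study files, then:

```
$ python analysis/03_modularity_null.py --replicates 10 --null 30
region1:    M=0.298 (5 modules), null 0.181 +/- 0.004, p=0.0323
region2:    M=0.331 (5 modules), null 0.196 +/- 0.005, p=0.0323
region2_II: M=0.299 (5 modules), null 0.177 +/- 0.006, p=0.0323

region 2 (arctic-like) more modular than region 1: True
```

Each regional web is significantly more modular than degree-matched
random networks (p is the one-sided permutation p-value over the null
ensemble), the species-poor "arctic-like" web is the most modular, and
adding the four wide-diet fish (`region2_II`) pulls its modularity back
down toward the "boreal-like" value — the structural signature of
generalist-driven module coupling. The role step then shows why:

```
$ python analysis/04_topological_roles.py
region1: {'network_hub': 6, 'connector': 75, 'peripheral': 92, 'module_hub': 1}
  super-generalist fish_gen0: z=2.98, PC=0.77 -> network_hub
  super-generalist fish_gen1: z=3.44, PC=0.71 -> network_hub
```

The planted super-generalists sit in the network-hub region of the z–PC
plane (high within-module degree *and* links spread across modules).
`analysis/05_module_traits.py` confirms modules segregate by habitat and
trophic level (permutation p = 0.002 at 499 permutations), and
`analysis/06_degree_centrality_maps.py` shows the generalist-rich
southern station block has a higher mean fish degree (20.3 vs 12.2).

The same pipeline runs on user-supplied empirical files (edge-list CSV
`prey,predator`, attribute CSV `id,habitat,group`, one-species-per-line
region lists) via `analysis/07_dryad_reproduction.py` or the CLI:

```bash
trophoweb compare --meta metaweb.csv --attrs attributes.csv \
    --region1 boreal.txt --region2 arctic.txt --add newcomers.txt \
    --seed 42 --out comparison.json
```

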