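# melspat

Spatial heterogeneity analysis of multiplexed immunofluorescence and
microregional transcriptomics in primary melanoma tissue.

Primary melanomas are spatially patterned: tumor cells in different
differentiation states (melanocytic, transitional, mesenchymal,
neural-crest-like) are often intermixed at the single-cell level, and the
degree of intermixing tracks with local progression stage and with the
immune microenvironment. `melspat` implements the analysis stack needed to
quantify this from single-cell imaging data:

* **Gate-based phenotyping** — per-specimen marker gates rescale raw
  intensities so that 0.5 is the positivity boundary; cells are called by a
  hierarchical rule set, and SOX10+ tumor cells get a differentiation state
  from their binarized MART1/SOX9/NGFR pattern.
* **Spatial entropy** — on a Delaunay graph G = (V, E) of tumor cells with
  Euclidean edge weights d_ij, each cell's local Shannon entropy is computed
  over its neighbors' states, and each region is scored with

  H = −α Σ_l (M̄_l / D̄_l) · p_l log₂ p_l

  where, for cells of state l, M̄_l is the mean number of heterotypic
  Delaunay neighbors (intermixing strength), D̄_l the mean summed distance to
  them, and p_l = n_l / N the state frequency. H is 0 for a single-state
  region and grows with intermixing; doubling all coordinates halves H.
* **Recurrent cellular neighborhoods (RCN/RCNG)** — each cell's 15 µm
  neighborhood composition is k-means clustered (default k = 25) into RCNs,
  which are agglomeratively grouped (default g = 11) into RCN groups.
* **Invasion bands and proximity analysis** — cells are banded by distance
  to the annotated epidermis in 0.2 mm increments; the surroundings of two
  focal tumor states (e.g. SOX10+MART1− vs SOX10+MART1+) are compared
  per phenotype with rank-sum tests and Benjamini–Hochberg correction.
* **SOM metagene portraits and the correlation spanning tree (CST)** —
  microregional expression is log10-transformed, quantile normalized and
  gene-centered; genes are mapped onto a 30 × 30 self-organizing map (900
  metagenes), per-sample portraits and overexpression cluster areas are
  derived, and microregions are arranged into a minimum spanning tree on
  1 − Pearson r of their metagene profiles, decomposed into branches.
* **Synthetic tissue and expression generators** — marked Poisson point
  processes with hard-core thinning simulate an epidermis/dermis section
  with tumor nests (state intermixing controlled by a mixing parameter θ),
  clustered immune infiltrates (optionally coupled to nest intermixing),
  and vessels; a two-latent-factor (progression × inflammation)
  negative-binomial model simulates microregion × gene counts. Every
  analysis stage is therefore testable against planted ground truth.

## Worked example

```python
import melspat as m

cfg = m.TissueSimConfig(seed=11, theta=0.4)        # 40% state redraws
cells, regions, truth = m.simulate_tissue(cfg)
table = m.rescale_table(cells, m.true_gates(cfg))
table = m.call_phenotypes(table)
table = m.assign_tumor_states(table)

for r in m.entropy_by_region(table, regions, "tumor_state"):
    if r.status == "ok":
        print(f"{r.region_id}: n={r.n_cells} L={r.L} H={r.H:.4f}")
```

Output:

```
nest_00: n=94 L=4 H=0.0861
nest_01: n=100 L=4 H=0.0887
nest_02: n=101 L=4 H=0.0826
nest_03: n=172 L=4 H=0.0796
nest_04: n=62 L=4 H=0.0902
nest_05: n=236 L=4 H=0.0813
```

Each simulated tumor nest is one annotated region; all four tumor states are
present (L = 4) because θ = 0.4 redraws 40% of cell states uniformly, and
the per-region spatial entropies (bits/µm) are similar because every nest
shares the same θ. With θ = 0 each nest is single-state and H = 0 exactly;
H increases monotonically with θ.

The same table feeds the neighborhood stage:

```python
nm = m.neighborhood_composition(table, r=15.0)
rcn = m.group_rcns(m.cluster_rcn(nm, k=8, seed=0), g=4)
print(rcn.rcng_labels()[rcn.labels >= 0].value_counts(normalize=True))
```

which on this tissue yields four RCN groups with proportions
0.475 / 0.383 / 0.115 / 0.027 (stroma-dominated, tumor-dominated,
epidermal, and immune-rich neighborhoods).

A full synthetic run (simulate → phenotype → entropy → rcn → bands →
proximity → som) with a provenance manifest:

```sh
melspat run out/ --seed 0
melspat report out/
```

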