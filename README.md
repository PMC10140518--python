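# rhizocomm

Downstream analysis of root-compartment microbial communities: the
statistical stages that follow OTU picking in a 16S survey of bulk soil,
rhizosphere and rhizoplane sampled across plant growth stages.

The package targets the standard analysis surface of such studies:

* **Diversity** — Shannon (nats), Simpson dominance
  (D = Σ nᵢ(nᵢ−1)/(N(N−1))), bias-corrected Chao1, ACE; Bray–Curtis
  dissimilarity, PCoA, one-way PERMANOVA with seeded permutations,
  two-way ANOVA, Tukey-HSD letters and Bonferroni-corrected Mann–Whitney
  group comparisons.
* **Community assembly** — abundance-weighted βMNTD and its z-score βNTI
  against a tip-shuffling null, the Bray–Curtis Raup–Crick index
  (RC_Bray), and the five-way ecological-process classification:
  homogeneous selection (βNTI < −2), heterogeneous selection (βNTI > +2),
  dispersal limitation (|βNTI| < 2, RC > 0.95), homogenizing dispersal
  (|βNTI| < 2, RC < −0.95), undominated otherwise.
* **Co-occurrence networks** — all-pairs Spearman on prevalent taxa
  (present in over 50% of samples), edges kept at |ρ| ≥ 0.7 and raw
  p ≤ 0.01; topology metrics (average degree 2E/N, clustering, path
  distance, modularity, connectedness 1 − components/nodes, ±link ratio);
  modularity-based modules; Zi–Pi node roles (module hub Zi > 2.5,
  connector Pi > 0.62) and a keystone-candidate report.
* **Abundance trends** — per-phylum beta regression (logit mean link,
  precision φ) along the spatial (bulk→rhizosphere→rhizoplane) or
  temporal (tillering→heading→mature) gradient, coded 0/1/2, with
  increasing/decreasing/flat calls.
* **Functional groups** — rule-based annotation over ranked lineages
  (a FAPROTAX-compatible subset format), with PCA and heatmap-ready
  z-scored matrices.
* **Synthetic communities** — a generator with known ground truth
  (birth–death phylogeny, Brownian niche traits, Gaussian environmental
  filtering graded by compartment, planted correlated taxon blocks) that
  makes every stage testable without sequence data.

## Worked example

```python
import rhizocomm as rc

cfg = rc.SimulationConfig(n_taxa=120, depth=5000, seed=42)
ds = rc.simulate_dataset(cfg)           # matrix, metadata, tree, traits, truth

alpha = rc.alpha_diversity_table(ds.matrix)
comp = ds.metadata.factor("compartment")
print(alpha.join(comp).groupby("compartment")
      [["shannon", "simpson", "chao1", "ace"]].mean().round(4))

bc = rc.bray_curtis(ds.matrix)
r = rc.permanova(bc, ds.metadata, "compartment", n_perm=999, seed=0)
print(f"PERMANOVA compartment: pseudo-F={r.pseudo_f:.2f} "
      f"r2={r.r_squared:.3f} p={r.p_value:.3f}")
```

prints

```
             shannon  simpson     chao1       ace
compartment
bulk          4.1157   0.0319  119.6204  119.7260
rhizoplane    3.4022   0.0835  107.8519  107.9772
rhizosphere   4.0568   0.0367  118.4603  118.1514
PERMANOVA compartment: pseudo-F=147.97 r2=0.925 p=0.001
```

The generator's compartment-graded filtering (filtering width shrinking
from bulk to rhizoplane) shows up exactly as expected: the rhizoplane is
the least diverse compartment (lowest Shannon, highest Simpson dominance,
fewest estimated taxa), and compartment — not growth stage — structures
the Bray–Curtis distances (the same PERMANOVA on `"stage"` gives
r² = 0.004, p ≈ 1).

The assembly stage then quantifies *why* communities differ:

```python
res = rc.assembly_analysis(ds.matrix, ds.tree, n_null=199, seed=0)
print(rc.process_summary(res, ds.metadata))
```

reports, per compartment, the percentage of sample pairs assembled by
each ecological process and the deterministic fraction (|βNTI| > 2).

Everything is also reachable from a CLI (`rhizocomm simulate`,
`diversity`, `assembly`, `network`, `trends`, `functions`, or
`rhizocomm run --config pipeline.yaml` for the whole chain with a
manifest and byte-reproducible outputs under fixed seeds).

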