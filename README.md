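# lncstage

Cell- and developmental-stage-specific lncRNA–mRNA regulatory network
inference from single-cell transcriptomics.

Long non-coding RNAs (lncRNAs) regulate mRNA expression in ways that
differ between developmental stages, but bulk methods — and even most
single-cell network methods — pool all cells, hiding that heterogeneity.
`lncstage` infers one bipartite lncRNA → mRNA network **per cell** from
a genes × cells expression matrix, restricted to a user-supplied list of
putative lncRNA–target interactions, then unions the per-cell networks
of each developmental stage into stage-specific networks. Downstream it
provides the analyses a stage-resolved network study needs: hub lncRNAs,
conserved/rewired edge classification, between-stage similarity,
hypergeometric gene-set enrichment with Benjamini–Hochberg adjustment,
Kolmogorov–Smirnov comparison of biomarker target distributions, and a
benchmarking harness (random edge baseline, validated-interaction
fractions, paired t-tests). A seeded synthetic-data generator with
planted, stage-restricted dependencies makes the whole pipeline testable
without any external download.

It is aimed at computational biologists working with small-to-medium
scRNA-seq datasets (hundreds of cells) who have candidate lncRNA–target
pairs from interaction databases and want stage-resolved, per-cell
evidence for them.

## The statistic

For a candidate pair (u, v) and focal cell *k*, each gene defines a
*neighborhood*: with n = max(1, ⌊0.1·m⌋) out of m cells, the box
half-width is the distance of the n-th nearest cell to cell *k*'s
expression value, and the neighborhood N<sub>u</sub>(k) is every cell
within that distance (the focal cell always included; boundary ties all
included, so the construction is deterministic and robust to the zero
ties typical of scRNA-seq). Writing m<sub>u</sub>(k) = |N<sub>u</sub>(k)|,
m<sub>v</sub>(k) = |N<sub>v</sub>(k)| and m<sub>uv</sub>(k) for the size
of their intersection,

    ρ_uv(k) = m_uv(k)/m − (m_u(k)/m)·(m_v(k)/m)

measures the excess joint-neighborhood mass over what independence
predicts. Standardised by its null standard deviation,

    ρ̂_uv(k) = ρ_uv(k) / σ_uv(k),
    σ_uv(k) = sqrt( m_u m_v (m − m_u)(m − m_v) / (m⁴ (m − 1)) ),

ρ̂ is approximately N(0, 1) under independence; an upper-tail p-value
below α = 0.05 makes (u, v) an edge of cell *k*'s network. A stage
network is the union of its cells' networks; each edge carries its
*support*, the number of cells in which it was significant.

## Worked example

```python
from lncstage import (
    CellNetworkInference, StageNetworkAggregator, SimulationConfig,
    simulate_dataset, evaluate_recovery, preprocess, ExpressionMatrix,
    classify_edges, classification_summary, hub_lncrnas,
)

# five-stage synthetic study: 26/26/123/24/77 cells, 20 planted edges
# hidden among 200 decoy priors
sim = simulate_dataset(SimulationConfig(seed=1))
expr = preprocess(ExpressionMatrix(sim.expression.values.copy()), sim.annotation)
print(f"{expr.n_genes} genes ({len(expr.lncrnas)} lncRNAs) x {expr.n_cells} cells")

nets = CellNetworkInference(box_fraction=0.1, alpha=0.05).fit(expr, sim.priors)
stages = StageNetworkAggregator(min_support=5).fit(nets.cell_networks_, sim.stages)
for net in stages.stage_networks_:
    hubs = hub_lncrnas(net, fraction=0.2)
    print(f"{net.stage}: {net.n_cells} cells, {net.n_edges} edges, "
          f"top hub {hubs[0]}")

summary = classification_summary(classify_edges(stages.stage_networks_))
print(f"conserved {summary['pct_conserved']:.1f}% | "
      f"rewired {summary['pct_rewired']:.1f}% of {summary['total']} edges")
rec = evaluate_recovery(stages.stage_networks_, sim.truth)
print(f"mean recall of planted edges: {rec['recall'].mean():.2f}, "
      f"decoy hit rate: {rec['decoy_fpr'].mean():.2f}")
```

prints

```
230 genes (30 lncRNAs) x 276 cells
S1: 26 cells, 45 edges, top hub LNC0002
S2: 26 cells, 49 edges, top hub LNC0007
S3: 123 cells, 201 edges, top hub LNC0022
S4: 24 cells, 42 edges, top hub LNC0028
S5: 77 cells, 162 edges, top hub LNC0022
conserved 12.3% | rewired 21.6% of 204 edges
mean recall of planted edges: 1.00, decoy hit rate: 0.40
```

Every planted edge is recovered in every stage (recall 1.00) while well
under half of the independent decoy priors survive the support-5 filter;
larger stages accumulate more union edges, which is why the two biggest
stages (S3, S5) carry the most edges and share a hub.

The same pipeline runs from the shell on TSV/MTX inputs:

```sh
lncstage simulate --out-dir data --seed 1
lncstage run --expression data/expression.tsv --annotation data/annotation.tsv \
             --priors data/priors.tsv --stages data/stages.tsv --out-dir out
```

`out/` then contains the stage edge table, hub lists, conservation
classes, similarity matrices and a `manifest.json` (input checksums,
parameters, seed) from which the run reproduces byte-identically.

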