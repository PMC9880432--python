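# Methods

## Model and procedure

`lncstage` treats regulation as a per-cell association question: in cell
*k*, is the joint expression of a candidate lncRNA–mRNA pair (u, v)
concentrated around (u_k, v_k) more than independence would allow? Each
gene defines a neighborhood of cell *k* — all cells whose expression of
that gene lies within the distance of the n-th nearest cell to the focal
value, n = max(1, ⌊f·m⌋) with box fraction f — and the test statistic is
the standardised excess of the joint neighborhood over the product of
the marginals:

    ρ_uv(k)  = m_uv/m − (m_u/m)(m_v/m)
    ρ̂_uv(k) = ρ_uv(k) / σ_uv(k),
    σ_uv(k)  = sqrt( m_u m_v (m−m_u)(m−m_v) / (m⁴(m−1)) )

which algebraically equals
√(m−1)·(m·m_uv − m_u·m_v)/√(m_u m_v (m−m_u)(m−m_v)). Under
independence ρ̂ is asymptotically standard normal (its null moments are
those of the overlap of two random m_u- and m_v-subsets of m cells), so
an upper-tail normal p-value is attached to each (pair, cell) instance
and instances with p < α become directed lncRNA → mRNA edges of that
cell's bipartite network.

Assumptions worth stating explicitly:

- the statistic is evaluated **only on the prior candidate list**; the
  prior list is the false-positive control, not an afterthought;
- neighborhoods are computed over **all** cells of the dataset, not per
  stage — stage specificity enters only through aggregation;
- association, not causation: an edge says the pair co-varies locally,
  with direction assigned by the prior's lncRNA → target convention;
- p-values are raw per-(pair, cell) tests. No multiple-testing
  correction is applied at the edge-calling step; the per-cell networks
  are exploratory objects that gain reliability through stage-level
  support.

Stage networks are unions of their member cells' networks; each edge
carries its support (number of member cells where it is significant),
its mean ρ̂ and its minimum p. An optional minimum-support threshold
(default 1, the pure union) counters the edge inflation that unions
over a hundred-plus cells necessarily produce.

## Preprocessing

Raw matrices are cleaned in a fixed order: duplicate gene symbols are
collapsed to the row mean (first-occurrence order kept), genes constant
across all cells are dropped, values are transformed as log2(x + 1),
and genes without a lncRNA/mRNA role annotation are removed. Constancy
is invariant under the monotone log transform, so filtering before
transforming is equivalent to the reverse order; filtering first is
chosen and documented here. Missing values are rejected rather than
imputed — scRNA-seq matrices are dense-with-zeros.

## Neighborhood construction: numerical choices

- **Box size.** n = max(1, ⌊f·m⌋), f = 0.1 by default. Flooring rather
  than rounding is a deliberate calibration choice: at m = 276 the
  measured null false-positive rate at α = 0.05 is ≈ 0.08 with ⌊·⌋ and
  ≈ 0.11 with rounding (the focal cell's forced membership makes the
  normal approximation anticonservative, and the smaller box keeps that
  inflation acceptable).
- **Ties.** The box is defined by a distance radius, so cells tied at
  the boundary are all included and the marginal sizes m_u, m_v are
  data-dependent (≥ n). This matters for zero-inflated data: an
  index-based tie-break would hand every zero-heavy gene the same
  arbitrary subset of its zero cells, manufacturing overlap between
  independent genes. With the radius rule, two independent dropout-heavy
  genes overlap in proportion to m_u·m_v/m, exactly what the null
  expects.
- **Self-inclusion.** The focal cell is always in its own box (distance
  zero), so m_uv ≥ 1; a single forced overlap cannot reach significance
  on its own.
- **Degenerate margins.** If a box covers every cell (possible for a
  gene that is one value in almost all cells), the null variance is
  zero and the instance carries no evidence; the vectorised engine
  reports ρ̂ = 0 (p = 0.5 one-sided), never significant. The scalar
  `normalized_stat` raises instead, since explicit counts with a
  degenerate margin indicate a caller error.
- **Tail.** One-sided (upper) by default: only positive association is
  read as regulation. A two-sided mode exists for users who want to
  retain negative associations.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `box_fraction` | 0.1 | neighborhood size as a fraction of cells; smaller boxes localise the test but coarsen the overlap distribution |
| `alpha` | 0.05 | per-(pair, cell) significance cutoff (raw p) |
| `tail` | upper | direction of the alternative |
| `min_support` | 1 | cells per stage an edge needs to enter the stage network |
| `hub_fraction` | 0.2 | top share of degree-ranked lncRNAs called hubs |
| `similarity` | jaccard | between-stage set similarity (overlap coefficient available) |

Hubs are the top ⌈0.2·L⌉ of the L lncRNAs with degree ≥ 1, ranked by
out-degree with ties broken by symbol; the cut is deterministic and
boundary ties beyond it are excluded. Edges (and hubs) present in every
stage are *conserved*, in exactly one stage *rewired*, otherwise
*intermediate* — the three classes partition the union set by
construction. Both Jaccard and overlap coefficients are implemented
because the literature uses either for stage similarity; the choice is
recorded in output metadata, and two empty sets are defined as
perfectly similar.

## Enrichment and downstream statistics

Gene-set enrichment of a network is the upper hypergeometric tail
P(X ≥ r) with universe N, annotated S, network genes M and annotated
network genes r, computed through scipy's log-gamma implementation
(exact to ~1e-15 against rational enumeration). By default lncRNAs and
mRNAs are counted jointly as "genes in the network"; role-restricted
counting is a flag. BH step-up adjusts across gene sets. The biomarker
case study builds per-stage distributions of predicted-target counts
(or annotated-target fractions) over a fixed lncRNA panel — biomarkers
with no targets contribute 0 rather than being dropped, so stages stay
comparable — and compares stages with the two-sample KS test
(asymptotic p by default, exact enumeration mode for small panels). The
method-comparison harness computes per-stage validated fractions for
the inferred networks and for a seeded uniform random edge baseline
matched per stage in edge count, then a classic paired t-test across
stages.

## Synthetic data

The generator emulates the shape of a multi-stage cortical scRNA-seq
study: five stages of 26/26/123/24/77 cells by default (276 total), a
small lncRNA panel (30) against a larger mRNA background (200),
negative-binomial marginals (mean 8, dispersion 0.4) and independent
dropout zero-masking (rate 0.3) — together ≈ 1/3 zeros, the zero-heavy
overdispersed look of real data at this depth. Dependence is planted
through a latent Gaussian copula: in the stages where a true edge is
active, the target's latent normal is ρ_sim-correlated with its
regulator's before marginal transformation. Planted edges (20) hide in
a ten-fold larger list of independent decoy priors, mRNA targets are
distinct across planted edges so each target has one regulator, and
everything is reproducible from one seed.

What the generator does **not** emulate: library-size variation between
cells (off by default to keep the planted correlation interpretable),
pseudotime/trajectory structure, batch effects, doublets, or the
mean–variance and mean–dropout coupling of real protocols. Passing
recovery tests therefore show that the statistic detects monotone
latent dependence under realistic sparsity — not that real prior lists
have the decoy structure simulated here.

## Problem sizes and what the tests show

The test suite runs the statistic against an independent O(m²)
brute-force oracle on hundreds of random instances (m ≤ 50), checks
null calibration on 1,000 independent pairs at m = 276 (observed ≈ 0.08
at α = 0.05 — the normal approximation is slightly anticonservative,
and markedly so for much smaller boxes, e.g. ≈ 0.2 at m = 100), and
runs recovery on 5 × 60-cell simulations: planted-edge recall rises
from ≈ 0.7 (ρ_sim = 0.3) through ≈ 0.96 (0.6) to 1.0 (0.9) at support
threshold 5, while decoy hit rates stay near the per-cell null rate
compounded over a stage. The full pipeline is exercised at the 276-cell
layout and must rerun byte-identically from the same manifest; all
floating-point output is written with a fixed `%.10g` format for that
reason.

## Known limitations

- The N(0, 1) null is an approximation; its accuracy degrades for small
  m (boxes of a handful of cells) and the per-test false-positive rate
  at α = 0.05 is closer to 0.08 at the design scale. Support thresholds
  and validated-fraction benchmarks, not raw edge counts, should carry
  inferential weight.
- Pure-union stage networks saturate as stages grow; stages with very
  different cell counts should be compared via support-thresholded
  networks or per-cell rates.
- The method tests marginal association per pair; it does not condition
  on other regulators (no partial-correlation analogue) and cannot
  orient edges beyond the prior's convention.
- Prior-list quality bounds everything downstream: the statistic never
  proposes pairs outside the priors.
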