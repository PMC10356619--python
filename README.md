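# histoarch

Multiscale tissue-architecture analysis for cell-typed multiplexed-imaging
data (CODEX and similar), for computational biologists working with
segmented single-cell tables — one row per cell with coordinates, a cell
type and sample/donor metadata.

Highly multiplexed imaging resolves every cell in a tissue section, but the
biology lives in how cells organise: which types pack together, which
multicellular structures recur, how microstructures assemble into
macrostructures, and which structural interfaces host signalling.
`histoarch` implements that analysis stack end to end:

- **Same-cell density** — for each cell of type *t*, the mean distance to
  its 5 nearest same-type neighbours divided by the maximal-dispersion
  spacing √(A/N_t); scores near 0 mean tight aggregation, near 1 mean the
  type is spread as evenly as geometry allows.
- **Composition normalization and group tests** — per-compartment cell-type
  percentages, Welch *t*-tests between anatomical groups (small bowel SB vs
  colon CL), BH-adjusted p-values, and donor-covariate Pearson correlation.
- **Multicellular neighbourhoods** — each cell's 10-nearest-neighbour
  window summarised as a cell-type fraction vector, k-means overclustered
  (default 30), merged into named structures via an explicit mapping guided
  by fold-enrichment matrices; SB-vs-CL conservation as the enrichment
  difference ΔE ordered by Σ|Δ|.
- **Communities and tissue units** — the identical machinery re-applied to
  neighbourhood labels at windows of 100 and 300 cells.
- **Hierarchy graph** — each level's labels connected to the next level by
  largest contribution (argmax) or a ≥ 15% share of the upper structure.
- **Spatial context** — the minimal set of structure labels covering ≥ 85%
  of a cell's window; combination frequencies and their sublayer
  containment graph.
- **Tissue motifs** — contiguous same-label patches from a pruned Delaunay
  adjacency; pairs of patch labels tested against a label-permutation
  (maximum-entropy) null with Bonferroni correction (p × 2 × tests).
- **Colocalization quotient** —
  CLQ_{A→B} = (C_{A→B}/N_A) / (N_B/(N−1)), where C_{A→B} averages the
  fraction of type-B cells among the k = 10 nearest neighbours of each
  type-A cell; cross-group Welch tests with BH adjustment.
- **Ligand–receptor nomination** — for colocalized type pairs, two-sided
  Wilcoxon rank-sum tests of ligand/receptor expression between groups (BH
  within each cell-type × gene-role family), nominating pairs with both
  adjusted p < 0.05 and higher colon means; validation on held-out
  expression via one-sided Wilcoxon and a gene-label permutation test of
  the success rate.

A seeded synthetic generator (`histoarch.synthetic`) emulates layered
intestinal tissue — mucosa/submucosa/muscularis bands, crypts with
Paneth-like anchors, follicles with inner/outer zones, plasma-dense bands,
planted SB/CL composition shifts, group-restricted cell–cell attraction,
and negative-binomial expression with planted fold changes — so every
stage can be tested against known ground truth.

## Worked example

```bash
python examples/05_clq_and_ligand_receptor.py
```

prints (abridged):

```
CLQ(plasma->TA): SB 1.35, CL 1.99, adjusted p = 5.20e-06 (CL>SB)
The colon-only attraction shows as excess TA cells near plasma cells in CL only.

nominated 10 ligand-receptor pairs (10 were planted with log2FC = +1.5 in CL):
ligand receptor  ligand_log2fc  receptor_log2fc
  L000     R000           1.43             1.51
  ...

validation: 10/10 predictions replicate (100.0%), gene-label permutation p = 5.00e-04
```

The first line is the colocalization contrast: in the colon group, transit-
amplifying (TA) cells are ~2× over-represented among the 10 nearest
neighbours of plasma cells, versus ~1.4× in the small bowel — exactly the
planted attraction. The nomination step recovers the 10 planted
ligand–receptor pairs with their ~+1.5 log2 fold changes, and the
permutation test shows that the validation success rate is far beyond what
arbitrary gene relabelling achieves (p ≈ 1/2001).

The other examples cover cohort simulation (`01`), density and composition
(`02`), neighbourhoods/hierarchy (`03`) and spatial context/motifs (`04`).

There is also a thin CLI over the same functions:

```bash
histoarch simulate --donors 2 --seed 11 --out sim/
histoarch pipeline --cells sim/cells.csv --seed 11 --out results/
```

`pipeline` writes every stage's table (TSV) and graph (GraphML) plus a
manifest; identical inputs, config and seed give byte-identical files.

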