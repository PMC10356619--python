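# Methods

This note documents the models and procedures `histoarch` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical conventions and open design choices.

## Data model

A `CellMap` is one imaged section: a table of cells with Euclidean
coordinates (abstract length units — pixels or µm, never converted), a
categorical cell type, sample/donor/region/group metadata, and a section
area. Area defaults to the convex hull of the coordinates when read from a
file (the generator uses the true simulated extent); it is overridable per
sample because density scores divide by it. All distances are Euclidean;
exact distance ties are broken by cell id so every result is reproducible
even on degenerate inputs. Windows never cross sample boundaries.

Expression data ride in an `AnnData` (cells × genes, integer counts, with
`cell_type`, `group` and `sample_id` in `.obs`).

## Same-cell density

For a cell of type *t* (with N_t > k, default k = 5), the score is the mean
distance to its k nearest same-type neighbours (self excluded) divided by
D_max(t) = √(area / N_t), the mean spacing of a maximally dispersed
grid-like arrangement of N_t cells over the section. The per-type score is
the mean over cells; types with N_t ≤ k are reported missing, never zero.
Scores are not clipped at 1 (a type slightly more dispersed than a grid can
exceed it). The statistic is invariant to translation, rotation and joint
rescaling of coordinates and area, and equals 0 exactly for co-located
cells. The denominator convention is a genuine choice — the expected
nearest-neighbour distance under complete spatial randomness,
1/(2√(N/area)), is an equally defensible normaliser; √(area/N) was chosen
because it keeps typical scores in [0, 1] with 1 meaning "as dispersed as
possible", and the choice only rescales scores within a section, never
reorders types.

## Composition and group testing

Cell-type percentages are normalised within cell categories
(epithelial/immune/stromal via a user category map) plus an unnormalised
all-cells table; percentages within a (sample, category) sum to 100. Group
comparisons use Welch's unequal-variance two-sided *t*-test on per-donor
values; raw p-values are the primary output (asterisk-style reporting) with
Benjamini–Hochberg adjusted values alongside. Donor covariates (e.g. a
BMI-like variable) are tested by Pearson correlation with the exact
t-based p.

## Neighbourhoods, communities, tissue units

The window of a cell is the cell plus its k−1 nearest neighbours (total k;
whether the index cell counts is configurable since either convention
appears in the literature). Window rows are label fractions (counts / k),
not z-scored. K-means (fixed seed, 10 restarts, best inertia) overclusters
the rows — default 30 clusters at k = 10 for neighbourhoods. Merging
overclusters into named structures is an explicit user-supplied mapping;
`suggest_merges` lists pairs whose enrichment profiles correlate ≥ 0.9 but
never applies them silently, because merging is a judgement about biology,
not geometry. Communities and tissue units re-run the identical machinery
on the lower level's labels with k = 100 and k = 300 and 20 clusters.

Enrichment of lower label *c* in upper label *u* is
frac(c | u) / frac(c | all); the cell-weighted column sums of the matrix
are identically 1, which the tests exploit as a conservation identity.
Cross-group conservation is ΔE = E_SB − E_CL over shared labels, rows and
columns ordered by descending Σ|Δ|.

Concentric profiles pool, over all anchor cells of a chosen type, the
non-anchor cells within growing disks (default) or annuli, and report
composition and enrichment against the overall non-anchor composition —
the "crypt niche" view around Paneth-like anchors. Anchors are excluded
from the pooled composition so the profile describes their surroundings,
not themselves.

## Hierarchy graph

For consecutive levels, with joint counts n(l, u): an edge l → u exists if
u receives the largest share of l's cells (reason `argmax`, ties broken by
label name) or if l makes up at least 15% of u's cells (reason
`threshold`). Edge weight is the share of the *upper* structure composed of
the lower label; the share-of-lower alternative is exposed by flag since
the two readings of "contribution to the next level" are both plausible,
and both shares are stored on every edge. Nodes carry the fraction of all
cells; the graph is a DAG by construction and raising the threshold only
prunes threshold edges.

## Spatial context

For each cell, the labels of its k-cell window (k = 100 over neighbourhood
labels, 300 over community labels) are ranked by descending count, ties
lexicographic; the minimal prefix whose cumulative fraction reaches θ =
0.85 is the cell's combination (an unordered set — minimal prefixes are
unique and deterministic, unlike "any subset reaching θ"). The comparison
is ≥ θ by default with a strict > flag. Combinations with frequency above
0.1% form the nodes of the containment graph, with edges from each
combination to the combinations holding exactly one more label.

## Tissue motifs

Cell adjacency is the Delaunay triangulation pruned at a maximum edge
length, default 3× the median Delaunay edge — a parameter-light standard
for tissue graphs that removes the long boundary artefacts of a raw
triangulation. Degenerate point sets (collinear/duplicated) fall back to
mutual 6-nearest-neighbour adjacency with a warning. Instances are
connected components of same-label cells with ≥ 3 members ("multiple cells
of the same structure"); two instances are adjacent when any pruned edge
joins their cells. The statistic for an unordered label pair is the count
of adjacent instance pairs (multi-edges not double-counted; instances are
the units). The null permutes instance labels uniformly over the fixed
graph — the maximum-entropy distribution given the graph and the label
multiset — with the one-sided enrichment p = (1 + #{null ≥ obs}) / (B + 1)
at B = 1,000 permutations by default, and Bonferroni adjustment p × 2 ×
(number of tested pairs), capped at 1. Only pairs observed ≥ 5 times are
tested. Chains longer than two labels are out of scope.

## Colocalization quotient

CLQ_{A→B} = (C_{A→B}/N_A) / (N_B/(N−1)), with C_{A→B} the sum over type-A
cells of the fraction of type-B cells among each cell's k = 10 nearest
neighbours (self excluded). For A = B the denominator uses (N_A−1)/(N−1).
The direction convention is "B among the neighbours of A"; k is
configurable since the neighbour count behind a published CLQ is often
unstated. Under random labelling E[CLQ] = 1, which the calibration tests
verify together with centred label-permutation z-scores. Cross-group
comparison is a Welch test per ordered pair across samples with BH
adjustment and a recorded direction.

## Ligand–receptor nomination and validation

Discovery: for each colocalized type pair (L, R) and each ligand–receptor
gene pair, two-sided Wilcoxon rank-sum (normal approximation with tie
correction) of the ligand in type L and the receptor in type R between
groups; BH within each (cell type, gene role) family — pooling across cell
types would let a type with many strong signals distort another type's
threshold. A pair is nominated when both adjusted p < α = 0.05 and both
fold changes favour the colon. Types with fewer than 3 cells in a group
are skipped with a warning.

Validation: on an independent expression matrix, a prediction succeeds
when one-sided Wilcoxon (CL > SB) is BH-significant for both members in
their predicted types; predictions whose types or genes are absent are
dropped and counted. The null permutes the validation matrix's *gene
labels* (columns only), preserving every cell's count vector as a multiset
exactly, and recomputes the success count; p = (1 + #{null ≥ obs}) /
(B + 1), default B = 10,000. Because the success count is a small integer,
this deterministic p is discrete and conservative — under a fully null
matrix it is almost always exactly 1 — so the result additionally carries
the standard tie-randomized permutation p, which is exactly uniform under
the null and is the right quantity for calibration studies; the
deterministic p remains the primary reported value.

## Synthetic generator

The generator emulates the statistical structure the pipeline assumes:
horizontal zones with Poisson-process cell placement (so nearest-neighbour
distances have realistic variance, unlike a jittered grid) and zone-specific
type compositions; crypts whose composition blends linearly from an
override at the centre to the zone at the radius, with anchor cells placed
exactly at centres; follicles with distinct inner/outer compositions;
full-width bands; and "attraction" structures that relocate a
Bernoulli(strength) subset of source cells to uniform points within a
radius of random target cells — giving direct control of the planted CLQ.
Type-noise resamples a fraction of cells uniformly over all types,
strictly degrading spatial signal. Cohorts apply additive per-group
composition shifts (clipped, renormalised) and group-restricted
attractions, and can generate a donor covariate linear in a chosen type's
fraction plus Gaussian noise. Expression is negative-binomial with mean
baseline × 2^(sum of planted log2 fold changes) and fixed dispersion.

Defaults model the study conditions: 1000 × 1000-unit sections at 0.01
cells/unit² (~10,000 cells), three zones (mucosa 55%, submucosa 25%,
muscularis 20% of height), six crypts with 3 Paneth-like anchors each, one
follicle, a plasma band, a CL-only plasma→TA attraction of strength 0.5 at
radius 20, SB/CL shifts of +4% smooth muscle / −2% endothelium / +3%
plasma, 5% type noise; expression defaults are 100 genes (50 pairs), NB
mean 5 and dispersion 2, 2,000 cells per type per group, with +1.5 log2FC
planted on 10 pairs (ligand in plasma, receptor in TA, colon only). All
generators are pure functions of (config, seed).

What the generator does **not** emulate: cell morphology and segmentation
error, marker-intensity noise and cell-typing mistakes, anisotropic or
curved tissue geometry, batch effects between donors, spatial gradients of
expression within a type, and realistic gene–gene correlation. Passing
tests therefore demonstrate that the algorithms recover the structure they
are designed to detect under idealised sampling noise — not that they are
robust to upstream segmentation or annotation artefacts in real data.

## Numerical conventions

- Distance ties everywhere break by cell index (= cell id order after
  reads); maps of ≤ ~600 cells use an exact all-pairs path, larger maps a
  KD-tree with an exact fallback for tie groups straddling the query
  boundary.
- K-means: fixed `random_state`, `n_init=10`; clustering more clusters
  than distinct window vectors is an error rather than a silent downsize.
- The 85% context rule compares against θ·k with a 1e-9 guard so binary
  representation of θ cannot flip an exact-integer boundary.
- Welch tests on two identical constant groups report t = 0, p = 1 rather
  than NaN; zero-variance correlation inputs are flagged undefined.
- Empirical permutation p-values are +1-corrected; the minimum attainable
  p is 1/(B+1).
- TSV output uses fixed column order, `NA` for missing, 6-significant-digit
  floats; identical (input, config, seed) reruns are byte-identical, which
  the test suite asserts file-by-file.

## Problem sizes used in tests and the acceptance script

Module tests run on toy maps (tens to hundreds of cells) against O(N²)
brute-force oracles. System-level checks use the scales the methods are
meant for while staying desk-sized: CLQ calibration on 5,000-cell maps,
planted-zone recovery on ~10,000-cell sections, motif calibration on
~40-instance graphs with 200 shuffles × 199 permutations, the
ligand–receptor power study at 2,000 cells per arm × 20 seeds, and the
determinism check on an 8-section × ~10,000-cell cohort through the full
CLI. `scripts/acceptance.py` re-derives all of these from a single seed in
well under a minute of compute per section.

## Known limitations

- Cluster merging (30 → 20 named neighbourhoods) is user judgement by
  design; the pipeline cannot reproduce a published naming without it.
- The CLQ neighbour count k and the density denominator convention are
  configurable precisely because published analyses often leave them
  unstated; comparisons across datasets must fix them explicitly.
- Motif testing treats the instance graph as fixed; it does not model
  uncertainty in the segmentation of patches themselves.
- The discovery Wilcoxon uses the normal approximation, adequate at the
  tested group sizes (≥ 3 cells enforced, hundreds typical) but not exact
  for very small groups.
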