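# Methods

This note documents the models and procedures implemented in `pathpsn`,
the parameters that matter, the synthetic study design the tests run on,
and the numerical and design choices that were genuinely open.

## Pipeline overview

Given two-class multi-omics count matrices (molecule × sample), a
pathway collection (GMT), optional ncRNA→target relations and an
optional binary mutation matrix with an interaction network, a fit
proceeds:

1. normalize each ome (CPM, log2(x+1); zero-count molecules dropped);
2. propagate mutations into continuous scores (random walk with
   restart) and select significantly class-biased mutated genes;
3. per ome, compute elFC / vlFC and select molecules with the moderated
   t gate; ncRNA target sets passing the anti-correlation test join the
   pathway collection as candidates;
4. hypergeometric over-representation analysis over the combined
   molecule universe, BH-corrected; assign each enriched pathway a
   direction category; flag pathways containing mutated genes;
5. freeze per-molecule min-max scaling on the fitting samples, build
   one patient similarity network per enriched pathway, score
   separability power, keep power ≥ 1, compute centralities, sparsify;
6. train one GraphSAGE classifier per signature network, gate on
   validation MCC; accepted models vote on unknowns by majority.

Cross-validation wraps steps 1–6 in a stratified k-fold loop. Test
patients never influence feature selection, scaling parameters, network
retention or training: they enter a network only through
`attach_unknowns`, which adds their edges to training nodes without
touching training–training edges.

## Statistics

**Fold changes.** elFC = log2((ADV_case+ε)/(ADV_control+ε)) on class
means; vlFC likewise on coefficients of variation (sample SD / mean,
ddof = 1); stability = −vlFC. The pseudocount ε = 1e−8 keeps the ratios
finite for zero means or constant molecules; it is far below the
post-normalization value scale (log2 CPM, units of ~1–20), so it does
not distort non-degenerate molecules. Both statistics are antisymmetric
under swapping the class roles.

**Moderated t.** The per-molecule pooled variance (df = n1+n2−2) is
shrunk toward the grand mean of pooled variances with a fixed prior
df = 4, and the p-value uses a t distribution with residual+prior df.
The shrinkage target and prior weight are deliberately simple: the point
is a stabilized variance for small cohorts, not a full hierarchical fit.
Significant molecules (BH-adjusted p ≤ α, default α = 0.05) are ranked
by rank(|elFC|) × rank(|vlFC|), smaller is better, so a molecule must
be extreme on *both* axes to rank highly.

**ncRNA–target link.** Spearman correlations of the ncRNA with its
measured targets versus with up to 200 background genes; a one-sided
two-sample Kolmogorov–Smirnov test asks whether the target-correlation
distribution is stochastically smaller, and the set is kept only when
additionally the median target correlation is negative (the sign gate
stops a significant KS statistic on the wrong side from passing). Fewer
than 5 measured targets → not testable, not kept.

**ORA.** Hypergeometric upper tail on the overlap between selected
molecules and each pathway (intersected with the universe and
size-filtered to [5, 500]); BH across tested pathways; kept at adjusted
p ≤ α with overlap ≥ 3. The universe is every molecule measured after
normalization across the continuous omes. The implementation agrees
with exhaustive enumeration over all selections on small universes
(tested at C(20,4) and C(20,5)).

**Categories.** Significant members vote by their (elFC, stability)
quadrant: (+,+) activated by cases, (−,−) activated by controls, (−,+)
inhibited by cases, (+,−) inhibited by controls. Plurality wins; ties
break toward the quadrant with the larger mean |elFC|; members at the
exact origin abstain. Zero coordinates on one axis count as positive —
an arbitrary but fixed convention that only matters for exactly-zero
statistics.

## Similarity and separability

`Sim = Comp1 · Comp2 / 2` with Comp1 = Σmin/Σmax over the pathway's
molecules (0/0 → 1: the profiles are identical) and Comp2 = the mean of
the two patients' molecule averages, flipped to 1 − mean for inhibited
pathways. Inputs are per-molecule min-max scaled to [0, 1] (constant
molecules map to 0.5, a neutral intensity), so Sim ∈ [0, 0.5]. Scaling
parameters are frozen at training time and applied with clipping to any
later sample — the intensity component is only meaningful on a bounded
scale, and freezing prevents information leaking from test samples into
the training-time networks. For ncRNA target-set pathways the profile
concatenates the ncRNA's row (from its ome) with the targets' rows
(from the gene ome), each scaled within its own ome.

**Percentile schedule.** Ten levels; the low percentile falls linearly
0.35 → 0.10 and the high percentile rises 0.65 → 0.90. Quantiles use
linear interpolation between order statistics; comparisons are strict,
so an all-equal network scores 0. The power is the highest *consecutive*
level passed, and the two orientations are mutually exclusive (level-1
success in both directions is arithmetically impossible), so each
signature network has a unique cohesive class. The schedule endpoints
are fixed by the scoring description; the linear interpolation between
them is this package's choice and is configurable
(`power_low_range` / `power_high_range` / `power_levels`).

**Sparsification.** Each patient marks its top ⌈keep_fraction·(n−1)⌉
edges (default keep_fraction = 0.2, configurable); the union of marked
edges survives. Unknown patients attached later keep their top
⌈keep_fraction·n_train⌉ edges under the same rule.

## Centrality, stratification, PSN²

Raw centrality = Median(similarities to own class, self excluded) ×
(1 − Median(similarities to other class)) / 2, min-max scaled within
each network so the most central patient is exactly 1 (if all raw
values tie, everyone scales to 1). Cohesive-class patients are
stratified by k-means on their scaled-centrality vectors across
signature networks; each network is assigned to the subgroup of its
most central cohesive patient. The PSN² weight between two patients is
the weighted Jaccard of their adjacency columns (0/0 → 1; diagonal
entries are zero, so two connected patients' columns are never
literally identical). Representatives are chosen per class by k-means
on PSN² profiles (k = min(20, class size) by default, so a plot shows
at most 2k nodes) and laid out with the seeded Fruchterman–Reingold
algorithm.

## Graph classifier

Two GraphSAGE layers, hidden width 16: `h' = ReLU(W_s h + W_n (Ā h))`
with Ā the row-normalized weighted adjacency (similarity magnitudes are
the information carrier), dropout 0.5 between layers, a linear softmax
head, cross-entropy on training nodes, Adam at learning rate 0.01, at
most 200 epochs with early stopping on validation loss (patience 20).
Node features are the class one-hot plus a known-indicator for training
nodes and all-zeros for validation/test nodes: validation and test
labels are never encoded in features, which makes the gate and the test
predictions honest. The defaults are standard small-graph settings and
all live in `RunConfig`. A model is accepted iff its validation MCC ≥
`acceptance_mcc` (default 0.5 — "performs clearly better than chance");
rejected models cannot vote, and an exact vote tie goes to the class
with the higher mean predicted probability. The implementation is plain
numpy with hand-written gradients and Adam: the graphs have tens of
nodes, so this is fast, dependency-free and bit-reproducible from the
run seed (each network's training seed is derived from the run seed and
the pathway id).

Mutation propagation iterates `F ← (1−α)·F0 + α·F·S`, S the
symmetrically degree-normalized adjacency, restart α = 0.7 (standard in
the network-propagation literature; configurable), to L1 tolerance
1e−6; this is a contraction for any α ∈ (0,1), per-sample mass is
restored to the input mass afterwards, and the fixed point matches the
direct linear solve (tested on a 3-node path). Genes missing from the
network keep their scores with a warning.

## Synthetic study design

The generator emulates RNA-seq-like data: per-molecule baseline means
drawn log-normal (median 100, log-sd 1), counts drawn gamma-Poisson
(negative binomial) with a target coefficient of variation (base CV
0.4). Planted pathways set, for the driving class, the designed mean
fold change (default elFC = 2, i.e. 4×, in the direction the category
dictates) and the designed stability (default CV ratio 2, the driving
class tighter). The default design is 40 patients per class, 300 genes,
three planted pathways of 15 molecules (one per category except
inhibited_control), ten background pathways, 30 miRNAs with one planted
miRNA whose ten targets are sampled with per-sample means decreasing in
the miRNA's expression, and a 40-gene mutation layer with eight drivers
mutated at 0.6 vs 0.1 between classes over a small-world interaction
network. Gene-level structure (baselines, set membership, interaction
topology) comes from a separate `baseline_seed`, so cohorts generated
with different `seed` values represent new patients from the same
biology — which is what the external-cohort inference tests require.
Identical design + seed reproduce every output bitwise.

What the generator does *not* emulate: library-size artifacts, batch
effects, correlated background genes, dropout/zero inflation, or
overlap between planted pathways. Passing tests therefore demonstrate
that the pipeline recovers planted mean/stability structure and rejects
exchangeable noise — not that it is robust to real-cohort confounding.

The test and acceptance runs use this default scale (80 patients, ~330
molecules, ~14 candidate pathways, 5-fold cross-validation); a full fit
takes well under a second and the whole suite a few tens of seconds,
which makes the recovery and null-control replicate loops (10–20 seeds)
cheap.

## Known limitations

- Binary classification only; multi-class would need a different vote
  and separability definition.
- The moderated-t prior df is fixed, not estimated from the data.
- The eCDF anti-correlation test assumes enough measured targets (≥ 5)
  and exchangeable background genes.
- CPM normalization is compositional: very strong planted effects shift
  the library size and can drag background molecules past the
  significance gate (visible in small omes); ORA and the power filter
  absorb this in practice, but the selected-molecule lists themselves
  are not composition-corrected.
- `refit_with_predicted` re-runs the full pipeline with predicted
  labels merged in; it reports pathway confirmation, not a corrected
  significance level (no selective-inference adjustment).
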