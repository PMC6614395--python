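# Methods

This note records the modelling choices behind `targetrank`: what each
score assumes, the parameters that matter, what the synthetic worlds do
and do not emulate, and the numerical conventions adopted where the
procedure left room for interpretation.

## Modulation score

The score treats a perturbation as a candidate therapy for a disease when
the genes it down-regulates overlap the genes the disease up-regulates,
and vice versa. Raw co-occurrence counts are not comparable across
diseases (signature sizes differ) or across perturbations, so each count
is standardized twice — against all perturbations for that disease (row)
and against all diseases for that perturbation (column) — and the two
z-scores are summed. The two directions (up∩down, down∩up) are scored in
separate matrices and averaged, so a perturbation must oppose both halves
of a signature to score highly.

Conventions:

* **Population (N-denominator) standard deviation.** The background is
  the complete, fixed set of co-occurrence values in the row or column,
  not a sample from a larger population.
* **Zero-variance backgrounds contribute Z = 0.** A cell identical to a
  constant background carries no evidence either way; this also avoids
  division by zero.
* **Raw counts, no size normalization.** Signature size effects are
  absorbed by the row/column standardization; normalizing counts first
  would double-correct.
* Each background is computed within its own matrix; the matrices are
  only combined at the final averaging step.
* Scores may be negative (anti-reversal). Scaling to [0, 1] happens in
  the ensemble layer so that the modulation module's output remains
  interpretable as a signed z-scale.

At least two diseases and two perturbations are required — a single row
or column has no background and is rejected rather than scored.

## Tissue-specific score

The premise is that a useful target acts near the disease genes in the
tissue where the disease lives, and that paths through genes specifically
expressed in that tissue are more plausible routes of influence.

* **Subnetwork threshold z_E ≥ 1.0** keeps genes about one standard
  deviation more active in the tissue than average. Genes without an
  expression measurement are excluded (absence of evidence is not
  activity). The threshold is a parameter.
* **Edge costs.** Expression z-scores are min-max scaled to [0, 1] over
  the subnetwork, and the traversal cost of a node is 1 − scaled. Using
  scaled expression itself as cost would make highly expressed genes
  *expensive* and invert the intended behaviour; a `raw-costs` flag
  exposes that alternative for comparison. A constant expression vector
  scales to 0.5 everywhere.
* **The disease-gene exception** (an edge into d ∈ D is priced by its
  source) prevents a disease gene's own expression from discounting the
  final hop: the last step should be judged by the gene delivering the
  effect.
* **Destination weights c(d).** Disease genes are ranked by degree,
  cost-weighted betweenness and proximity-weighted clustering, aggregated
  by Borda (within-metric ties share a competition rank so an
  uninformative metric cannot distort the aggregate; aggregate ties break
  lexicographically), and cut into three equal buckets: 0.75 for the most
  central third, then 0.5 and 0.25. Centrality *amplifies* a disease
  gene's contribution: failing to be near the hub disease genes costs
  more than failing to be near peripheral ones. Fewer than three disease
  genes all get 0.5.
* **Unreachable disease genes are excluded and the average renormalized**
  rather than penalized with an arbitrary constant; the fraction reached
  is reported as `coverage` so callers can filter low-coverage scores.
  A gene reaching no disease gene gets an absent score, not a bad one.
* Betweenness distances use the mean endpoint cost per edge; clustering
  weights use the complementary proximity (1 − cost). Both are computed
  on the undirected subnetwork.

TSS is ≤ 0 by construction; 0 means every reachable disease gene is at
zero cost (in practice, the gene is itself a maximally expressed disease
gene).

## Safety scores

* **ADR score.** freq(a) is the fraction of annotated genes carrying
  category a — a gene-level relative frequency. With 17 broad categories
  every product is in [−1, 0); genes whose categories are rare end near
  0 and are flagged unsafe, on the premise that rare adverse-reaction
  classes are the severe ones. An unannotated gene gets an *absent*
  score: an empty product would equal −1 and silently claim "safest"
  for "no data".
* **Centrality score.** Per tissue, all subnetwork genes are Borda-ranked
  from most to least connected; a gene's score is the sum of its rank
  positions over tissues, with absent-in-tissue contributing that
  ranking's length + 1 (worst-plus-one) so totals stay comparable across
  genes with different tissue coverage. The set of tissues is a
  parameter — restricting to disease-relevant tissues is the caller's
  choice.
* **Onco-driven score.** A plain membership count over down-regulated
  oncogenic signature sets; 0 is a meaningful value (the gene appears in
  none), so it is not treated as missing.
* **Combination.** Components are oriented so larger = more unsafe (ADRS
  is already so after min-max scaling; centrality is flipped; onco is
  scaled directly), then combined with the normalized harmonic sum over
  whichever components are present.

## Ensemble layer

The harmonic sum follows the Open-Targets convention: sort descending,
weight 1, ½, ¼, …; the normalized variant divides by the maximum
attainable sum for the number of scores present, which keeps extension
pairs (targets covered by only one source) on the same [0, 1] scale.
Whether to normalize is a flag; normalized is the default used before
taking maxima with S_m or S_t. Known-drug evidence can be excluded from
aggregation via a column-exclusion parameter, since a benchmark against
known drugs must not see it. Missing scores are NaN everywhere, never 0,
and aggregations adapt to the values present. Final rankings break ties
by efficacy and then target id so benchmark percentiles are reproducible.

## Benchmarking

Normalized ppv divides the precision among the top k by the prevalence of
positives over the *full* ranked list — the expected precision of a
random ordering at any depth. Curves are reported to half the list by
default. Percentile depths use n = max(1, ⌊pct/100 · N⌋). The bootstrap
subsamples 80% of the gold standard without replacement 100 times
(resampling a fixed fraction is subsampling; a with-replacement mode is a
flag) and reports the (0.025, 0.975) percentile interval of the replicate
distribution. The ANOVA F statistic and Tukey's studentized range q are
computed from group sums of squares directly; scipy's F and
studentized-range distributions supply p-values, and Benjamini–Hochberg
adjusted p-values are reported across all pairs alongside the
Tukey-adjusted ones. Degenerate inputs are defined, not crashed: equal
groups with zero variance give F = 0, p = 1; perfect separation gives
p = 0.

## Synthetic worlds

The generator produces the complete input bundle with planted truth. The
default world has 500 genes, 5 diseases, 50 perturbed genes × 3
perturbations, signatures of 20 up + 20 down genes, 4 tissues over one
interactome of average degree 16 (physical interactomes are dense; ~20
interactions per protein is typical), 17 ADR categories with a geometric
frequency profile, 10 oncogenic sets, and 10% planted-unsafe genes.

* **Reversal signal.** One reverser perturbation per disease overlaps the
  disease signature in exactly ⌊ρ · 20⌋ genes in each direction (ρ = 0.8
  by default); null perturbations overlap one random disease binomially
  at rate 0.1 and fill the rest from genes outside every disease
  signature. Exact planted overlaps make the generator's contract
  testable by set arithmetic; binomial null overlaps give a realistic
  extreme-value background, so recovery power degrades smoothly as
  ρ approaches the null rate.
* **Tissue signal.** Each disease is assigned a tissue in which its 8
  disease genes and 5 proximal target genes are strongly expressed
  (z ∈ [1.5, 3]). Each target reaches 4 disease genes through a dedicated
  linker gene with z ∈ [3.5, 4] — above the ceiling of the N(0, 1)
  background, so the cheap routes into the disease module are the planted
  ones. Linkers keep only their planted edges and, being proximal by
  construction, are counted as positives alongside the targets.
* **Safety signal.** Planted-unsafe genes carry the rarest ADR
  categories, join oncogenic sets with probability 0.5 (versus 0.02),
  and are wired as hubs (+30 edges) expressed in every tissue at
  z ∈ [1.2, 1.8] — present and central in every subnetwork but not cheap
  conduits that would contaminate the tissue score.
* **Association table.** Per-source scores are uniform draws from
  [0.5, 1] for gold pairs and [0, 0.5] otherwise, with 30% of cells
  missing — a deliberately crude monotone-in-truth generator, sufficient
  to exercise the ensemble logic and missing-data contracts.

What the worlds do *not* emulate: scale-free interactome topology,
correlated evidence sources, ontology structure among diseases, shared
biology between diseases, or realistic signature sizes. Passing the
recovery tests therefore demonstrates that each score detects the
structure it assumes when that structure is present and calibrates to
chance when it is not — not that it will attain any particular accuracy
on real databases, whose benchmarks depend on specific releases.

## Problem sizes

The test suite evaluates 100 seeded worlds per recovery property (400
for the modulation power curve), 1000 random shuffles for ppv
calibration and 1000 null simulations for the ANOVA type-I error; the
full suite runs in about six minutes on one core. The acceptance script
uses 50/30/10 worlds for the modulation, tissue and safety summaries
respectively, 1000 calibration shuffles and 500 ANOVA simulations
(~2 minutes); these sizes give means stable to well within the
tolerances asserted.

## Known limitations

* The modulation score has no analytic null distribution; it is a
  ranking signal, not a calibrated p-value.
* TSS values are comparable within one tissue subnetwork but not across
  tissues (each is min-max scaled on its own genes).
* The absent-in-tissue penalty (length + 1) makes the centrality score
  depend on the tissue list supplied; scores computed over different
  tissue sets should not be mixed.
* With fewer than ~3 gold positives in a ranked universe, normalized
  ppv at shallow depths is extremely granular; benchmark conclusions
  need either deeper lists or aggregated replicates.
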