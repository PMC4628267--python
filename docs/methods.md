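# Methods

## Model and assumptions

`varfunc` rests on one biological premise: a family of homologous proteins
decomposes into subfamilies, each conserved at its own set of positions, and
each an implicit representative of a distinct set of molecular functions.  A
profile HMM built from one subfamily is then a probabilistic description of
"what it takes" to perform that subfamily's function, and the change in a
sequence's fit to that model under a point mutation measures how much of the
function the mutation gains or loses.

Given an aligned homolog family with a designated wild-type (query) row and
a substitution on the query, the pipeline (i) cleans and windows the
alignment, (ii) partitions the window rows into subfamily clusters
C₀…C₍k−1₎ with the query in C₀, (iii) builds one profile HMM per cluster of
size >1 and computes a per-cluster damage score for the variant, and (iv)
maps the target-cluster score S⁰ and the minimum other-cluster score Sˣ
through two logistic functions into a soft four-way classification.

The classification assumes that losing the original function and acquiring
a new one are independent events, and that the log odds of each are linear
in the cutoff t.  Both are modelling conveniences, not estimated
quantities; the confidences should be read as calibrated orderings, not
posteriors.

## Alignment processing

Parameters (all per-run configurable):

| parameter | default | meaning |
|---|---|---|
| identity threshold | 0.95 | a pair above this pairwise identity (matches / columns where both rows are ungapped) is redundant; the row with fewer residues is dropped, ties drop the later row; the query is immune |
| column gap threshold | 0.99 | columns with a greater gap fraction are removed |
| minimum window width | 10 columns | the region scored around the variant |
| extension gap threshold | 0.10 | secondary extension passes only columns below this gap fraction |

Redundancy removal is greedy in input order, which makes it deterministic
and idempotent.  Window growth alternates left-first, one column at a time,
through columns where the query is ungapped (keeping the query contiguous);
only if both directions block before reaching the minimum width does it
continue through low-gap columns.  Extension clamps at the alignment edges,
and rows that are entirely gaps inside the window are dropped.  Identity is
computed over the ungapped overlap of a pair rather than all columns, since
the overlap is what the two sequences actually share.

## Subfamily clustering

The partition of window rows minimises a combinatorial entropy objective
with two terms.  The fit term is, summed over clusters and columns,

S_obs − Ŝ_exp,  with S_obs = ln( s! / ∏_a n_a! )

the log multinomial coefficient of the column's residue counts within the
cluster (gap counted as a 21st symbol), and Ŝ_exp the Monte-Carlo mean of
the same quantity for a random same-sized subset of the column (20 seeded
permutations by default).  A column conserved within a cluster has S_obs =
0 and contributes −Ŝ_exp; a cluster that is a random sample of the window
contributes ≈ 0.  The second term is the encoding cost of the partition
itself, ln( n! / ∏_c s_c! ).  Without it the fit term alone keeps paying
for finer partitions: shaving off a few rows that merely share noise
residues removes the full log-binomial of every polymorphic column from
S_obs while Ŝ_exp shrinks almost additively, so the optimum shatters noisy
subfamilies (measured on 10-column windows at 95 % conservation, the
shattered partition scores below the planted truth and frequently isolates
the query).  The encoding term charges exactly that currency — a split of a
cluster of a+b rows costs ln C(a+b, a) — so only splits supported by
consistent column-wise structure pay for themselves.  Both terms vanish for
the single-cluster partition, making any partition's objective directly its
improvement over not clustering.

Optimisation is greedy agglomeration: start from the average-linkage tree
on p-distance cut at height zero (identical rows together, everything else
a singleton), repeatedly apply the pair merge that most decreases the
objective, stop at a local minimum.  The objective is non-increasing across
accepted merges by construction.  The number of clusters is therefore an
output.  Restarts (default 3) redraw the permutation stream behind Ŝ_exp;
the best final objective wins.  Everything is deterministic given the seed.

The K-means baseline embeds rows as one-hot vectors over column × symbol
and takes the best of 100 seeded random initialisations by within-cluster
sum of squares, with k fixed by the user.  Partition quality is compared by
the Dunn index (minimum between-cluster distance over maximum
within-cluster diameter; higher is better) and the Davies–Bouldin index
(mean over clusters of the worst (scatter_i+scatter_j)/separation ratio
with medoid-based scatter; lower is better), both on p-distance.  A
partition whose largest diameter is zero makes Dunn infinite and is flagged
degenerate rather than silently clipped.

## Profile HMMs and the damage score

Each cluster of size >1 yields a match/insert/delete profile: columns with
cluster gap fraction ≤ 0.5 become match states; emissions are Laplace
(count + 1)/(s + 20) against a uniform background; transitions are
estimated from each row's observed state path with the same pseudocount.
Clusters of size 1 are retained in the partition object but excluded from
scoring — a single sequence cannot define a subfamily distribution beyond
its pseudocounts.

A sequence is scored by the forward algorithm in log space, in global mode
(the scored sequences are exactly the windowed region), as log₂ of the
ratio of its probability under the profile to its probability under the
background.  The damage score of a variant against one model is, in the
default **ratio** form, bitscore(wild)/bitscore(mutant), and in the
**difference** form bitscore(wild) − bitscore(mutant); in both, larger
means the mutant fits that subfamily worse, and the neutral fixed point is
1 (ratio) or 0 (difference).  The ratio form matches the scale on which
the default cutoff t = 2.7 and the "score > 2 is deleterious" convention
were established; it is, however, only meaningful where bit scores are
small or of mixed sign.  When every wild and mutant bit score is strongly
positive — as for the synthetic families below, where windows are gap-free
and highly conserved — all ratios compress toward 1 and no cutoff can
separate outcome types, whereas the difference form measures the fit change
in bits on an absolute scale.  The synthetic benchmarks therefore run the
pipeline in difference mode; real, divergent families are the intended home
of ratio mode.  If ratio mode encounters a zero-bit-score denominator, all
clusters of that variant are rescored in difference mode so scores stay
comparable, and the output records the mode used.

A variant whose wild and mutant bit scores fall below the significance
floor (default 0 bits) against every eligible model is reported as
`no_call` rather than forced into a class.  When no eligible non-target
cluster exists, the acquire probability is fixed at 0 — with nothing to
acquire from, the variant can only lose or conserve.

## Classification

L = σ(S⁰ − t) and A = σ(t − Sˣ); confidences L(1−A), LA, (1−L)A,
(1−L)(1−A) for LoF, SoF, GoF, CoF.  The predicted type is the maximum
confidence; exact ties resolve LoF → SoF → CoF → GoF.  Off ties this argmax
coincides with the threshold reading (L > 0.5, A < 0.5 ⇒ LoF, and so on);
on the A = 0.5 or L = 0.5 boundaries the tie order governs.  Calls whose
maximum confidence does not exceed 0.5 carry a low-confidence flag — for
such variants the individual L and A values are more informative than the
combined call.  Confidences are reported to three decimals; full precision
is kept internally.

The inverse logistics (t + ln(p/(1−p)) for loss, t − ln(p/(1−p)) for gain)
recover scores from reported probabilities; they round-trip with the
forward maps to 10⁻¹².

## Evaluation utilities

Annotation databases typically label variants only GoF or LoF, so the
confusion matrix is 2×4 (annotation × prediction) and the binary metrics —
sensitivity with respect to GoF, specificity, accuracy — are computed only
over the predicted-GoF/LoF block, with undefined ratios reported as
undefined rather than 0.  The ROC sweeps the cutoff t over a grid,
recomputes the restricted metrics at each point, drops undefined points,
and integrates trapezoidally with (0,0) and (1,1) anchors.  Confidence
filtering keeps calls whose maximum confidence strictly exceeds the floor.
Transactivity labels for TP53-style functional data use half-open
intervals — <20 nonfunctional, [20,75) partially functional, [75,140)
functional, ≥140 supertrans — assigning the boundary values 20/75/140 to
the upper class (the conventional strict inequalities leave them
unassigned).

## Synthetic families

The generator emulates exactly the structure the method presupposes and
nothing more.  Columns are interleaved round-robin in three kinds:
family-conserved (one residue shared by all subfamilies), signature (one
position, a distinct conserved residue per subfamily), and variable.  A
variable column carries a two-residue pool (R_a, R_b): every non-target
subfamily is conserved at R_a, while the target subfamily mixes R_a and
R_b evenly, so the column says nothing about the target's own function but
plenty about the others'.  Rows emit the relevant consensus with
probability equal to the conservation parameter (default 0.95), otherwise
a uniform alternative.  Planted variants then have clean score geometry:

* **LoF** — family-conserved column → residue absent everywhere: worse fit
  in every subfamily (S⁰ and Sˣ both ≫ 0);
* **SoF** — target signature column → another subfamily's signature
  residue: worse in C₀, neutral-or-better elsewhere;
* **GoF** — variable column, R_b → R_a: neutral in C₀, much better in the
  other subfamilies (Sˣ ≪ 0);
* **CoF** — variable column, R_a → R_b: neutral in C₀ (both residues
  common there), worse everywhere else.

Alignments are gap-free, residue background is uniform (no substitution-
matrix weighting), and there are no indels, rate heterogeneity, or
phylogenetic correlation between rows.  Passing the planted benchmarks
therefore demonstrates that the pipeline's machinery — windowing,
clustering, HMM scoring, classification — composes correctly on data
satisfying the model's assumptions; it says nothing about performance on
real families, where subfamily boundaries are soft, alignments are gapped,
and conservation varies along the sequence.

## Benchmark problem sizes

The repository's standing benchmarks use two-subfamily families of 10 rows
each (30 columns, conservation 1.0, 10 seeds) for planted-partition
recovery, and three-subfamily families of 12 rows each (40 columns,
conservation 0.95, 20 seeds, one planted variant per type per seed) for
end-to-end label recovery with a ≥80 % per-type bar — sizes chosen to be
comfortably informative for the statistics involved while keeping the full
suite fast on one CPU.

## Known limitations

* The CEO formulation here is a behaviourally faithful reconstruction, not
  a transcription of the original algorithm's internals; its
  expected-entropy term is Monte-Carlo estimated, so the objective value
  (not the comparisons that matter) drifts slightly with the shuffle count.
* Ratio-form scores are unstable near zero-bit denominators and compress
  for uniformly well-fitting sequences; difference mode is provided and
  recorded per run.
* Global-mode scoring assumes the variant window aligns end-to-end to the
  model; local/glocal modes are out of scope.
* Homolog search and alignment are upstream: the package consumes a
  prebuilt MSA and never calls PSI-BLAST or MUSCLE.
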