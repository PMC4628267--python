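# varfunc

Classify protein point mutations by their **functional outcome** — loss of
function (LoF), gain of function (GoF), switch of function (SoF), or
conservation of function (CoF) — from nothing but a multiple alignment of
homologous sequences.

Most variant-effect predictors answer a binary question (damaging or not).
For oncogenes, receptors, and enzymes that is often the wrong question: an
activating receptor mutation and an inactivating one are both "damaging"
but have opposite clinical meaning.  `varfunc` answers the finer question by
exploiting the subfamily structure of a protein family: homologs cluster
into subfamilies with distinct conserved positions, and each subfamily is an
implicit carrier of a distinct set of functions.  A mutation that abandons
the query's own subfamily signature but matches another subfamily's has
*switched* function; one that only abandons its own has *lost* it; one that
moves toward another subfamily without leaving its own has *gained*; one
that does neither has *conserved*.

## Method

For a variant at ungapped query position p:

1. **Alignment processing** — near-duplicate rows (>95 % identity over the
   ungapped overlap) are removed, gap-dominated columns (>99 % gaps) are
   dropped, and a window of ≥10 columns around the variant column is cut
   out, extending left/right through columns where the query is ungapped
   (then through columns with <10 % gaps if still too narrow).
2. **Subfamily clustering** — the window rows are partitioned into clusters
   C₀ … C₍k−1₎ (C₀ contains the query) by combinatorial entropy
   optimization: minimise, over clusters and columns, the log multinomial
   coefficient of the observed residue counts minus its expectation under
   random row permutations, plus the encoding cost ln(n!/∏ s_c!) of the
   partition itself.  k is an output.  A K-means baseline (best of 100
   seeded restarts on one-hot rows) and Dunn / Davies–Bouldin indices are
   provided for comparison.
3. **Profile-HMM scoring** — each cluster of size >1 becomes a profile HMM
   (match/insert/delete states, Laplace pseudocounts).  The wild-type and
   mutant window sequences are forward-scored in bits against each model
   Hₘ, giving per-cluster damage scores Sᵢᵐ (larger ⇒ the mutant fits that
   subfamily worse).  S⁰ is the score against C₀ and Sˣ the minimum over
   the other clusters.
4. **Soft classification** — with a user cutoff t (default 2.7):

   L = 1 / (1 + e^−(S⁰ − t)),   A = 1 / (1 + e^−(t − Sˣ))

   are the probabilities of losing the original function and of acquiring
   another subfamily's.  Assuming independence, the four confidences are
   L(1−A), L·A, (1−L)A, (1−L)(1−A) for LoF, SoF, GoF, CoF; the call is the
   argmax, ties broken LoF → SoF → CoF → GoF.

## Worked example

Simulate a three-subfamily family (12 rows each, 40 columns, 95 % column
conservation) with one planted variant of each type, then classify:

```sh
varfunc simulate --subfamilies 3 --rows 12 --width 40 --conservation 0.95 \
    --seed 1 --plant LoF --plant GoF --plant SoF --plant CoF --out fam
varfunc classify --msa fam/family.fasta --query sf0_r0 \
    --variants S1A,G6E,I2S,A3C --score-mode difference --seed 1 --out run
cat run/results.tsv
```

```text
variant S0      Sx      argmin_cluster L     A     conf_LoF conf_SoF conf_GoF conf_CoF predicted
S1A     3.6566  3.3837  1              0.722 0.335 0.480    0.242    0.093    0.184    LoF
G6E     0.4129  -3.3718 2              0.092 0.998 0.000    0.092    0.906    0.002    GoF
I2S     3.6473  -3.4049 1              0.721 0.998 0.002    0.719    0.279    0.001    SoF
A3C     -1.3144 3.3610  1              0.018 0.341 0.012    0.006    0.334    0.648    CoF
```

Reading the first row: mutating the family-conserved S1 makes the mutant
fit the query's own subfamily ~3.7 bits worse than the wild type (S⁰), and
every other subfamily worse too (Sˣ = 3.38 > t), so the loss probability is
high (0.722) while the acquire probability is low (0.335) — a loss-of-
function call.  I2S instead lands on another subfamily's signature residue:
the mutant fits cluster 1 *better* than the wild type does (Sˣ = −3.4), so
both L and A are high and the call is switch of function.  All four planted
outcomes are recovered.

`varfunc evaluate` compares a results table against GoF/LoF database
annotations, reporting the 2×4 confusion matrix and sensitivity /
specificity / accuracy restricted to the predicted-GoF/LoF block.

## Scope

The pipeline starts from a prebuilt alignment (PSI-BLAST homolog search and
MUSCLE alignment are upstream of this package; the documented MUSCLE
parameters for that stage are `-maxiters 1 -diags -sv -distance1 kbit20_3`).
Only protein substitutions in `A95E` notation are supported — no indels,
haplotypes, or DNA input.
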