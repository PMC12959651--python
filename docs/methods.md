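# Methods

## Scope and coordinates

`delpath` classifies short sequence-retaining protein deletions — in-frame
events removing 1–10 residues without altering the downstream sequence.
All coordinates are 1-based closed intervals on the protein.  Deletions at
position 1 are rejected (start-codon loss prevents translation; there is
nothing to classify).  The 10-residue cap corresponds to the 30-nucleotide
in-frame limit that excludes exon-skipping events.  Genomic/transcript
input is deliberately out of scope: users pre-map coordinates with a
transcript-aware tool (TransVar, VEP) and supply protein-level variants.
Duplicate variants — the same (protein, start, end) from several sources —
collapse to one record; duplicates with conflicting labels are dropped
with a warning, since neither label can be trusted.

## Features

**Context (5 features).**  Two position logos are built from the training
variants, one per class, over offsets −5…−1 and +1…+5 relative to the
deletion boundary.  Windows clipped at a terminus contribute only their
existing positions; an offset with zero observations gets uniform
frequencies and zero information.  Column information content is
`log₂20 − H` (bits), letter score = frequency × information, with raw
frequencies and no small-sample correction — the simplest defensible
choice, and the filter cascade guards against degenerate columns anyway.
A variant's four context features are its flank-residue scores summed per
side (≤ 5 upstream, ≤ 5 downstream) against each class logo; residues
absent from a logo column and positions beyond a terminus contribute 0, so
the sums are non-negative.  A fifth feature, the pathogenic-minus-benign
summed difference, completes the group; it can be disabled
(`include_diff_feature=False`).

**Content.**  Arithmetic means over the deleted residues of (a) any number
of amino-acid propensity scales (AAindex flat format or two-column TSV;
non-standard residues shrink the denominator, an all-`X` deletion makes
the feature unavailable) and (b) provider-supplied per-residue tracks:
conservation information content, solvent-accessible surface area, mean
substitution-pathogenicity score.  Recomputing these tracks from primary
databases/structures is out of scope; they enter through the
`AnnotationProvider` interface, which must be deterministic and must
report per-protein availability.  A variant on a protein with any
unavailable provider feature is excluded and listed ("prediction not
possible") rather than imputed.

**Position.**  Length; relative position = deletion midpoint / protein
length; distance to the nearer terminus = min(start − 1, L − end); protein
length; and binary overlap flags (closed-interval intersection; adjacency
is not overlap) against annotation tracks.  Palindromic regions — maximal
substrings reading identically in both directions, minimum length 5
(configurable) — are computed internally by centre expansion; all other
tracks (domains, repeats, TM, IDR, secondary-structure classes including
low-confidence model regions, last-exon window pre-expanded by its
50-bp-equivalent margin) are provider-supplied intervals.

**Gene/protein.**  Binary gene-class flags, gene age, and six centralities
of the undirected weighted interaction graph: degree (edge count),
closeness (component-restricted, normalised), betweenness (raw pair
counts), harmonic centrality, hub score (principal eigenvector of the
adjacency matrix, scaled to max 1), and Bonacich power centrality with
attenuation 0.9/λ_max and √n scaling.  Isolated nodes take 0 for the
distance-based measures.

The three fixed-width sequence segments (first five deleted residues,
five upstream, five downstream; `X`-padded — upstream on its distal side,
downstream on its C-terminal side) are extracted and stored for
sequence-encoding models but are never part of the tabular learner input,
and therefore bypass the filter cascade by construction.

## Filter cascade

Fit on training rows only, replayed as a fixed drop list elsewhere:

1. binary features whose minority class has ≤ 5 samples (unstable);
2. numeric features with exactly zero variance (strict equality — a column
   varying by 1e−12 is left to stage 3);
3. greedy Spearman scan in the canonical category-then-name registry
   order: a column whose |ρ| (average ranks for ties) with any already-kept
   column exceeds 0.8 is dropped, recorded against the first offending
   kept column.  Keeping the earlier column makes the cascade fully
   deterministic; the surviving set provably contains no pair above the
   threshold, and re-running the cascade on its own output drops nothing.

## Training

Evaluation honesty rests on protein-disjoint partitioning: variants of one
protein never appear on both sides of any boundary.  Proteins get a
protein-level class (majority label of their variants; ties resolve to
pathogenic, the conservative direction) and are split by stratified
shuffling — a 20 % test share per class — then the training proteins are
dealt round-robin per class into five protein-disjoint CV folds.  Folds
are protein-disjoint even though only the train/test boundary strictly
requires it; leakage through shared sequence context is cheap to avoid.

The base learner is LightGBM at library defaults plus determinism flags;
logistic regression (balanced class weights), random forest (100 trees)
and a linear-kernel SVM with probability estimates serve as framework
baselines, the non-tree learners wrapped with MinMax scaling.  No class
reweighting is applied to the tree learner, and probabilities are used raw
(no recalibration) against the 0.5 threshold.

**Feature refinement.**  RFE with the base learner produces a full
ranking; candidate sizes (top 10 … 190, step 10, truncated to the
available count) are scored by mean protein-disjoint CV AUC, and the
smallest size within 0.005 of the best is chosen — small feature sets are
preferred when indistinguishable from large ones.

**Hyperparameter search.**  Seeded random search (100 trials by default)
over learning rate, boosting type (gbdt/dart), number of leaves, L1/L2
regularisation, bagging fraction and frequency, minimum child weight,
minimum split gain, feature fraction, and minimum child samples, with mean
CV AUC as the objective.  The trial log records the incumbent after every
trial.  On well-separated data tuning moves AUC by well under 1 % — the
feature set, not the hyperparameters, carries the performance.

**Ensemble.**  `DeletionEnsembleClassifier` draws `n_splits` (default 5)
independent stratified protein-disjoint partitions seeded
`random_state + split`, and trains one model per CV fold of each —
25 models sharing one feature list.  Every stochastic step takes an
explicit recorded seed; refitting with the same seeds reproduces
predictions exactly.  Bundles persist as a directory of per-(split, fold)
model files plus a JSON manifest (features, parameters, seeds, protein
partitions).

## Three-state prediction

The mean of the 25 probabilities gives the binary call: pathogenic iff
p̄ > 0.5 (0.5 itself is benign).  The VUS test bootstrap-resamples the 25
probabilities (B = 1000), computes resample means m*, and doubles the
smaller inclusive tail `#{m* ≥ 0.5}`, `#{m* ≤ 0.5}`, divided by B and
capped at 1.  Inclusive tails and the cap are our resolution of the
under-specified tail convention; they make the degenerate all-0.5 ensemble
yield p = 1 (VUS) and a unanimous confident ensemble p = 0.  `p ≥ α`
(default 0.05) yields VUS; α = 1 disables abstention entirely, reducing
the predictor exactly to the binary one.  The bootstrap generator is
seeded from the global seed XOR a hash of the variant id, so calls are
independent of batch composition and order; the probability multiset is
sorted first, making the p-value exactly permutation-invariant.

## Evaluation

Confusion counts are real-valued (fold-averaged and class-normalised
counts are fractional).  Pathogenic is the positive class; VUS calls enter
only the missing count and fraction, all ratio metrics being computed on
the classified subset.  MCC returns 0 on a vanishing denominator; any
other zero denominator yields 0 with a warning.  OPM is the product
`(PPV+NPV)(Sens+Spec)(Acc+(1+MCC)/2)` divided by 8 — with all six
components at their ideal values the product is 2·2·2 and OPM = 1.  AUC is
the rank-based (Mann–Whitney) statistic with average ranks for ties.
Class normalisation scales the benign row (TN, FP) by the
pathogenic-to-benign total ratio; every ratio metric is algebraically
invariant to which row is scaled, so the direction affects displayed
counts only.  Display rounding is 2-decimal half-even; full precision is
kept internally.

## Synthetic data

The generator exists so every stage is testable offline, and its defaults
are the study conditions the pipeline targets.

`simulate_proteome` draws uniform-random sequences (80–400 residues) and
plants: non-overlapping domain intervals (~30 % coverage), disordered
(~15 %) and repeat (~6 %) regions, transmembrane segments in a quarter of
proteins, alternating secondary-structure stretches, a last-exon window
(final ~15 %); per-residue conservation elevated inside domains and
solvent accessibility depressed there (domains are conserved and buried);
a substitution-pathogenicity field tracking conservation with noise; a
sparse random interaction graph (~4 partners/protein); Bernoulli
gene-class flags and an integer gene age.  One seeded generator drives all
randomness; fixed seed ⇒ byte-identical output.

`simulate_variants` labels deletions pathogenic with probability 0.577 and
samples lengths from a geometric distribution truncated to [1, 10] with
the success parameter solved to match class-conditional means of 2.71
(pathogenic) and 4.11 (benign) — the simplest family with mode 1 and those
means, mirroring curated clinical data where single-residue deletions
dominate both classes and pathogenic deletions run shorter.  Start
positions are drawn with weight `exp(±separation · conservation z-score)`
— pathogenic towards conserved/domain/buried positions, benign away from
them (hence towards termini, disorder, repeats).  The default separation
of 1.0 was calibrated once so the end-to-end synthetic study lands in the
regime real curated data produces (blind-test AUC ≈ 0.9, MCC ≈ 0.65)
rather than being perfectly separable.  Position 1 is never deleted.

`simulate_feature_table` skips sequences entirely: balanced classes,
standard-normal features with the first `n_informative` columns shifted by
`effect` SDs between classes, plus optional planted duplicate / constant /
rare-binary / monotone-transformed columns to exercise the filter.  Each
row is its own synthetic protein, so protein-disjoint machinery reduces to
plain row splitting.

**What passing synthetic tests does and does not show.**  The generator
reproduces the statistical *shape* the pipeline assumes — class-dependent
placement and length, annotation-correlated residue fields, redundant
feature structure — but not real-data pathologies: database-specific label
noise and class scarcity, phylogenetically correlated proteins, feature
distributions with heavy tails, or systematic missingness.  Recovery on
planted signal demonstrates the machinery is correct and leakage-free; it
does not certify real-data performance, which depends on the external
annotation resources.

A structural caveat on the null regime: with no signal at all, the 25
ensemble members still share training rows (~40–60 % pairwise overlap), so
they learn correlated noise functions and agree on which side of 0.5 an
unseen variant falls.  The bootstrap test reads that agreement as
evidence, so under a pure-noise null roughly a quarter to two-fifths of
variants are abstained as VUS rather than the large majority one might
expect from an "uninformative ⇒ uncertain" intuition.  The member
correlation is set by the split/fold geometry and is insensitive to the
learner or its regularisation; it is a property of consensus-based
abstention generally, not of this implementation.

## Problem sizes and numerical choices

Tests and the demo run at deliberately modest sizes chosen as scaled-down
but structurally faithful studies: 60–150 proteins / 150–400 variants for
sequence-level stages, 2 000 × 50 feature tables (5 informative, effect
2 SD) for end-to-end recovery, B = 200–1000 bootstrap resamples, 20
hyperparameter trials in the end-to-end run (100 remains the package
default).  Ties in Spearman ranks use average ranks; RFE eliminates one
feature per step; all tolerances (RFE 0.005 AUC, filter threshold 0.8,
α = 0.05) are exposed as parameters.  Degenerate inputs — empty proteomes,
all-`X` deletions, single-class folds, all-VUS evaluations, isolated graph
nodes — either take documented conventions or raise early with named
errors.

## Known limitations

* External annotations (conservation, accessibility, domains, gene
  classes, interaction networks) must be provided; the package never
  fetches or recomputes them.
* Only the deletion HGVS-p forms `p.X#del` and `p.X#_Y#del` are parsed.
* No probability recalibration or conformal abstention; the VUS mechanism
  is purely the ensemble-consensus bootstrap test, with the null-regime
  caveat above.
* Longer deletions (> 10 aa) and exon-skipping events are out of scope.
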