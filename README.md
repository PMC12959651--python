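# delpath

Pathogenicity prediction for short **sequence-retaining protein deletions**
— in-frame deletions of 1–10 amino acids that remove residues without
changing the downstream sequence.  Such deletions are common in clinical
variant databases, frequently misannotated, and sit awkwardly between the
well-served worlds of missense prediction and large structural variation.
`delpath` is a library + CLI for building and evaluating trainable deletion
classifiers with an explicit third output class: the **variant of uncertain
significance (VUS)**, for cases the model cannot confidently call either
way.

It is aimed at variant-effect method developers and computational
geneticists who want a reproducible, leakage-safe pipeline: feature
engineering over protein sequence and annotations, redundancy filtering,
gradient-boosted ensemble training with protein-disjoint validation, and an
abstaining three-state classifier.

## The model

Each deletion (protein `P`, 1-based closed interval `[start, end]`,
`end − start + 1 ≤ 10`, `start > 1` since removing the initiator methionine
abolishes translation) is described by four feature groups:

* **context** — sequence-logo bit scores of the five flanking residues on
  each side.  A class-specific logo assigns letter `a` at offset `o` the
  score `f_a(o) · IC(o)` with `IC(o) = log₂20 − H(o)` (Shannon entropy in
  bits); the flank scores are summed per side against a benign-trained and
  a pathogenic-trained logo;
* **content** — averages over the deleted residues: physicochemical
  propensity scales (AAindex-style), conservation, solvent accessibility,
  mean substitution-pathogenicity score;
* **position** — deletion length, relative position, distance to the
  nearer terminus, and overlap flags against annotation tracks (domains,
  repeats, transmembrane segments, disordered regions, palindromes,
  secondary-structure classes, last-exon window);
* **gene/protein** — gene-class flags (haploinsufficiency, housekeeping,
  essentiality, …), gene age, and six interaction-network centralities
  (degree, closeness, betweenness, harmonic, hub score, Bonacich power).

Features pass a three-stage filter (rare binary features with minority
count ≤ 5; zero-variance columns; for every pair with |Spearman ρ| > 0.8
the later column in a deterministic registry order is dropped), then
recursive feature elimination picks the smallest feature count whose
cross-validated AUC is within tolerance of the best.

The classifier is an ensemble of **25 gradient-boosted models** (LightGBM;
5 protein-disjoint train–test splits × 5 protein-disjoint CV folds).  The
mean of the 25 probabilities `p̄` gives the binary call (pathogenic iff
`p̄ > 0.5`).  For the three-state output the 25 probabilities are bootstrap
resampled (B = 1000) and a two-sided test of `p̄ = 0.5` is performed:

    p = min(1, 2 · min(#{m* ≥ 0.5}, #{m* ≤ 0.5}) / B)

Variants with `p ≥ α` (default α = 0.05) are reported as VUS.

Evaluation uses PPV, NPV, sensitivity, specificity, accuracy, MCC, a
rank-based AUC, and the composite overall performance measure

    OPM = (PPV + NPV)(Sens + Spec)(Acc + (1 + MCC)/2) / 8,

each reported raw and after scaling one confusion-matrix row so both
classes have equal totals (all ratio metrics are invariant to which row is
scaled).  VUS calls enter only the missing count; metrics are computed on
the classified subset.

## Worked example

Everything below runs offline on a simulated study (150 proteins with
planted domains/disorder/conservation and a random interaction network,
400 labelled deletions with class-dependent placement and length):

```
delpath simulate --n-proteins 150 --n-variants 400 --seed 11 --out demo/sim
delpath featurize --fasta demo/sim/proteins.fasta --variants demo/sim/variants.csv \
    --tracks demo/sim/tracks.tsv --annotations demo/sim/annotations.tsv \
    --edges demo/sim/edges.tsv --gene-info demo/sim/gene_info.json --out demo/feat
delpath filter --features demo/feat/features.csv --registry demo/feat/registry.json --out demo/filt
delpath train --features demo/filt/features.csv --registry demo/filt/registry.json \
    --n-trials 5 --seed 2 --out demo/model
```

which prints

```
wrote 150 proteins, 400 variants to demo/sim
feature table: 400 rows x 38 features
38 -> 32 features (1 rare-binary, 0 zero-variance, 5 correlated dropped)
blind-test (3-state) MCC 0.71 OPM 0.62 AUC 0.95
```

The filter line itemises the cascade; the last line scores the held-out
protein-disjoint blind test (20 % of proteins never seen by the filter,
the feature selection, the hyperparameter search, or any of the 25
models).  `demo/model/blind_test_tristate.json` holds the full report —
here PPV 0.87, NPV 0.84, sensitivity 0.87, specificity 0.84, accuracy
0.86, MCC 0.71, OPM 0.62, with 4.2 % of blind-test variants abstained as
VUS.  Batch prediction and the coverage/performance trade-off:

```
delpath predict --model demo/model/model --features demo/filt/features.csv --out demo/preds.csv
delpath sweep-alpha --model demo/model/model --features demo/filt/features.csv \
    --truth demo/truth.csv --alphas 1.0,0.05,0.001 --out demo/sweep.tsv
```

The prediction CSV has one row per variant: mean probability, bootstrap
p-value, binary call, three-state call.  The sweep (here over all 400
simulated variants, training rows included) shows the characteristic
trade-off — at α = 1.0 nothing is abstained and the three-state predictor
equals the binary one; tightening α improves the metrics on the classified
subset while the missing fraction grows:

```
 alpha  n_vus  missing_fraction  ...  accuracy  MCC  OPM
 1.000      0            0.0000  ...      0.89 0.77 0.69
 0.050     22            0.0550  ...      0.91 0.82 0.76
 0.001     29            0.0725  ...      0.92 0.85 0.79
```

The same workflow applies to real data: FASTA proteins, a CSV/TSV variant
table (explicit coordinates or HGVS-p `p.X#del` / `p.X#_Y#del` strings),
TSV annotation intervals, and TSV numeric annotations.  Genomic
coordinates are out of scope — map them to protein coordinates first
(e.g. with TransVar or VEP).

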