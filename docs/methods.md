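# Methods

## Problem and model

`foldunits` identifies two kinds of structured regions in a protein
sequence, intended as candidate antigen constructs — fragments stable
enough to express, purify, and present for synthetic antibody selection:

1. **Consensus domains.** Sequence-based domain hits (Pfam/SMART/PROSITE
   style profiles and motifs) and structure-based hits (Gene3D style) are
   reconciled by overlap rules. One sequence-based hit covering more than
   50% of one structure-based hit ("good overlap") yields the span
   covering both as consensus. When several hits of one class overlap a
   single hit of the other class ("fragmented"), the structure-based
   hit(s) win, each becoming its own consensus domain. Isolated hits pass
   through unchanged. The >50% test divides the shared residue count by
   the structure-based hit's length, and is strict. A 1:1 pair at or below
   50% keeps the structure-based hit, consistent with the fragmented
   cases' preference for structural evidence. "Overlaps" means sharing at
   least one residue — the weakest reading that makes the rules
   deterministic. Components joining two or more members of both classes
   are treated as fragmented (all structure-based members kept). When
   consensus outputs of different components still overlap, they merge to
   their union span, recording the most frequent contributing rule
   (precedence on ties: good_overlap, fragmented_structure,
   fragmented_sequence, structure_only, sequence_only).

2. **Putative structural units.** Regions outside annotated domains that
   nevertheless look folded. Each residue gets a target score

       score = (0.8·order + 1.0·ss + 0.6·conservation
                + 0.1·antigenicity + 0.1·hydrophobicity) / 2.6

   i.e. a weighted mean of five per-residue signals, each normalized to
   [0, 1] per protein. Dividing by the weight sum keeps the score on
   [0, 1], which is the only reading under which the default calling
   cutoff of 0.52 is both attainable and discriminative; the raw weighted
   sum (maximum 2.6) remains available via `normalize_score: false`.
   Residues inside consensus domains, trans-membrane segments or signal
   peptides are masked and score exactly 0.

   Units are called by a 1-D density-grid clustering: the chain is
   partitioned into consecutive grids of 5 residues (the final grid may be
   shorter), each grid gets the mean score of its residues (masked zeros
   included), and the highest-mean grid above the cutoff seeds a
   candidate (leftmost on ties). The candidate grows one grid at a time;
   a grid is added only if it is free of masked or previously claimed
   residues and its own mean exceeds the cutoff, which also keeps the
   candidate's running mean above the cutoff. When both sides qualify,
   the side yielding the higher candidate mean is taken (left on ties).
   Growth stops when neither neighbor qualifies; candidates longer than
   40 residues are emitted with their mean score. Claimed residues —
   including those of too-short candidates — never re-seed, and seeding
   repeats until no eligible grid remains, so several units per protein
   are possible. At grid size 1 this procedure provably returns exactly
   the maximal runs of consecutive above-cutoff residues, which is the
   brute-force oracle the tests enumerate independently.

## Feature tracks

The five signals and their built-in sequence-only providers (all windowed
means with windows truncated at the termini, then min-max normalized per
protein; a constant raw signal normalizes to 0.5):

| feature             | provider                                   | window |
|---------------------|--------------------------------------------|--------|
| order               | 1 − normalized TOP-IDP disorder propensity | 21     |
| secondary_structure | max(helix, strand) Chou–Fasman propensity  | 9      |
| conservation        | 1 − column entropy / log₂20 over a homolog alignment | — |
| antigenicity        | Kolaskar–Tongaonkar propensity             | 7      |
| hydrophobicity      | Kyte–Doolittle hydropathy                  | 9      |

The score equation rewards order, so disorder propensity is inverted into
an order propensity. Conservation columns with fewer than two non-gap
symbols are uninformative and score 0.5; without an alignment the
conservation track defaults to a constant 0.5 (weight it to zero, or
import real evolutionary-rate output). Non-standard residue letters
(B, Z, U, O, …) map to X with a warning and contribute scale value 0.

These providers are deliberately simple propensity profiles, not
re-implementations of any named disorder/secondary-structure predictor;
users with real predictor output import it through the long-format track
TSV. Imported vectors are min-max normalized per protein per feature —
an identity when the raw values already span [0, 1] — with missing
positions filled with 0 first. Normalization is per protein rather than
global for self-containment: a protein's prediction never depends on
which other proteins were in the batch.

## Weight training

`grid_search_weights` exhaustively evaluates candidate weight
combinations (default grid {0, 0.1, …, 1.0} per weight, matching the
one-decimal precision of the published optimum), scoring each by the
residue-wise ROC AUC of the normalized target score pooled over all
proteins (micro-averaging, per the residue-wise framing). Masked residues
are excluded from both classes. The normalized score is invariant under
scaling all weights by a positive constant, so the grid contains
equivalent combinations; ties resolve deterministically by smaller weight
sum, then lexicographic order. AUC values are compared after rounding to
10 decimals so mathematically tied combinations (whose computed AUCs can
differ at machine epsilon) fall through to the sum tie-break. AUC itself
is the standard rank statistic with ties counted half
(`sklearn.metrics.roc_auc_score`); tests cross-check it against explicit
positive–negative pair counting. `threshold_sweep` reports sensitivity,
specificity and balanced accuracy over all observed cutoffs (predicting
positive at score ≥ cutoff) and marks the balanced-accuracy maximizer,
smallest cutoff on ties.

## Evaluation

Residue-level confusion counts exclude masked residues from all four
cells, consistent with domain regions being removed from scoring.
Percentages are rounded half-up to two decimals only at the reporting
layer. The interval-level benchmark scores each reference construct by
its best reciprocal overlap — 100·min(|a∩b|/|a|, |a∩b|/|b|) — against any
predicted unit (0 with no predictions), counts recoveries strictly above
the threshold (70% by convention), and summarizes with mean and sample
(n−1) standard deviation; at realistic benchmark sizes the n−1 choice is
negligible but it is pinned for reproducibility.

## Synthetic data

The generator emulates the statistical structure the target score
assumes: planted structured regions carry high feature signal, the rest
of the chain low signal. Defaults: 50 proteins of 220–400 residues, 1–2
planted units of 50–120 residues per protein (units separated by ≥25
residues and ≥10 from the termini, so distinct units resolve as separate
calls), inside/outside feature means 0.9/0.1 with Gaussian noise of
SD 0.05 clipped to [0, 1]. Residue composition is also skewed
(hydrophobic/order-promoting letters inside, disorder-promoting outside)
so the built-in providers separate the classes, not only the generated
tracks. Each protein draws from an independent stream keyed by
(seed, protein index), so datasets are reproducible and adding proteins
never perturbs existing ones. Five named annotation scenarios with
analytically known consensus outputs (good_overlap, fragmented_structure,
fragmented_sequence, sequence_only, none) use fixed geometries in the
first 160 residues; planted units then start after residue 170 so domain
masking never eats into them.

What the fixture does **not** emulate: real domain-database annotation
statistics, correlated errors of real disorder/secondary-structure
predictors, compositional biases of real proteomes, or boundary
ambiguity of real structured regions. Passing recovery tests therefore
demonstrates the pipeline's correctness and internal consistency, not
field accuracy on real proteins — published residue-level accuracies on
curated test sets (e.g. ~69% accuracy, ~70% balanced accuracy) depend on
datasets not reproducible from printed information, and this package
reproduces only their arithmetic.

## Numerical choices and limitations

* Coordinates are 1-based inclusive everywhere; no half-open
  representation leaks into files or reports.
* Window truncation (not padding) at the termini avoids phantom residues
  but makes terminal windows noisier.
* Min-max normalization is degenerate for constant signals (mapped to
  0.5, a deliberately uninformative value).
* The unit caller's extension rule is grid-wise; boundary placement is
  therefore quantized to the grid (±4 residues at the default grid of 5).
  The run sizes used in the recovery checks (50 proteins, ~75 planted
  units; 500 random oracle profiles) were chosen as the smallest sets
  whose summary statistics are stable to well under a percentage point
  across seeds.
* Trans-membrane and signal-peptide regions enter only as user-supplied
  mask intervals; no TM/SP predictor is bundled.
* The default weight grid has 11⁵ ≈ 161k combinations; with the scaling
  invariance this is redundant by one dimension, and large training sets
  may warrant a coarser grid (the grid is configurable everywhere).
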