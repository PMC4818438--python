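# foldunits

Structured-unit calling in protein sequences, for people who need to pick
a fragment of a protein that will actually fold — antigen-construct
design for synthetic antibody selection, expression-construct boundary
choice, and related structural-bioinformatics tasks.

The package identifies two kinds of structured regions:

* **Consensus domains** — sequence-based domain annotations (Pfam/SMART/
  PROSITE style) and structure-based ones (Gene3D style) reconciled by
  overlap rules: a sequence-based hit covering >50% of a structure-based
  hit yields their union span; fragmented many-to-one overlaps keep the
  structure-based hit(s); isolated hits pass through.
* **Putative structural units** — regions outside annotated domains that
  look folded anyway. Each residue *i* gets a target score

  ```
  S(i) = (0.8·order + 1.0·ss + 0.6·cons + 0.1·antig + 0.1·hydro) / 2.6
  ```

  from five per-protein-normalized signals (order = complement of
  intrinsic-disorder propensity, secondary-structure propensity, sequence
  conservation, antigenicity, hydrophobicity), with annotated-domain /
  trans-membrane / signal-peptide residues masked to 0. A density-grid
  clustering (grids of 5 residues; seed at the best grid above the 0.52
  cutoff; grow while the next grid stays above the cutoff) calls units,
  keeping those longer than 40 residues.

The weights come from an exhaustive grid search maximizing residue-wise
ROC AUC on labeled training residues — the same procedure
`foldunits train-weights` runs on your own data. Residue-level metrics
(sensitivity, specificity, accuracy, balanced accuracy, precision) and
a reciprocal-overlap benchmark (a construct counts as recovered when
min(|a∩b|/|a|, |a∩b|/|b|) > 70%) are built in.

Built-in feature providers are simple propensity-scale profiles
(TOP-IDP, Chou–Fasman, Kolaskar–Tongaonkar, Kyte–Doolittle); output of
real predictors can be imported as per-residue tracks instead. See
`docs/methods.md` for the full model, parameters and limitations.

## Worked example

Generate a synthetic dataset with planted structured regions, then
predict:

```bash
foldunits simulate --seed 5 --out demo
foldunits predict --fasta demo/proteins.fasta --domains demo/domains.tsv \
    --tracks demo/tracks.tsv --out demo/run
head -6 demo/run.units.tsv
```

```
# coordinates are 1-based, inclusive at both ends
protein_id	kind	start	end	length	mean_score	provenance
SYNP0000	putative_unit	51	100	50	0.9036	density_grid
SYNP0000	putative_unit	176	280	105	0.8964	density_grid
SYNP0001	putative_unit	16	120	105	0.8937	density_grid
SYNP0001	putative_unit	151	230	80	0.9028	density_grid
```

Each row is one called unit: its kind (`consensus_domain` units would
carry the consensus rule in the provenance column and a mean score of 0),
its 1-based inclusive boundaries and length, and the mean target score of
its residues — here ≈0.90, far above the 0.52 cutoff, because the planted
regions were generated with high feature signal. Compare with the planted
truth in `demo/labels.tsv`: the first protein's units were planted at
51–101 and 174–280, so the calls recover them to within one 5-residue
grid. `demo/run.scores.tsv` holds the per-residue score track and
`demo/run.summary.json` echoes the configuration (the default weights
0.8/1.0/0.6/0.1/0.1).

The same `predict`/`evaluate`/`train-weights`/`score` commands run on
real FASTA, annotation TSVs and imported predictor tracks; the Python API
(`foldunits.predict`, `foldunits.grid_search_weights`, …) exposes every
step individually.

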