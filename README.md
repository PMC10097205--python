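# lsp-suite

Prediction of **leaderless secretory proteins (LSPs)** in plants.

Plant cells secrete many proteins that lack the N-terminal signal peptide
(SP) of the classical ER–Golgi pathway. These leaderless secretory
proteins are hard to identify: secretome proteomics is plagued by
intracellular contamination, and almost no plant LSPs have been
independently validated, so there is no gold-standard training set.
`lsp-suite` implements a complete workflow for this setting, aimed at
plant proteomics groups who need to triage candidate LSPs from
secretome experiments:

1. **LSPDB construction** — partition a proteome's genes by secretory
   features (SP, GPI anchor, transmembrane domains) and secretome
   observation status into SEC (observed, classical features), SPT
   (features but unobserved), UNCLASSIFIED (observed, featureless — the
   LSP candidates) and NONSEC, with isoform-discordant and TM-only genes
   set aside.
2. **Tiered confidence scoring** — each UNCLASSIFIED protein is scored
   against three evidence categories, each worth the points of its
   highest qualifying tier:

   | points | PPI network | PFAM domain | GO term |
   |---|---|---|---|
   | 3 | > 1 SEC partner, ≤ 33 NONSEC partners | domain only on SEC + candidate | term only on SEC + candidate |
   | 2 | > 1 SEC partner, > 33 NONSEC partners | only on SEC/SPT/candidates | only on SEC/SPT/candidates |
   | 1 | an SPT partner whose own profile is > 1 SEC, 0 NONSEC | majority of carriers in SEC ∪ SPT | majority of carriers in SEC ∪ SPT |

   Totals map to confidence: **High ≥ 5**, **Medium 3–4**, **Low < 3**.
   A self-interaction (homodimer) is annotated at 0.5 points but never
   changes the label.
3. **Classifier training** — six training-data schemes (LSPpred1–2 train
   High/Medium candidates against non-secreted data; SPLpred1–4 train
   SP-removed classical secretory proteins against NONSEC under four
   sequence-modification designs). Within each class, sequences are
   redundancy-reduced to ≤ 40 % pairwise global-alignment identity.
   Sequences become ~200 numeric features (composition, per-residue
   entropy, GRAVY and windowed hydropathy, CTD encodings on property
   alphabets, isoelectric point, PTM motifs, terminal features). A
   **balanced random forest** (each tree fit on a class-balanced
   bootstrap) is trained with a stratified 75/25 split and 5-fold CV;
   the decision threshold is calibrated so each fold's false-positive
   rate stays at or below 5 %, the upper quartile of features by Gini
   importance is retained, and the final model is refit and reported on
   the held-out test data (balanced accuracy at the calibrated threshold
   and at 0.5).
4. **Bias estimation** — schemes that modify training sequences can teach
   a model to recognise the modification itself (e.g. a missing initiator
   methionine) instead of biology. The suite scores matched
   modified/unmodified pairs and reports the mean signed score
   difference, the evidence used to choose among schemes.
5. **Prediction** — trained LSPpred/SPLpred bundles score new FASTA
   input in high-confidence (calibrated threshold) or low-confidence
   (0.5) mode, plus an AND/OR consensus.

A synthetic-proteome generator (`lspsuite.synth`) produces fixtures with
planted signal peptides, compositionally shifted LSP-like sequences and
consistent PPI/PFAM/GO tables, so the whole pipeline runs and is tested
without any external data or predictors. SP/TMD/GPI calls are inputs
(plain TSV), never computed here.

## Worked example

```sh
lsp-suite synth --out fixture --seed 3
lsp-suite train --fasta fixture/proteome.fasta \
    --annotations fixture/annotations.tsv --ppi fixture/ppi.tsv \
    --pfam fixture/pfam.tsv --go fixture/go.tsv \
    --scheme SPLpred3 --out spl_bundle --seed 3 --n-trees 200
lsp-suite train --fasta fixture/proteome.fasta \
    --annotations fixture/annotations.tsv --ppi fixture/ppi.tsv \
    --pfam fixture/pfam.tsv --go fixture/go.tsv \
    --scheme LSPpred1 --out lsp_bundle --seed 3 --n-trees 200 --n-folds 3
lsp-suite predict --fasta fixture/proteome.fasta \
    --lsppred-bundle lsp_bundle --splpred-bundle spl_bundle -o predictions.tsv
```

The train commands print, to stderr:

```
SPLpred3: AUROC 0.994±0.012  threshold 0.746  balanced accuracy (threshold) 1.000  (0.5) 1.000
LSPpred1: AUROC 0.967±0.029  threshold 0.483  balanced accuracy (threshold) 1.000  (0.5) 1.000
```

i.e. five-fold cross-validated AUROC (mean ± sd), the FPR-calibrated
score threshold, and held-out balanced accuracy at that threshold and at
the 0.5 majority cutoff. Prediction writes one row per protein:

```
protein_id  lsppred_score  splpred_score  lsppred_high  lsppred_low  splpred_high  splpred_low  consensus_high  consensus_low
SEC0000.1   0.715000       0.735000       true          true         false         true         false           true
NSC0001.1   0.220000       0.035000       false         false        false         false        false           false
```

`*_high` means the score reached the calibrated threshold (expected FPR
≈ 5 %); `*_low` means it reached 0.5 (more sensitive, more false
positives); the consensus column combines the two modules (AND by
default).

The same workflow is available as library calls (`build_lspdb`,
`assemble_training_set`, `run_training_pipeline`, `estimate_bias`,
`predict`) — see `docs/methods.md` for the underlying model and the
design decisions.

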