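# esipred

Naive-Bayes prediction of E3 ubiquitin ligase–substrate interactions (ESIs)
from heterogeneous biological evidence.

Five evidence scorers — ortholog transfer of known interactions, enrichment
of (E3-side, substrate-side) protein-domain pairs, the analogous GO-term
pair enrichment, triangle/quadrilateral counts through the query edge in a
protein–protein interaction network, and per-E3 linear recognition motifs —
are each calibrated as binned likelihood ratios (LRs) against gold-standard
positive/negative pair sets. A naive Bayesian classifier multiplies the
per-type LRs (keeping the maximum LR within each type) into a composite LR,
which a base-10 logistic normalization squashes to a confidence score in
(0, 1). Evaluation machinery covers stratified k-fold cross-validation with
full per-fold retraining, TP/FP-ratio cutoff curves, ROC/AUROC with a
Hanley–McNeil 95% CI, the C1/C2/C3 pair-input partition, and a one-tailed
Fisher's exact test. A seeded synthetic-world generator produces all input
files with controllable planted signal, so the entire pipeline runs with no
downloads.

## Library quick start

```python
import esipred as ep

world = ep.generate_world(ep.WorldConfig(seed=1))      # synthetic inputs
model = ep.train_model(world.gold, world.inputs(), seed=1)

pair = sorted(world.gold.positives)[0]
pred = ep.predict(pair, model, world.inputs())
print(pred.per_type_lr, pred.lr_comp, pred.score)

outcome = ep.kfold_cross_validate(world.gold, world.inputs(), k=5, seed=1)
print(ep.roc_auroc(outcome.records).auroc)
```

## CLI

A single entry point `esipred` with subcommands:

```sh
# generate a synthetic world (writes gsp.tsv, gsn.tsv, domains.tsv, go.gaf,
# ppi.tsv, orthologs.tsv, mouse_esi.tsv, proteome.fasta, truth.json)
esipred simulate --seed 1 --out world/

# sample a negative set from PPI edges incident to an E3 list
esipred negatives --ppi world/ppi.tsv --e3-list e3s.txt \
    --gsp world/gsp.tsv -n 500 --seed 1 --out gsn.tsv

# train a model archive (directory of TSV tables + JSON manifest)
esipred train --gsp world/gsp.tsv --gsn world/gsn.tsv \
    --domains world/domains.tsv --go world/go.gaf --ppi world/ppi.tsv \
    --orthologs world/orthologs.tsv --mouse-esi world/mouse_esi.tsv \
    --fasta world/proteome.fasta --model model/ --seed 1

# score a pair list / scan all (E3, protein) pairs above a score cutoff
esipred predict --model model/ --pairs query.tsv ...inputs... --out pred.tsv
esipred scan --model model/ --e3-list e3s.txt ...inputs... \
    --min-score 0.9 --out hits.tsv

# cross-validate (or score an independent holdout with --holdout-gsp/-gsn)
esipred evaluate --gsp world/gsp.tsv --gsn world/gsn.tsv ...inputs... \
    --folds 5 --seed 1 --out eval/
```

`evaluate` writes per-pair scores, the TP/FP cutoff curve, ROC points with
an AUROC summary, and per-class (C1/C2/C3) AUROCs. Model behavior (LR bin
edges, smoothing pseudocount, motif search parameters, enrichment filters)
is configurable via `--config config.yaml`; see `esipred.config.ModelConfig`
for the keys and defaults.

## File formats

- pair lists: TSV `e3 <TAB> substrate [<TAB> pubmed [<TAB> ISO date]]`
- annotations: two-column TSV (protein, label), or GAF 2.x for GO
- PPI network: edge-list TSV / PSI-MI TAB (first two columns)
- ortholog map: two-column TSV (source id, target id; one-to-many allowed)
- sequences: FASTA (accession = first header token; residues ACDEF…Y + X)

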