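# scsh

Sequence-clustering + structural-homology (SCSH) annotation toolkit for
phage proteomes.

## The problem

Most mycobacteriophage proteins have no informative annotation: sequence
homology alone leaves roughly two thirds of a typical proteome labelled
"hypothetical protein", because viral sequences diverge far faster than the
folds they encode.  Structure comparison finds those remote homologs, but
predicting a structure for every protein in a large proteome is
prohibitive.  The SCSH strategy makes it tractable in three steps:

1. **Cluster** the proteins by pairwise sequence similarity (greedy set
   cover over alignments with identity ≥ 0.5 and bidirectional coverage
   ≥ 0.9), so only one representative per cluster needs a structure.
2. **Model** each representative (externally, e.g. AlphaFold) and **search**
   the model against structure databases (externally, e.g. Foldseek with
   TM-score ≥ 0.5 and coverage ≥ 0.8).
3. **Transfer** the representative's best hit name to every cluster member.

This package implements everything around the external predictors: the
clustering semantics, hit filtering and best-hit selection, annotation
transfer, the summary statistics that quantify the result, and a seeded
synthetic-corpus generator with planted ground truth so the whole pipeline
is testable offline.  It is aimed at phage genomics groups who already have
alignment/search tool outputs and want a reproducible, scriptable way to
turn them into annotations and reports.

## The statistics at the core

With `n_all` proteins, of which `n_unannotated` carry "hypothetical
protein" products and `n_match` received a transferred structural hit,
`n_void` of those hits being uninformative (putative / hypothetical /
uncharacterized / domain of unknown function):

```
sequence-based rate  = (n_all − n_unannotated) / n_all
structure-based rate = (n_match − n_void) / n_all
```

Cluster quality is measured by per-cluster mean LDDT/TM of members aligned
to their representative, and by label consistency: over ordered pairs
(ref, other) of annotated members, a Pfam pair scores
`|pfam(ref) ∩ pfam(other)| / |pfam(ref)|`, EC codes are compared after
truncation to each of the four hierarchical levels, and the cluster score
is the mean over pairs.  Structural-homolog taxonomy is summarised by
lowest common ancestor over the hit lineages, and phage–host interaction
candidates are screened on the multimer confidence
`0.8·ipTM + 0.2·pTM` (network at > 0.5, stringent list at > 0.7).

## Worked example

`examples/06_synthetic_pipeline.py` generates a seeded corpus with planted
ground truth and runs the full workflow:

```
$ python examples/06_synthetic_pipeline.py
corpus: 92 proteins in 40 families
recovered 40 clusters; matches planted partition: True
sequence-based rate:  34.78% (planted 34.78%)
structure-based rate: 60.87% (planted 60.87%)
```

The clustering recovers the planted protein families exactly (the
generator keeps within-family and between-family identities separable),
and both annotation rates equal their planted values: about a third of the
proteins are annotated by sequence alone, while transferring structural
hits from cluster representatives annotates well over half — the gain the
workflow exists to deliver.  The other examples cover each capability in
isolation (clustering, transfer and rates, consistency scoring, LCA
summaries, interaction networks).

The same stages are available as a CLI over on-disk artifacts:

```
scsh simulate --seed 1 --out corpus/
scsh all --data corpus/ --out run/
```

`run/report.json` then holds the rates and purity summaries; each stage
directory carries its tables plus a manifest with the config hash.  All
thresholds default to the published tool parameters (`--min-seq-id 0.5`,
`-c 0.9`, `--tmscore-threshold 0.5`, `-c 0.8`, …) and can be overridden by
flags or a YAML config.

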