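# pentashape

High-throughput prediction of DNA structural features from sequence alone,
using a sliding-pentamer query table.

## The problem

Many proteins recognize DNA not only by reading its bases but by reading its
three-dimensional *shape* — most prominently the width of the minor groove.
Experimental structures of unbound DNA exist for only a tiny fraction of
sequences, and atomistic simulation of every sequence of interest is far too
slow for genome-scale work.  The way out is a lookup model: the shape of a
base pair is, to a good approximation, a function of its two nearest
neighbors on each side, i.e. of the pentamer centered on it.  If the average
structural features of all 512 pentamer classes (4^5 = 1024 pentamers merged
with their reverse complements) are tabulated once from
conformational-ensemble analyses of many short duplex fragments, the shape
profile of *any* sequence — up to whole genomes — can be computed instantly
by sliding a 5-bp window along it.

`pentashape` implements that method end to end for four features:

| feature | type | B-DNA norm | definition used here |
|---|---|---|---|
| MGW  | per bp   | ~5.8 Å | mean of three groove-width levels around the bp plane |
| ProT | per bp   | <0°    | propeller twist of the pair |
| Roll | per step | ~0°    | inter-bp roll of the two central pentamer steps |
| HelT | per step | ~35°   | helix twist of the two central pentamer steps |

The three-level MGW definition and the reverse-complement class merging make
every prediction exactly strand-independent: predicting a sequence and its
reverse complement gives mirror-image profiles, bit for bit.

The package also provides the validation machinery that goes with such a
model — palindromic symmetrization, filtering of deformed regions in
experimental structures (MGW > 8.5 Å or < 1.5 Å, HelT > 45°, |Roll| > 20°,
plus 3-bp flanks), concatenated Spearman rank correlation, per-dinucleotide
Roll/HelT summaries, and leave-one-out cross-validation — and a synthetic
data module that generates ground-truth pentamer models and corpora of
per-position structural records, so the entire pipeline is testable without
any external data.

## Worked example

```python
import numpy as np
from pentashape import PentamerShapeModel, dinucleotide_summary
from pentashape.synthetic import make_model, make_corpus

model = make_model(1)                # known ground-truth pentamer parameters
corpus = make_corpus(model)          # 2121 fragments, 12-27 bp
est = PentamerShapeModel(trim=2).fit(corpus)
print("classes:", est.coverage_["n_classes"],
      "mean occurrences: %.1f" % est.coverage_["mean_occurrences"])
p = est.predict("CGCGAATTCGCG")      # the Dickerson dodecamer
np.set_printoptions(precision=2, suppress=True)
print("MGW :", p.mgw)
print("Roll:", p.roll)
_, grand = dinucleotide_summary(est.table_)
print("mean HelT over the 10 dinucleotides: %.1f deg" % grand["HelT"])
```

prints

```
classes: 512 mean occurrences: 47.8
MGW : [ nan  nan 4.67 5.83 4.97 5.19 5.19 4.97 5.83 4.67  nan  nan]
Roll: [  nan  9.35 -6.35 -7.61 11.08  0.42 11.08 -7.61 -6.35  9.35   nan]
mean HelT over the 10 dinucleotides: 35.1 deg
```

All 512 pentamer classes are covered, each mined about 48 times.  MGW and
ProT are undefined at the two terminal bp and Roll/HelT at the terminal step
on each end (`nan` / `NA` on disk) — a pentamer cannot be centered there.
Because the dodecamer is palindromic, the profile is exactly symmetric about
its center.  The values themselves come from the synthetic ground-truth
model; with a table mined from real conformational ensembles the same code
produces physical profiles.

The same pipeline is available from the shell:

```sh
pentashape simulate --seed 1 --fragments 2121 --out records.tsv
pentashape build-table --records records.tsv --out table.tsv
pentashape predict --table table.tsv --in genome.fa --out profiles/
pentashape loocv --records records.tsv
pentashape validate --table table.tsv --records records.tsv
pentashape summarize-dinucleotides --table table.tsv
```

Inputs may be multi-record FASTA or one-sequence-per-line text, 5 bp to
10^6 bp per sequence (configurable); N-containing windows yield `NA` rather
than errors, so genome-scale FASTA with assembly gaps works directly.

## Scope

The package consumes per-position structural measurements (groove-width
levels, ProT, Roll, HelT per fragment); it does not run molecular
simulations, compute helical parameters from 3D coordinates, or predict
hydroxyl-radical cleavage.  See `docs/methods.md` for the model's
assumptions and numerical choices.
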