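# triads

Construction, permutation testing and annotation of **RNA–protein–DNA
interaction triads** from pairwise interactome peak data.

All-to-all RNA–chromatin interactome protocols (RADICL-seq, GRID-seq,
Red-C) are among the noisiest genomic assays: most captured RNA–DNA
contacts are nonspecific mRNA contacts, and contact density decays with
distance from the source gene (RD-scaling), swamping regulatory signal.
This package implements a two-stage filter: an RNA–DNA contact is kept
only when its DNA part lands in a ChIP-seq peak of a nuclear protein
*and* its RNA part lands in an RNA-IP peak (RIP/fRIP/eCLIP) of the same
protein on the same transcript. The surviving (RNA, protein, DNA-locus)
records — *triads* — are candidate protein-mediated regulatory contacts.
It is aimed at regulatory-genomics analysts who already have called
peaks (BaRDIC-style RNA–DNA peaks, MACS2 ChIP peaks, Piranha RNA-IP
peaks) and want to intersect, test and annotate them.

## Method

For a contact *c* and a protein *P*, a triad is emitted iff

* the DNA part of *c* intersects a ChIP-seq peak of *P* extended by
  2 kbp on both sides, by **≥ 19 bp**, and
* the RNA part of *c* intersects an RNA-IP peak of *P* on the same
  transcript, extended 100 bp toward the 3′ end, by **≥ 19 bp**.

Each triad aggregates the three peak-calling q-values into a harmonic
mean,

```
HMQ = 3 / (1/q_Piranha + 1/q_MACS2 + 1/q_BaRDIC),
```

and cis-contact density is normalised for RD-scaling with per-bin
weights `W = N(bin_i) / (L(bin_i) · ΣN) · 1e9` over geometric distance
bins from the gene.

Observed per-protein triad counts are tested against a
structure-preserving permutation null: ChIP peaks are shifted per
chromosome by ±{1,3,5,7,10} Mbp while conserving their A/B-compartment
annotation, and RNA-IP peaks are resampled 4:1 from "related" proteins
(similar RNA repertoires, Jaccard distance) versus unrelated ones,
preserving peak count and RNA-biotype composition. RNA–DNA contacts are
never shuffled. The empirical p-value uses the add-one estimator over
(by default) 10 000 replicates.

Downstream statistics include the paired Wilcoxon test for cis/trans
ratio shifts, χ² goodness-of-fit of triad DNA parts against the
protein's ChIP-peak chromatin-state composition (ChromHMM/SPIN groups),
common/specific RNA classification with a Fisher exact specificity
test, A/B-compartment densities, RNA-IP fold changes, Jaccard
similarity of triad datasets, and a windowed-correlation measure of
cross-protocol consistency of DNA-part coverage tracks.

## Worked example

A fully synthetic dataset (the `triads.synth` module generates every
input format, with 20 planted protein-mediated triads for protein P001
among noise contacts):

```python
import numpy as np
from triads import builder, background
from triads.synth import SynthConfig, generate, recovery_report

cfg = SynthConfig(n_proteins=8, n_rnas=40, contacts_per_rna=40,
                  pd_peaks_per_protein=100, pr_peaks_per_protein=80,
                  n_planted=20, planted_protein="P001", seed=303)
data = generate(cfg)

contacts = builder.filter_rd_by_peaks(data.rd_contacts, data.rd_peaks)
pd_ext = {p: builder.extend_pd_peaks(v, data.genome) for p, v in data.pd_peaks.items()}
pr_ext = {p: builder.extend_pr_peaks(v, data.genome) for p, v in data.pr_peaks.items()}
triads = builder.build_triads(contacts, pd_ext, pr_ext)

res = background.simulate_null("P001", contacts, pd_ext, pr_ext,
                               data.compartments, data.genome,
                               seed=17, n_reps=200)
```

This prints (via the obvious `print` statements):

```
1620 contacts, 851 inside RNA-DNA peaks
22 triads; planted protein P001 has 21
recovery vs truth table: recall=1.00 precision=0.91
P001: observed=21 null mean=0.03 null 95th pct=0.0 p=0.0050
example triad: RNA0018 x P001 @ chr4:13198515-13198685 HMQ=0.0296
```

Reading: of 1620 raw contacts, 851 fall inside an RNA–DNA peak of their
own RNA; the two-sided peak filter then leaves 22 triads, 21 of them
for the planted protein (all 20 planted records recovered, recall 1.0,
plus two coincidental triads). Shifting P001's ChIP peaks and
resampling its RNA-IP peaks 200 times essentially never reproduces that
count (null mean 0.03), so the observed count is significant at the
add-one empirical p of 1/201 ≈ 0.005 — the qualitative picture expected
for a protein that genuinely mediates RNA–chromatin contacts.

The same pipeline is available from the shell:

```sh
triads synth --seed 3 -o data/
triads build --contacts data/contacts.tsv --rd-peaks data/rd_peaks.bed \
    --pd-peaks data/pd_peaks.bed --pr-peaks data/pr_peaks.tsv \
    --genome data/genome.chrom.sizes -o triads.tsv
triads simulate --reps 200 --seed 3 ... -o sim.tsv
triads run --seed 3 -o run/        # end-to-end with a manifest
```

## Layout

* `triads.intervals` — genomic interval arithmetic, labeled tracks
  (compartments/states), BED/narrowPeak/chrom.sizes IO
* `triads.builder` — contact filtering, peak extension, triad assembly,
  HMQ, control-set subtraction and triad-set comparison
* `triads.background` — compartment-preserving ChIP-peak shift,
  relatedness-aware RNA-IP peak shuffle, empirical p-values
* `triads.stats` — cis/trans tests, scaling weights, state enrichment,
  Fisher/χ² tests, fold changes, consistency metrics
* `triads.synth` — synthetic data generator with planted-triad truth
  tables
* `triads.cli` — `triads synth|build|simulate|stats|run`
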