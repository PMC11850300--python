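# Methods

## The triad model

The package treats three pairwise interactomes as evidence layers for a
single object, the **triad** (RNA, protein, DNA locus):

* **RD** — RNA–chromatin contacts from all-to-all protocols
  (RADICL-seq, GRID-seq, Red-C): one stranded RNA interval on the
  source gene plus one DNA interval, with a gene id and biotype.
* **PD** — protein–DNA interactions as ChIP-seq peaks (MACS2-style,
  q-value filtered).
* **PR** — protein–RNA interactions as RNA-IP peaks
  (RIP/fRIP/eCLIP via Piranha), annotated to transcripts.

A contact is accepted as a triad of protein *P* when its DNA part
intersects an extended PD peak of *P* and its RNA part intersects an
extended PR peak of *P* annotated to the same transcript, both by at
least `min_overlap` bases. The underlying assumption is that bridge
ligation in interactome protocols is protein-mediated, so genuine
regulatory contacts should co-locate with both interaction layers of
some nuclear protein; contacts that do not are predominantly noise.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `pd_ext` | 2000 | bp/side | absorbs the restriction-site offset between the observed ligation point and the true contact (a cut site roughly every 256 bp) |
| `pr_ext` | 100 | bp toward 3′ | the RNA segment actually ligated tends to lie 3′ of the called RNA-IP peak |
| `min_overlap` | 19 | bp | discards grazing intersections of nearby contacts with extended peaks; applied independently to the DNA and RNA side, on the **extended** peaks |
| `ratio_related` | 0.8 | — | 4:1 related:unrelated mix of the PR-peak resampling pool |
| `n_reps` | 10 000 | — | permutation replicates; desk-scale runs use `--reps` |

When several peaks on one side clear the threshold, the maximal-overlap
peak is recorded, ties broken toward the smaller start coordinate, so
outputs are deterministic.

Each triad carries `HMQ = 3/(1/q_Piranha + 1/q_MACS2 + 1/q_BaRDIC)`,
the harmonic mean of its three source q-values. The harmonic mean is
dominated by the smallest q, lies between the extremes, and is monotone
in each argument, making it a usable single importance weight. The
RNA–DNA q rides on the contact from the peak-filtering step
(`filter_rd_by_peaks` attaches the best-overlap peak's q); contacts
used without that step carry q = 1, so their HMQ is conservative.

Cis-contact density is debiased with the RD-scaling weight
`W = N(bin)/(L(bin)·ΣN)·1e9` over geometric distance bins (default
edges 0, 1 kb, 2 kb, … ≥ 100 Mb, factor 2), distance being the gap
between the DNA-part midpoint and the nearest gene edge (0 inside the
gene). By construction Σ W·L = 1e9 whenever any contact exists, which
the suite asserts as an invariant.

## Permutation null

The null asks: how many triads would protein *P* accrue if its PD and
PR layers were random *but structurally similar*? RD contacts are never
permuted — their distance decay and compartment bias cannot be
regenerated by shuffling, and only the relative positioning of contacts
and peaks matters, so randomising the peak layers suffices.

**PD shift.** Per replicate and per chromosome, one magnitude is drawn
uniformly from {1, 3, 5, 7, 10} Mbp (restricted to magnitudes smaller
than the chromosome) and one sign uniformly; all of that chromosome's
peaks move by the signed amount. Coordinates wrap toroidally
(`new_start = (start + shift) mod (L − width)`), which conserves peak
count and width exactly. A peak whose shifted midpoint lands in the
opposite A/B compartment is relocated to the nearest position whose
midpoint lies inside a compartment block of the original type with the
peak fully inside the block; a peak wider than every candidate block is
centred on the nearest block with overhang, then nudged inward to stay
on the chromosome. Compartment labels are therefore conserved exactly
(asserted over 20 seeds), preserving the open/closed-chromatin bias of
ChIP data that would otherwise leak into the test statistic.

**PR shuffle.** Proteins are compared by the Jaccard distance between
their RNA repertoires. For each target protein the closest tercile of
the other proteins (plus itself) is its "related" set. The target's
peak set is resampled with replacement per biotype: `round(0.8·n_b)`
draws from the related pool and the rest from the unrelated pool, so
the output preserves count and biotype histogram exactly and at most
20% (+ one peak per biotype of rounding slack) originates from
unrelated proteins. A pool missing a biotype is backed by the other
pool with a logged warning. The phrase "top third of distances" in the
motivating description literally denotes the farthest tercile, which
contradicts its stated intent (related proteins share repertoires);
this package uses the closest tercile and exposes `farthest=True` for
the literal reading.

**Empirical p.** `p = (1 + #{sim ≥ observed}) / (n_reps + 1)` — the
add-one permutation estimator, never 0 and at most 1.

## Downstream statistics

* **cis/trans shift** — per-RNA trans fractions before (raw contacts)
  and after (triads), paired two-sided Wilcoxon signed-rank (scipy,
  exact method for ≤ 25 nonzero pairs; zero differences dropped; p = 1
  with no nonzero pair). Pairing per RNA is a documented choice; the
  alternative per-chromosome pairing is not implemented.
* **State enrichment** — per state, triad DNA-part bp over total
  DNA-part bp divided by the state's genomic share (gaps "."
  excluded from denominators). The χ² goodness-of-fit compares triad
  DNA-part state **counts** (midpoint assignment) against expected
  proportions from the protein's ChIP-peak midpoints; categories with
  expected count < 5 are merged into "other". A bp-weighted expected
  mode is available through `state_distribution` output.
* **Protein grouping** — proteins split at the median χ² p
  (strictly-below = "associated"; the median element is "other").
* **Common/specific RNAs** — an RNA in triads with ≥ 20 distinct
  proteins is "common". Fisher's exact test (two-sided) on
  (specific/common) × (ChIP overlap/none) contact counts scores
  per-protein specificity.
* **Fold change** — `FC(g) = (f_exp(g)+0.01)/(f_ctrl(g)+0.01)` with f a
  gene's fraction of its replicate's counts. The pseudo-count is added
  to the *fractions*, keeping FC dimensionless and bounded; adding it
  to raw counts would make FC depend on sequencing depth.
* **Cross-protocol consistency** — DNA parts of two triad sets are
  extended ±500 kb, binned at 10 kb, and compared by a centred
  sliding-window Pearson correlation (50 bins). A contact is consistent
  iff its unextended midpoint falls in a bin with local correlation
  ≥ 0.5 and both tracks nonzero there. This windowed correlation is a
  deliberate, simpler substitute for kernel-based track correlation; it
  finds the same object (regions of high local correlation) but is not
  numerically identical to kernel estimates, and bin size, window and
  threshold are configurable. Percentages are printed with banker's
  rounding to 2 decimals and trailing zeros trimmed.

## Synthetic data

The generator emulates the statistical structure the method relies on:

* genome of 4 × 20 Mb chromosomes (large enough for 10 Mb shifts),
  alternating 1 Mb A/B compartment blocks, 50 kb chromatin-state blocks
  drawn from configurable proportions;
* 47 proteins by default (the roster size of the motivating datasets);
  ChIP peaks placed with 2:1 A:B odds (~2× A density); RNA-IP peaks
  placed on genes and annotated with the gene's id and biotype;
* 100 RNAs with an mRNA-dominant biotype mix (0.70 mRNA by default);
  cis contacts (fraction 0.7) at distances from the gene edge drawn
  with density ∝ d^−α (α = 1 default; the decline is a stated power law
  with no published exponent), trans contacts uniform on other
  chromosomes;
* q-values uniform on (0.001, 0.05); all placement driven by one seed,
  so outputs are byte-identical across runs;
* planted triads: mutually overlapping RD contact, RD peak, PD peak
  and PR peak per truth-table record, loci ≥ 50 kb apart so extended
  peaks cannot bridge two records. With noise off, the pipeline must
  return exactly the truth table (recall = precision = 1), which the
  suite checks over 20 seeds.

What the generator does **not** emulate: read-level noise and peak
caller behaviour (peaks are placed, not called), replicate structure,
copy-number or mappability artefacts, chromatin-state autocorrelation
beyond block structure, and realistic chromosome-scale heterogeneity.
Passing tests therefore demonstrate correctness of the pipeline's
logic and statistics under controlled conditions, not performance on
real interactome data.

## Numerical choices and degeneracies

* Coordinates are 0-based half-open throughout; labels of intervals are
  taken at the midpoint (stable under symmetric extension and
  unambiguous on half-open partitions).
* Shift magnitudes infeasible for a short chromosome are redrawn from
  the feasible subset; a chromosome with no block of the required
  compartment type keeps the wrapped position with a warning.
* Zero-variance or empty windows in the consistency correlation are
  skipped (contacts there count as inconsistent).
* Degenerate Fisher margins return p = 1 with a warning; empty triad
  sets make recovery precision vacuously 1.0 with a warning.
* Problem sizes in the test-suite simulations (12 proteins × 520 peaks
  for the shuffle bound, 8 proteins × 1620 contacts × 200 replicates
  for planted-signal recovery) are the package's desk-scale reference
  conditions; production runs scale `n_reps` to 10 000.

## Known limitations

* The "shared with the negative control" predicate (same RNA, ≥ 1 bp
  DNA overlap) is the strictest reading consistent with the shared-triad
  definition; the bp threshold is configurable.
* The windowed consistency correlation is not a kernel correlation;
  absolute correlation values are not comparable across bin sizes.
* The relatedness tercile is computed per protein from the supplied
  dataset only; proteins absent from the input cannot contribute peaks
  to any pool.
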