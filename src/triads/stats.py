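"""Downstream statistics and annotation of triads.

Covers the cis/trans ratio shift test, distance-decay (RD-scaling)
contact weights, chromatin-state enrichment of triad DNA parts and the
chi-squared comparison against ChIP-seq peak state composition,
common/specific RNA classification with the Fisher specificity test,
RNA-repertoire Jaccard similarity between triad datasets, A/B-compartment
density, RNA-IP fold changes, and cross-protocol consistency of DNA-part
coverage tracks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .builder import RDContact, Triad
from .intervals import (
    Genome,
    GenomicInterval,
    LabeledTrack,
    binned_coverage,
    extend_interval,
    intersect_length,
)

logger = logging.getLogger(__name__)

#: default geometric distance-bin range for scaling weights
SCALING_BIN_MIN_BP = 1_000
SCALING_BIN_MAX_BP = 100_000_000
SCALING_BIN_FACTOR = 2.0
#: weights are expressed per Gb of bin length
SCALING_NORM = 1e9

#: cross-protocol consistency defaults
CONSISTENCY_EXT_BP = 500_000
CONSISTENCY_BIN_BP = 10_000
CONSISTENCY_WINDOW_BINS = 50
CONSISTENCY_CORR_THRESHOLD = 0.5

#: an RNA contacting at least this many proteins is "common"
COMMON_RNA_MIN_PROTEINS = 20


def cis_trans_label(contact: RDContact) -> str:
    """"trans" iff the DNA locus lies on a different chromosome than the
    RNA's source gene, else "cis"."""
    return "trans" if contact.is_trans else "cis"


def _trans_fraction_by_rna(records: Sequence[RDContact]) -> dict[str, float]:
    trans: dict[str, int] = {}
    total: dict[str, int] = {}
    for c in records:
        total[c.rna_id] = total.get(c.rna_id, 0) + 1
        if c.is_trans:
            trans[c.rna_id] = trans.get(c.rna_id, 0) + 1
    return {rna: trans.get(rna, 0) / n for rna, n in total.items()}


def cis_trans_shift_test(
    before: Sequence[RDContact], after: Sequence[Triad]
) -> tuple[float, float, pd.DataFrame]:
    """Paired Wilcoxon signed-rank test for a shift in per-RNA trans
    fractions between the raw contacts and the triad-filtered contacts.

    Each RNA present in both sets contributes one pair (trans fraction
    before, after); zero differences are dropped per the standard
    signed-rank convention and p = 1 when no nonzero pair remains.
    Returns (statistic, two-sided p, per-RNA table).
    """
    f_before = _trans_fraction_by_rna(before)
    f_after = _trans_fraction_by_rna([t.contact for t in after])
    shared = sorted(set(f_before) & set(f_after))
    if not shared:
        raise ValueError("no RNA present in both contact sets")
    table = pd.DataFrame(
        {
            "rna_id": shared,
            "trans_frac_before": [f_before[r] for r in shared],
            "trans_frac_after": [f_after[r] for r in shared],
        }
    )
    diffs = table["trans_frac_after"] - table["trans_frac_before"]
    nonzero = diffs[diffs != 0]
    if nonzero.empty:
        return 0.0, 1.0, table
    method = "exact" if len(nonzero) <= 25 else "auto"
    res = sps.wilcoxon(nonzero, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), table


@dataclass(frozen=True)
class ScalingBin:
    """One geometric distance bin of an RNA's cis-contact profile."""

    index: int
    lo: int  # bp distance, inclusive
    hi: int  # bp distance, exclusive
    n_contacts: int
    weight: float  # contacts per bp per total contact, scaled by 1e9

    @property
    def length(self) -> int:
        return self.hi - self.lo


def geometric_bin_edges(
    lo: int = SCALING_BIN_MIN_BP,
    hi: int = SCALING_BIN_MAX_BP,
    factor: float = SCALING_BIN_FACTOR,
) -> list[int]:
    """Distance-bin edges [0, lo, lo*f, ...] extended until >= hi."""
    edges = [0, lo]
    while edges[-1] < hi:
        edges.append(int(math.ceil(edges[-1] * factor)))
    return edges


def scaling_weights(
    contacts: Sequence[RDContact],
    gene_locus: GenomicInterval,
    edges: Sequence[int] | None = None,
) -> list[ScalingBin]:
    """Distance-decay normalisation weights for one RNA's cis contacts.

    The genomic distance of a contact is the gap between its DNA-part
    midpoint and the nearest gene edge (0 inside the gene body).  Contacts
    are counted in geometric distance bins and each contact in bin i gets
    weight N(bin_i) / (L(bin_i) * sum_i N(bin_i)) * 1e9, so that the
    weights integrate to 1e9 over bin length.
    """
    if edges is None:
        edges = geometric_bin_edges()
    counts = [0] * (len(edges) - 1)
    for c in contacts:
        if c.dna_part.chrom != gene_locus.chrom:
            raise ValueError(f"trans contact passed to scaling_weights: {c.rna_id}")
        mid = c.dna_part.midpoint
        if gene_locus.start <= mid < gene_locus.end:
            d = 0
        else:
            d = min(abs(mid - gene_locus.start), abs(mid - (gene_locus.end - 1)))
        i = int(np.searchsorted(edges, d, side="right")) - 1
        i = min(i, len(counts) - 1)
        counts[i] += 1
    total = sum(counts)
    bins = []
    for i, n in enumerate(counts):
        length = edges[i + 1] - edges[i]
        w = (n / (length * total)) * SCALING_NORM if total else 0.0
        bins.append(ScalingBin(i, edges[i], edges[i + 1], n, w))
    return bins


@dataclass(frozen=True)
class StateDistribution:
    """bp composition of a set of DNA intervals over chromatin-state
    groups, normalised against the genomic share of each state."""

    labels: tuple[str, ...]
    dna_part_bp: dict[str, int]
    state_bp: dict[str, int]
    normalized_density: dict[str, float]

    def fractions(self) -> dict[str, float]:
        total = sum(self.dna_part_bp.values())
        return {s: (self.dna_part_bp[s] / total if total else 0.0) for s in self.labels}


def state_distribution(
    dna_parts: Sequence[GenomicInterval],
    states: LabeledTrack,
    genome: Genome,
) -> StateDistribution:
    """Per-state bp of DNA parts and normalised densities.

    f_parts(s) = overlap bp of the DNA parts with state s / total DNA-part
    bp; f_genome(s) = state bp / covered genome bp; normalised density =
    f_parts / f_genome.  Gap label "." is excluded from the genome
    denominator; zero-bp states are dropped with a warning.
    """
    state_bp = {s: bp for s, bp in states.label_bp().items() if s != "."}
    for s in [s for s, bp in state_bp.items() if bp == 0]:
        logger.warning("state %s covers zero bp; excluded", s)
        del state_bp[s]
    labels = tuple(sorted(state_bp))
    genome_bp = sum(state_bp.values())
    part_bp = {s: 0 for s in labels}
    for part in dna_parts:
        for block, s in states.blocks(part.chrom):
            if s in part_bp:
                ov = intersect_length(part, block)
                if ov:
                    part_bp[s] += ov
    total = sum(part_bp.values())
    dens = {}
    for s in labels:
        f_parts = part_bp[s] / total if total else 0.0
        f_genome = state_bp[s] / genome_bp
        dens[s] = f_parts / f_genome
    return StateDistribution(labels, part_bp, state_bp, dens)


def state_counts(
    intervals: Sequence[GenomicInterval], states: LabeledTrack
) -> dict[str, int]:
    """Number of intervals whose midpoint lies in each state."""
    out: dict[str, int] = {}
    for iv in intervals:
        s = states.label_at(iv.chrom, iv.midpoint)
        out[s] = out.get(s, 0) + 1
    return out


def chisq_state_test(
    observed_counts: Mapping[str, int],
    expected_proportions: Mapping[str, float],
    min_expected: float = 5.0,
) -> tuple[float, float]:
    """Goodness-of-fit of triad DNA-part state counts against the state
    composition of the protein's ChIP-seq peaks.

    Labels whose expected count falls below `min_expected` are merged
    into an "other" category before testing (standard chi-squared
    validity rule).  Returns (chi2, p).
    """
    labels = sorted(set(observed_counts) | set(expected_proportions))
    n = sum(observed_counts.get(s, 0) for s in labels)
    prop_total = sum(expected_proportions.get(s, 0.0) for s in labels)
    if n == 0 or prop_total == 0:
        raise ValueError("empty observed counts or expected proportions")
    obs, exp = [], []
    merged_obs = merged_exp = 0.0
    for s in labels:
        e = n * expected_proportions.get(s, 0.0) / prop_total
        o = observed_counts.get(s, 0)
        if e < min_expected:
            merged_obs += o
            merged_exp += e
        else:
            obs.append(o)
            exp.append(e)
    if merged_exp > 0:
        obs.append(merged_obs)
        exp.append(merged_exp)
    if len(obs) < 2:
        raise ValueError("fewer than two categories after merging")
    chi2, p = sps.chisquare(obs, exp)
    return float(chi2), float(p)


def split_by_median_p(
    p_by_protein: Mapping[str, float]
) -> tuple[list[str], list[str]]:
    """Split proteins into an "associated" group (p strictly below the
    median) and the rest; the median element goes to "other"."""
    if len(p_by_protein) < 2:
        raise ValueError("need at least two proteins")
    med = float(np.median(list(p_by_protein.values())))
    associated = sorted(p for p, v in p_by_protein.items() if v < med)
    other = sorted(p for p in p_by_protein if p not in set(associated))
    return associated, other


def common_specific_split(
    triads: Sequence[Triad], threshold: int = COMMON_RNA_MIN_PROTEINS
) -> tuple[set[str], set[str]]:
    """RNAs in triads with >= threshold distinct proteins are "common";
    the rest are "specific"."""
    proteins_by_rna: dict[str, set[str]] = {}
    for t in triads:
        proteins_by_rna.setdefault(t.rna_id, set()).add(t.protein)
    common = {r for r, ps in proteins_by_rna.items() if len(ps) >= threshold}
    specific = set(proteins_by_rna) - common
    return common, specific


def fisher_specificity(
    contacts: Sequence[RDContact],
    chip_loci: Sequence[GenomicInterval],
    common_rnas: set[str],
) -> tuple[float, float, np.ndarray]:
    """Fisher exact test for a protein's ability to form specific
    contacts.

    Contacts are cross-classified as (RNA specific / common) x (DNA part
    overlaps >= 1 ChIP-seq locus of the protein / does not); the 2x2
    table rows are (specific, common), columns (overlap, no overlap).
    Returns (odds ratio, two-sided p, table).  A degenerate margin gives
    p = 1 with a warning.
    """
    from .builder import Peak, _best_peak, _tree_by_chrom

    loci = [Peak("chip", iv, 1.0, "PD") for iv in chip_loci]
    trees = _tree_by_chrom(loci)
    table = np.zeros((2, 2), dtype=int)
    for c in contacts:
        row = 1 if c.rna_id in common_rnas else 0
        col = 0 if _best_peak(c.dna_part, loci, trees, 1) is not None else 1
        table[row, col] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate margin in Fisher table %s", table.tolist())
        return float("nan"), 1.0, table
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def jaccard_rna_similarity(
    rna_sets_by_dataset: Mapping[str, set[str]]
) -> pd.DataFrame:
    """Pairwise Jaccard similarity of the RNA repertoires of triad
    datasets; empty-vs-empty pairs score 0 by convention."""
    names = list(rna_sets_by_dataset)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            sa, sb = rna_sets_by_dataset[a], rna_sets_by_dataset[b]
            union = sa | sb
            if not union:
                logger.warning("both RNA sets empty for %s/%s; Jaccard 0", a, b)
                v = 0.0
            else:
                v = len(sa & sb) / len(union)
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def compartment_density(
    dna_parts: Sequence[GenomicInterval],
    compartments: LabeledTrack,
    genome: Genome,
) -> dict[str, float]:
    """Number of DNA parts whose midpoint lies in each compartment label,
    normalised by the label's total bp."""
    label_bp = compartments.label_bp()
    counts: dict[str, int] = {lab: 0 for lab in label_bp}
    for part in dna_parts:
        lab = compartments.label_at(part.chrom, part.midpoint)
        if lab in counts:
            counts[lab] += 1
    return {
        lab: counts[lab] / bp for lab, bp in label_bp.items() if bp > 0 and lab != "."
    }


def pr_fold_change(
    gene_counts_exp: Mapping[str, int],
    gene_counts_ctrl: Mapping[str, int],
    pseudo: float = 0.01,
) -> dict[str, float]:
    """RNA-IP fold change per gene: the ratio of the gene's count
    fraction in the experimental replicate to that in the control, each
    with a pseudo-count of 0.01 added to the fraction."""
    total_exp = sum(gene_counts_exp.values())
    total_ctrl = sum(gene_counts_ctrl.values())
    if total_exp <= 0 or total_ctrl <= 0:
        raise ValueError("replicate totals must be positive")
    genes = set(gene_counts_exp) | set(gene_counts_ctrl)
    return {
        g: (gene_counts_exp.get(g, 0) / total_exp + pseudo)
        / (gene_counts_ctrl.get(g, 0) / total_ctrl + pseudo)
        for g in genes
    }


def format_percent(numerator: int, denominator: int) -> str:
    """Percentage rendered the way the consistency tables print it:
    round-half-even to 2 decimals, trailing zeros trimmed
    (2.9022 -> "2.9", 3.7946 -> "3.79")."""
    pct = Decimal(numerator * 100) / Decimal(denominator)
    q = pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)
    s = format(q.normalize(), "f")
    return s


@dataclass(frozen=True)
class ConsistencyResult:
    n_consistent: int
    pct_a: str
    pct_b: str
    total_a: int
    total_b: int
    windows: dict[str, np.ndarray]  # per-chromosome per-bin local correlation


def _rolling_corr(x: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling Pearson correlation; nan where either series has
    zero variance or is all-zero in the window."""
    n = len(x)
    out = np.full(n, np.nan)
    half = window // 2
    xf = x.astype(float)
    yf = y.astype(float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i - half + window)
        xs, ys = xf[lo:hi], yf[lo:hi]
        if not xs.any() or not ys.any():
            continue
        if xs.std() == 0 or ys.std() == 0:
            continue
        out[i] = float(np.corrcoef(xs, ys)[0, 1])
    return out


def cross_experiment_consistency(
    triads_a: Sequence[Triad],
    triads_b: Sequence[Triad],
    genome: Genome,
    ext: int = CONSISTENCY_EXT_BP,
    bin_size: int = CONSISTENCY_BIN_BP,
    window_bins: int = CONSISTENCY_WINDOW_BINS,
    corr_threshold: float = CONSISTENCY_CORR_THRESHOLD,
) -> ConsistencyResult:
    """Cross-protocol consistency of two triad sets' DNA-part tracks.

    DNA parts of both sets are extended by `ext` bp on both sides and
    turned into binned coverage tracks; a sliding-window Pearson
    correlation (window `window_bins` bins) localises regions where the
    two tracks agree.  A contact is consistent iff its unextended
    DNA-part midpoint falls in a bin whose local correlation is >=
    `corr_threshold` (windows where either track is flat or empty are
    skipped).  Percentages are reported in the trimmed two-decimal style.
    """
    if not triads_a or not triads_b:
        raise ValueError("both triad sets must be nonempty")
    ext_a = [extend_interval(t.dna_part, ext, ext, genome) for t in triads_a]
    ext_b = [extend_interval(t.dna_part, ext, ext, genome) for t in triads_b]
    cov_a = binned_coverage(ext_a, genome, bin_size)
    cov_b = binned_coverage(ext_b, genome, bin_size)
    corr = {
        chrom: _rolling_corr(cov_a[chrom], cov_b[chrom], window_bins)
        for chrom in genome
    }

    def is_consistent(t: Triad) -> bool:
        c = corr[t.dna_part.chrom]
        b = t.dna_part.midpoint // bin_size
        v = c[b] if b < len(c) else np.nan
        return bool(not np.isnan(v) and v >= corr_threshold)

    n_a = sum(1 for t in triads_a if is_consistent(t))
    n_b = sum(1 for t in triads_b if is_consistent(t))
    # one shared count is reported; with asymmetric sets the smaller
    # per-set count is the conservative choice
    n_consistent = min(n_a, n_b)
    return ConsistencyResult(
        n_consistent=n_consistent,
        pct_a=format_percent(n_a, len(triads_a)),
        pct_b=format_percent(n_b, len(triads_b)),
        total_a=len(triads_a),
        total_b=len(triads_b),
        windows=corr,
    )
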