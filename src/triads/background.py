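"""Structure-preserving permutation nulls for triad counts.

The observed number of triads per protein is compared against a null in
which the protein's pairwise interaction data are randomised while the
biological structure of the data is preserved:

* ChIP-seq (protein-DNA) peaks are shifted per chromosome by a random
  whole number of megabases drawn from {1, 3, 5, 7, 10}, up- or
  downstream, and any peak that would land in the opposite A/B chromatin
  compartment is relocated to the nearest stretch of its original
  compartment type.  Peak count, widths and compartment annotation are
  conserved exactly.
* RNA-IP (protein-RNA) peaks are resampled with replacement from a pool
  of peaks of "related" proteins (proteins with similar RNA repertoires,
  including the protein itself) and, in a 4:1 ratio, of unrelated
  proteins, preserving the peak count and RNA-biotype composition.

RNA-DNA contacts are never shuffled: their distance-decay structure
(RD-scaling) makes a faithful permutation impossible, and only the mutual
positioning of contact and peak matters for the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .builder import Peak, RDContact, Triad, build_triads
from .intervals import Genome, GenomicInterval, LabeledTrack, label_of

logger = logging.getLogger(__name__)

#: shift magnitudes in bp (1, 3, 5, 7 or 10 Mbp)
SHIFT_MAGNITUDES_BP = (1_000_000, 3_000_000, 5_000_000, 7_000_000, 10_000_000)
#: fraction of resampled PR peaks drawn from the related-protein pool (4:1)
RATIO_RELATED = 0.8
#: default number of permutation replicates
N_REPS = 10_000


@dataclass(frozen=True)
class RelatednessMap:
    """Pairwise RNA-repertoire distances between proteins and the derived
    related-protein sets."""

    proteins: tuple[str, ...]
    distance: np.ndarray  # symmetric, zero diagonal, values in [0, 1]
    related_sets: dict[str, frozenset[str]]  # includes the protein itself

    def is_related(self, target: str, other: str) -> bool:
        return other in self.related_sets[target]


@dataclass(frozen=True)
class SimulationResult:
    protein: str
    observed_count: int
    sim_counts: tuple[int, ...]
    empirical_p: float
    seed: int

    @property
    def n_reps(self) -> int:
        return len(self.sim_counts)


def protein_distance_matrix(
    pr_peaks_by_protein: Mapping[str, Sequence[Peak]],
    farthest: bool = False,
) -> RelatednessMap:
    """Jaccard distance between proteins' RNA lists and per-protein
    related sets.

    distance(p, q) = 1 - |RNAs(p) & RNAs(q)| / |RNAs(p) | RNAs(q)|.  For
    each protein the closest tercile of the other proteins (smallest
    distances, i.e. most-shared RNA repertoires) is labeled related,
    plus the protein itself.  `farthest=True` flips the tercile.
    """
    proteins = tuple(pr_peaks_by_protein)
    rna_sets: dict[str, set[str]] = {}
    for prot in proteins:
        rnas = {getattr(p, "rna_id", "") for p in pr_peaks_by_protein[prot]}
        rnas.discard("")
        if not rnas:
            raise ValueError(f"protein {prot} has no annotated RNAs")
        rna_sets[prot] = rnas
    n = len(proteins)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rna_sets[proteins[i]], rna_sets[proteins[j]]
            d = 1.0 - len(a & b) / len(a | b)
            dist[i, j] = dist[j, i] = d
    related: dict[str, frozenset[str]] = {}
    for i, prot in enumerate(proteins):
        others = [(dist[i, j], proteins[j]) for j in range(n) if j != i]
        others.sort(key=lambda t: (t[0] if not farthest else -t[0], t[1]))
        k = int(np.ceil(len(others) / 3)) if others else 0
        related[prot] = frozenset(name for _, name in others[:k]) | {prot}
    return RelatednessMap(proteins, dist, related)


def _relocate(
    chrom_len: int,
    width: int,
    target_mid: int,
    candidates: Sequence[GenomicInterval],
) -> int:
    """Nearest midpoint position to `target_mid` such that a peak of
    `width` fits inside one of `candidates` (same-label compartment
    blocks); a peak wider than every block is centred on the nearest
    block.  Ties break toward the smaller coordinate.  Returns the start
    coordinate, shifted inward if needed to stay on the chromosome."""
    left = width // 2
    right = width - left
    best: tuple[int, int] | None = None  # (distance, midpoint)
    for block in candidates:
        if block.width >= width:
            lo, hi = block.start + left, block.end - right
            mid = min(max(target_mid, lo), hi)
        else:
            mid = block.midpoint
        key = (abs(mid - target_mid), mid)
        if best is None or key < best:
            best = key
    assert best is not None
    start = best[1] - left
    return min(max(start, 0), chrom_len - width)


def shift_pd_peaks(
    peaks: Sequence[Peak],
    compartments: LabeledTrack,
    genome: Genome,
    rng: np.random.Generator,
) -> list[Peak]:
    """Shift every ChIP-seq peak by a per-chromosome random offset while
    conserving its A/B compartment annotation.

    Per chromosome one magnitude is drawn uniformly from
    {1, 3, 5, 7, 10} Mbp (restricted to magnitudes shorter than the
    chromosome) and one sign uniformly from {+, -}; all peaks of the
    chromosome move by that signed amount with toroidal wrap.  A peak
    whose shifted midpoint falls in the opposite compartment is relocated
    to the nearest stretch of its original compartment type.
    """
    chroms = sorted({p.interval.chrom for p in peaks})
    shifts: dict[str, int] = {}
    for chrom in chroms:
        feasible = [m for m in SHIFT_MAGNITUDES_BP if m < genome.size(chrom)]
        if not feasible:
            raise ValueError(
                f"chromosome {chrom} shorter than every shift magnitude"
            )
        magnitude = int(rng.choice(feasible))
        sign = 1 if rng.random() < 0.5 else -1
        shifts[chrom] = sign * magnitude

    blocks_by_label: dict[tuple[str, str], list[GenomicInterval]] = {}
    for chrom in chroms:
        for iv, lab in compartments.blocks(chrom):
            blocks_by_label.setdefault((chrom, lab), []).append(iv)

    shifted: list[Peak] = []
    for p in peaks:
        iv = p.interval
        chrom_len = genome.size(iv.chrom)
        width = iv.width
        orig_label = label_of(iv, compartments)
        span = max(chrom_len - width, 1)
        new_start = (iv.start + shifts[iv.chrom]) % span
        new_iv = GenomicInterval(iv.chrom, new_start, new_start + width, iv.strand)
        if label_of(new_iv, compartments) != orig_label:
            candidates = blocks_by_label.get((iv.chrom, orig_label))
            if not candidates:
                logger.warning(
                    "no %s compartment on %s; peak kept at wrapped position",
                    orig_label, iv.chrom,
                )
            else:
                s = _relocate(chrom_len, width, new_iv.midpoint, candidates)
                new_iv = GenomicInterval(iv.chrom, s, s + width, iv.strand)
        shifted.append(replace(p, interval=new_iv))
    return shifted


def shuffle_pr_peaks(
    protein: str,
    pr_peaks_by_protein: Mapping[str, Sequence[Peak]],
    relmap: RelatednessMap,
    rng: np.random.Generator,
    ratio_related: float = RATIO_RELATED,
) -> list[Peak]:
    """Resample a protein's RNA-IP peaks from related/unrelated pools.

    For each RNA biotype with n_b original peaks, round(ratio_related *
    n_b) peaks are drawn (with replacement) from the pool of
    related-protein peaks of that biotype and the remainder from the
    unrelated pool, so the output preserves the peak count and biotype
    histogram exactly.  A pool missing a biotype is backed by the other
    pool (warning logged).  Drawn peaks keep their original owner so the
    unrelated fraction remains measurable downstream.
    """
    if not 0 < ratio_related <= 1:
        raise ValueError("ratio_related must be in (0, 1]")
    own = list(pr_peaks_by_protein[protein])
    related = relmap.related_sets[protein]
    pool_r: dict[str, list[Peak]] = {}
    pool_u: dict[str, list[Peak]] = {}
    for prot, peaks in pr_peaks_by_protein.items():
        pool = pool_r if prot in related else pool_u
        for p in peaks:
            pool.setdefault(p.biotype or "other", []).append(p)

    out: list[Peak] = []
    biotype_counts: dict[str, int] = {}
    for p in own:
        b = p.biotype or "other"
        biotype_counts[b] = biotype_counts.get(b, 0) + 1
    for b in sorted(biotype_counts):
        n_b = biotype_counts[b]
        n_r = int(round(ratio_related * n_b))
        n_u = n_b - n_r
        # the related pool always holds biotype b (it includes the
        # protein's own peaks); the unrelated pool may not
        have_r, have_u = pool_r.get(b), pool_u.get(b)
        if n_r and not have_r:
            logger.warning("related pool lacks biotype %s for %s", b, protein)
            n_u += n_r
            n_r = 0
        if n_u and not have_u:
            logger.warning("unrelated pool lacks biotype %s for %s", b, protein)
            n_r += n_u
            n_u = 0
        if n_r:
            idx = rng.integers(0, len(have_r), size=n_r)
            out.extend(have_r[i] for i in idx)
        if n_u:
            idx = rng.integers(0, len(have_u), size=n_u)
            out.extend(have_u[i] for i in idx)
    return out


def unrelated_fraction(
    shuffled: Sequence[Peak], protein: str, relmap: RelatednessMap
) -> float:
    """Fraction of a shuffled peak set drawn from the unrelated pool,
    judged by each drawn peak's original owner."""
    if not shuffled:
        return 0.0
    n_u = sum(1 for p in shuffled if not relmap.is_related(protein, p.owner))
    return n_u / len(shuffled)


def empirical_p_value(observed: int, sim_counts: Sequence[int]) -> float:
    """Add-one permutation p-value: (1 + #{sim >= observed}) / (reps + 1);
    never zero, at most one."""
    n = len(sim_counts)
    if n < 1:
        raise ValueError("need at least one replicate")
    return (1 + sum(1 for c in sim_counts if c >= observed)) / (n + 1)


def simulate_null(
    protein: str,
    contacts: Sequence[RDContact],
    pd_peaks_by_protein: Mapping[str, Sequence[Peak]],
    pr_peaks_by_protein: Mapping[str, Sequence[Peak]],
    compartments: LabeledTrack,
    genome: Genome,
    seed: int,
    n_reps: int = N_REPS,
    min_overlap: int = 19,
    ratio_related: float = RATIO_RELATED,
    relmap: RelatednessMap | None = None,
) -> SimulationResult:
    """Null distribution of the triad count for one protein.

    Each replicate shifts the protein's (already extended) PD peaks and
    resamples its PR peaks, then reruns triad assembly on the unshuffled
    contacts with identical parameters.  `contacts` must be the same
    (peak-filtered) set used for the observed count.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if relmap is None:
        relmap = protein_distance_matrix(pr_peaks_by_protein)
    observed = len(
        build_triads(
            contacts,
            {protein: pd_peaks_by_protein[protein]},
            {protein: pr_peaks_by_protein[protein]},
            min_overlap=min_overlap,
        )[protein]
    )
    rng = np.random.default_rng(seed)
    sim_counts: list[int] = []
    for _ in range(n_reps):
        pd_sim = shift_pd_peaks(pd_peaks_by_protein[protein], compartments, genome, rng)
        pr_sim = shuffle_pr_peaks(
            protein, pr_peaks_by_protein, relmap, rng, ratio_related=ratio_related
        )
        count = len(
            build_triads(
                contacts, {protein: pd_sim}, {protein: pr_sim}, min_overlap=min_overlap
            )[protein]
        )
        sim_counts.append(count)
    return SimulationResult(
        protein=protein,
        observed_count=observed,
        sim_counts=tuple(sim_counts),
        empirical_p=empirical_p_value(observed, sim_counts),
        seed=seed,
    )
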