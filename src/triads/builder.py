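"""Triad assembly: intersect RNA-chromatin contacts with protein-DNA and
protein-RNA peaks.

A triad is an (RNA, protein, DNA locus) record: one RNA-DNA contact whose
DNA part lands in a ChIP-seq (protein-DNA) peak of a protein and whose RNA
part lands in an RNA-IP (protein-RNA) peak of the same protein on the same
transcript.  Peaks are extended before intersection to absorb the
restriction/proximity-ligation offset of interactome protocols (2 kbp both
sides for DNA peaks, 100 bp toward the 3' end for RNA peaks), and
intersections shorter than 19 bp are discarded as likely coincidental.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .intervals import Genome, GenomicInterval, extend_interval, intersect_length

BIOTYPES = ("mRNA", "lncRNA", "snoRNA", "XRNA", "pseudogene", "rRNA", "other")

#: extension defaults (bp)
PD_EXTENSION = 2000
PR_EXTENSION = 100
#: minimal peak/contact intersection (bp); shorter overlaps are discarded
MIN_OVERLAP = 19


@dataclass(frozen=True)
class RDContact:
    """One RNA-DNA contact: the RNA part on the source gene plus the
    chromatin locus it was ligated to."""

    rna_id: str
    biotype: str
    rna_part: GenomicInterval
    dna_part: GenomicInterval
    experiment: str = ""
    q_bardic: float = 1.0  # q of the RNA-DNA peak the contact fell in

    def __post_init__(self):
        if self.rna_part.strand not in ("+", "-"):
            raise ValueError("rna_part must be stranded")
        if not 0 < self.q_bardic <= 1:
            raise ValueError("q_bardic must be in (0, 1]")

    @property
    def is_trans(self) -> bool:
        return self.rna_part.chrom != self.dna_part.chrom


@dataclass(frozen=True)
class Peak:
    """A scored peak interval owned by a protein (PD/PR kinds) or an RNA
    (RD kind).  q_value in (0, 1]."""

    owner: str
    interval: GenomicInterval
    q_value: float
    kind: str = "PD"  # {PD, PR, RD}
    biotype: str | None = None

    def __post_init__(self):
        if not 0 < self.q_value <= 1:
            raise ValueError(f"q_value must be in (0, 1], got {self.q_value}")
        if self.kind not in ("PD", "PR", "RD"):
            raise ValueError(f"unknown peak kind {self.kind!r}")


@dataclass(frozen=True)
class Triad:
    rna_id: str
    biotype: str
    protein: str
    contact: RDContact
    pd_peak: Peak
    pr_peak: Peak
    overlap_pd: int
    overlap_pr: int
    hmq: float = field(default=1.0)

    @property
    def dna_part(self) -> GenomicInterval:
        return self.contact.dna_part


def compute_hmq(q_piranha: float, q_macs2: float, q_bardic: float) -> float:
    """Harmonic mean of the three source q-values of a triad.

    HMQ = 3 / (1/q_Piranha + 1/q_MACS2 + 1/q_BaRDIC); lies between the
    smallest and largest of the three and is monotone in each.
    """
    qs = (q_piranha, q_macs2, q_bardic)
    if any(q <= 0 for q in qs):
        raise ValueError("q-values must be positive")
    return 3.0 / sum(1.0 / q for q in qs)


def _tree_by_chrom(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, i
        )
    return trees


def _best_peak(
    target: GenomicInterval,
    peaks: Sequence[Peak],
    trees: Mapping[str, IntervalTree],
    min_overlap: int,
) -> tuple[Peak, int] | None:
    """Peak with maximal overlap >= min_overlap; tie broken toward the
    smaller peak start for deterministic output."""
    tree = trees.get(target.chrom)
    if tree is None:
        return None
    best: tuple[int, int, int] | None = None  # (-overlap, start, index)
    for hit in tree.overlap(target.start, target.end):
        ov = min(target.end, hit.end) - max(target.start, hit.begin)
        if ov >= min_overlap:
            key = (-ov, hit.begin, hit.data)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return peaks[best[2]], -best[0]


def filter_rd_by_peaks(
    contacts: Sequence[RDContact], rd_peaks: Sequence[Peak]
) -> list[RDContact]:
    """Keep contacts whose DNA part falls within (>= 1 bp overlap) an
    RNA-DNA peak called for the same RNA; attach that peak's q-value.

    When several peaks of the RNA overlap the contact, the best-overlap
    peak (tie -> smaller start) supplies the q-value.  Order preserved.
    """
    by_rna: dict[str, list[Peak]] = {}
    for p in rd_peaks:
        by_rna.setdefault(p.owner, []).append(p)
    trees = {rna: _tree_by_chrom(ps) for rna, ps in by_rna.items()}
    kept: list[RDContact] = []
    for c in contacts:
        ps = by_rna.get(c.rna_id)
        if not ps:
            continue
        hit = _best_peak(c.dna_part, ps, trees[c.rna_id], 1)
        if hit is not None:
            kept.append(replace(c, q_bardic=hit[0].q_value))
    return kept


def extend_pd_peaks(
    peaks: Sequence[Peak], genome: Genome, extension: int = PD_EXTENSION
) -> list[Peak]:
    """Widen ChIP-seq peaks by `extension` bp on both sides (clamped)."""
    return [
        replace(p, interval=extend_interval(p.interval, extension, extension, genome))
        for p in peaks
    ]


def extend_pr_peaks(
    peaks: Sequence[Peak], genome: Genome, extension: int = PR_EXTENSION
) -> list[Peak]:
    """Widen RNA-IP peaks by `extension` bp toward the 3' end (strand
    aware; unstranded peaks are rejected since 3' is undefined)."""
    out = []
    for p in peaks:
        iv = p.interval
        if iv.strand == "+":
            ext = extend_interval(iv, 0, extension, genome)
        elif iv.strand == "-":
            ext = extend_interval(iv, extension, 0, genome)
        else:
            raise ValueError(f"PR peak {p.owner} at {iv} has no strand; 3' end undefined")
        out.append(replace(p, interval=ext))
    return out


def build_triads(
    contacts: Sequence[RDContact],
    pd_peaks_by_protein: Mapping[str, Sequence[Peak]],
    pr_peaks_by_protein: Mapping[str, Sequence[Peak]],
    min_overlap: int = MIN_OVERLAP,
) -> dict[str, list[Triad]]:
    """Assemble triads per protein from already-extended peak sets.

    A (contact, protein) pair yields a triad iff the contact's DNA part
    intersects a PD peak of the protein by >= min_overlap bp AND its RNA
    part intersects a PR peak of the protein annotated to the same RNA by
    >= min_overlap bp.  The maximal-overlap peak is recorded on each side
    (tie -> smaller start).  A contact may seed triads with several
    proteins.
    """
    result: dict[str, list[Triad]] = {}
    for protein in pd_peaks_by_protein:
        pd_peaks = list(pd_peaks_by_protein[protein])
        pr_peaks = list(pr_peaks_by_protein.get(protein, []))
        pd_trees = _tree_by_chrom(pd_peaks)
        pr_by_rna: dict[str, list[Peak]] = {}
        for p in pr_peaks:
            pr_by_rna.setdefault(_pr_rna_id(p), []).append(p)
        pr_trees = {rna: _tree_by_chrom(ps) for rna, ps in pr_by_rna.items()}
        triads: list[Triad] = []
        for c in contacts:
            pd_hit = _best_peak(c.dna_part, pd_peaks, pd_trees, min_overlap)
            if pd_hit is None:
                continue
            rna_peaks = pr_by_rna.get(c.rna_id)
            if not rna_peaks:
                continue
            pr_hit = _best_peak(c.rna_part, rna_peaks, pr_trees[c.rna_id], min_overlap)
            if pr_hit is None:
                continue
            pd_peak, ov_pd = pd_hit
            pr_peak, ov_pr = pr_hit
            triads.append(
                Triad(
                    rna_id=c.rna_id,
                    biotype=c.biotype,
                    protein=protein,
                    contact=c,
                    pd_peak=pd_peak,
                    pr_peak=pr_peak,
                    overlap_pd=ov_pd,
                    overlap_pr=ov_pr,
                    hmq=compute_hmq(pr_peak.q_value, pd_peak.q_value, c.q_bardic),
                )
            )
        result[protein] = triads
    return result


def _pr_rna_id(peak: Peak) -> str:
    rna_id = getattr(peak, "rna_id", "")
    if not rna_id:
        raise ValueError(f"PR peak of {peak.owner} lacks an rna_id annotation")
    return rna_id


@dataclass(frozen=True)
class PRPeak(Peak):
    """Protein-RNA peak: `owner` is the protein, `rna_id` the annotated
    transcript the peak sits on."""

    kind: str = "PR"
    rna_id: str = ""

    def __post_init__(self):
        super().__post_init__()
        if not self.rna_id:
            raise ValueError("PR peak needs an rna_id annotation")


def _contacts_shared(a: RDContact, b: RDContact, min_overlap: int = 1) -> bool:
    return a.rna_id == b.rna_id and intersect_length(a.dna_part, b.dna_part) >= min_overlap


def subtract_npm(
    triads_2fa: Sequence[Triad],
    npm: Sequence[RDContact | Triad],
    min_overlap: int = 1,
) -> list[Triad]:
    """Remove triads whose contact is shared with a non-protein-mediated
    (proteinase-treated control) contact: same RNA and DNA parts
    overlapping by >= min_overlap bp.  The survivors are the "CLEAN" set.
    `npm` may be raw control contacts or triads built from them.
    """
    npm_contacts = [x.contact if isinstance(x, Triad) else x for x in npm]
    by_rna: dict[str, list[RDContact]] = {}
    for c in npm_contacts:
        by_rna.setdefault(c.rna_id, []).append(c)
    trees = {
        rna: _tree_by_chrom([Peak(rna, c.dna_part, 1.0, "RD") for c in cs])
        for rna, cs in by_rna.items()
    }
    clean = []
    for t in triads_2fa:
        cs = by_rna.get(t.rna_id)
        if cs:
            tree = trees[t.rna_id].get(t.dna_part.chrom)
            if tree is not None and any(
                min(t.dna_part.end, h.end) - max(t.dna_part.start, h.begin) >= min_overlap
                for h in tree.overlap(t.dna_part.start, t.dna_part.end)
            ):
                continue
        clean.append(t)
    return clean


def shared_triads(
    set_a: Sequence[Triad], set_b: Sequence[Triad]
) -> tuple[list[tuple[Triad, Triad]], list[Triad], list[Triad]]:
    """Triad pairs whose DNA parts overlap (>= 1 bp) and whose RNA parts
    belong to the same transcript.

    Returns (pairs, shared subset of A, shared subset of B); a triad may
    participate in several pairs but appears once in its shared subset.
    """
    by_rna_b: dict[str, list[int]] = {}
    for i, t in enumerate(set_b):
        by_rna_b.setdefault(t.rna_id, []).append(i)
    pairs: list[tuple[Triad, Triad]] = []
    in_a: list[Triad] = []
    hit_b: set[int] = set()
    for ta in set_a:
        matched = False
        for i in by_rna_b.get(ta.rna_id, []):
            tb = set_b[i]
            if intersect_length(ta.dna_part, tb.dna_part) >= 1:
                pairs.append((ta, tb))
                hit_b.add(i)
                matched = True
        if matched:
            in_a.append(ta)
    return pairs, in_a, [set_b[i] for i in sorted(hit_b)]


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

CONTACT_COLUMNS = [
    "rna_chrom", "rna_start", "rna_end", "rna_strand", "rna_id",
    "biotype", "dna_chrom", "dna_start", "dna_end", "experiment",
]

TRIAD_COLUMNS = [
    "rna_id", "biotype", "protein", "dna_chrom", "dna_start", "dna_end",
    "overlap_pd", "overlap_pr", "q_piranha", "q_macs2", "q_bardic", "hmq",
]


def read_contacts(path: str | Path) -> list[RDContact]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                RDContact(
                    rna_id=row["rna_id"],
                    biotype=row["biotype"],
                    rna_part=GenomicInterval(
                        row["rna_chrom"], int(row["rna_start"]),
                        int(row["rna_end"]), row["rna_strand"],
                    ),
                    dna_part=GenomicInterval(
                        row["dna_chrom"], int(row["dna_start"]), int(row["dna_end"])
                    ),
                    experiment=row.get("experiment", ""),
                )
            )
    return out


def write_contacts(contacts: Sequence[RDContact], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(CONTACT_COLUMNS)
        for c in contacts:
            w.writerow([
                c.rna_part.chrom, c.rna_part.start, c.rna_part.end,
                c.rna_part.strand, c.rna_id, c.biotype,
                c.dna_part.chrom, c.dna_part.start, c.dna_part.end, c.experiment,
            ])


def write_scored_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """PD/RD peaks as BED6 with the owner in the name column and
    -log10(q) in the score column (MACS2 convention)."""
    import math as _math

    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.owner}\t"
                f"{-_math.log10(p.q_value):.5g}\t{iv.strand}\n"
            )


def read_scored_peaks(path: str | Path, kind: str = "PD") -> list[Peak]:
    from .intervals import read_bed

    return [
        Peak(name, iv, 10.0 ** (-score), kind) for iv, name, score in read_bed(path)
    ]


PR_PEAK_COLUMNS = ["chrom", "start", "end", "strand", "protein", "rna_id", "biotype", "q_value"]


def write_pr_peaks(peaks: Sequence["PRPeak"], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(PR_PEAK_COLUMNS)
        for p in peaks:
            iv = p.interval
            w.writerow([
                iv.chrom, iv.start, iv.end, iv.strand,
                p.owner, p.rna_id, p.biotype or "other", f"{p.q_value:.6g}",
            ])


def read_pr_peaks(path: str | Path) -> list["PRPeak"]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                PRPeak(
                    owner=row["protein"],
                    interval=GenomicInterval(
                        row["chrom"], int(row["start"]), int(row["end"]), row["strand"]
                    ),
                    q_value=float(row["q_value"]),
                    biotype=row["biotype"],
                    rna_id=row["rna_id"],
                )
            )
    return out


def group_by_owner(peaks: Sequence[Peak]) -> dict[str, list[Peak]]:
    out: dict[str, list[Peak]] = {}
    for p in peaks:
        out.setdefault(p.owner, []).append(p)
    return out


def write_triads(triads: Iterable[Triad], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(TRIAD_COLUMNS)
        for t in triads:
            w.writerow([
                t.rna_id, t.biotype, t.protein,
                t.dna_part.chrom, t.dna_part.start, t.dna_part.end,
                t.overlap_pd, t.overlap_pr,
                f"{t.pr_peak.q_value:.6g}", f"{t.pd_peak.q_value:.6g}",
                f"{t.contact.q_bardic:.6g}", f"{t.hmq:.6g}",
            ])
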