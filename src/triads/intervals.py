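"""Genomic interval arithmetic, labeled tracks and flat-file readers/writers.

Coordinates are 0-based, half-open (BED convention) everywhere in the
package; readers of 1-based dialects convert at the boundary.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


class Genome:
    """Chromosome name -> length (bp) registry.

    Parameters
    ----------
    chrom_sizes : mapping of chromosome name to length in bp; all lengths
        must be positive.
    """

    def __init__(self, chrom_sizes: Mapping[str, int]):
        sizes = dict(chrom_sizes)
        if not sizes:
            raise ValueError("genome must declare at least one chromosome")
        for name, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.chrom_sizes: dict[str, int] = sizes

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __iter__(self):
        return iter(self.chrom_sizes)

    def __len__(self) -> int:
        return len(self.chrom_sizes)

    def size(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self.chrom_sizes == other.chrom_sizes

    def __repr__(self) -> str:
        return f"Genome({len(self.chrom_sizes)} chromosomes, {self.total_size()} bp)"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + self.width // 2

    def __len__(self) -> int:
        return self.width


def intersect_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared base positions between two intervals (0 if on
    different chromosomes or merely abutting)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def extend_interval(
    iv: GenomicInterval, left: int, right: int, genome: Genome
) -> GenomicInterval:
    """Widen an interval by `left`/`right` bp, clamped to [0, chrom length]."""
    if left < 0 or right < 0:
        raise ValueError("extensions must be non-negative")
    length = genome.size(iv.chrom)
    return replace(iv, start=max(0, iv.start - left), end=min(length, iv.end + right))


class LabeledTrack:
    """A genome partition into labeled blocks (A/B compartments, grouped
    chromatin states...).

    Per chromosome the blocks must be sorted and non-overlapping.  Gaps
    are permitted; querying a position inside a gap returns
    ``default_label`` if one was declared, otherwise raises.
    """

    def __init__(
        self,
        intervals: Iterable[tuple[GenomicInterval, str]],
        default_label: str | None = None,
    ):
        by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
        for iv, label in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv, label))
        self._starts: dict[str, list[int]] = {}
        self._blocks: dict[str, list[tuple[GenomicInterval, str]]] = {}
        labels: set[str] = set()
        for chrom, pairs in by_chrom.items():
            pairs.sort(key=lambda p: p[0].start)
            for (a, _), (b, _) in zip(pairs, pairs[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"overlapping track blocks on {chrom}: {a} and {b}"
                    )
            self._blocks[chrom] = pairs
            self._starts[chrom] = [iv.start for iv, _ in pairs]
            labels.update(label for _, label in pairs)
        self.labels = labels
        self.default_label = default_label

    def __iter__(self):
        for chrom in self._blocks:
            yield from self._blocks[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._blocks.values())

    def blocks(self, chrom: str) -> list[tuple[GenomicInterval, str]]:
        return self._blocks.get(chrom, [])

    def label_at(self, chrom: str, pos: int) -> str:
        """Label of the block containing position `pos` (half-open)."""
        starts = self._starts.get(chrom)
        if starts:
            i = bisect_right(starts, pos) - 1
            if i >= 0:
                iv, label = self._blocks[chrom][i]
                if pos < iv.end:
                    return label
        if self.default_label is not None:
            return self.default_label
        raise KeyError(f"position {chrom}:{pos} not covered by track and no default label")

    def label_bp(self) -> dict[str, int]:
        """Total covered bp per label."""
        out: dict[str, int] = {}
        for iv, label in self:
            out[label] = out.get(label, 0) + iv.width
        return out


def label_of(iv: GenomicInterval, track: LabeledTrack) -> str:
    """Track label at the midpoint of `iv` (midpoint rule: stable under
    symmetric extension, unambiguous on half-open partitions)."""
    return track.label_at(iv.chrom, iv.midpoint)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per chromosome (strand ignored)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: v.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def binned_coverage(
    intervals: Sequence[GenomicInterval], genome: Genome, bin_size: int
) -> dict[str, np.ndarray]:
    """Covered bp per fixed-size bin, per chromosome.

    Overlapping input intervals are merged first, so coverage is a set
    property of the input (idempotent under duplication).  Bin vectors
    have length ceil(chrom_length / bin_size).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    out = {
        chrom: np.zeros(math.ceil(length / bin_size), dtype=np.int64)
        for chrom, length in genome.chrom_sizes.items()
    }
    for iv in merge_intervals(list(intervals)):
        vec = out[iv.chrom]
        first, last = iv.start // bin_size, (iv.end - 1) // bin_size
        for b in range(first, last + 1):
            lo = max(iv.start, b * bin_size)
            hi = min(iv.end, (b + 1) * bin_size)
            vec[b] += hi - lo
    return out


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> Genome:
    """Two-column TSV: chromosome name, length."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, length = line.split("\t")[:2]
        sizes[name] = int(length)
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{l}\n" for c, l in genome.chrom_sizes.items())
    )


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    """BED3/BED6 reader.

    Returns (interval, name, score) tuples; missing name -> "", missing
    score -> nan.  Scores follow the MACS2 convention of -log10(q) when
    the file carries peak q-values.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        strand = f[5] if len(f) > 5 else "."
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]), strand)
        name = f[3] if len(f) > 3 else ""
        score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else float("nan")
        rows.append((iv, name, score))
    return rows


def write_bed(
    rows: Iterable[tuple[GenomicInterval, str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv, name, score in rows:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def read_narrowpeak(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    """ENCODE narrowPeak reader; returns (interval, name, q_value) with
    the q-value decoded from the -log10 in column 9."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5] if f[5] in STRANDS else ".")
        q = 10.0 ** (-float(f[8]))
        rows.append((iv, f[3], q))
    return rows


def read_labeled_track(
    path: str | Path, default_label: str | None = None
) -> LabeledTrack:
    """LabeledTrack from a BED file with the label in the name column."""
    return LabeledTrack(
        [(iv, name) for iv, name, _ in read_bed(path)], default_label=default_label
    )


def write_labeled_track(track: LabeledTrack, path: str | Path) -> None:
    write_bed(((iv, label, 0.0) for iv, label in track), path)
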