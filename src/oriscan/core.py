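"""Domain types, interval algebra and readers/writers shared by every stage.

Coordinates are 0-based half-open (BED convention) everywhere internally;
1-based coordinates appear only in user-facing display. All interval
writers emit sorted, tab-delimited, newline-terminated text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from scipy import stats

VALID_BASES = frozenset("ACGTN")

_BASE_CLEAN = str.maketrans(
    {c: ("N" if c not in "ACGTN" else c) for c in map(chr, range(65, 91))}
)


@dataclass
class GenomeSequence:
    """A named chromosome: an uppercase string over the {A,C,G,T,N} alphabet."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().translate(_BASE_CLEAN)
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"{self.name}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(order=True)
class GenomicInterval:
    """Half-open genomic interval with optional strand and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", slop: int = 0) -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end + slop
            and other.start - slop < self.end
        )


class CoverageTrack:
    """Piecewise-constant non-negative read-count track for one chromosome.

    Stored as sorted, non-overlapping (start, end, value) runs; queries
    integrate the per-base value over an arbitrary range.
    """

    def __init__(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if not (len(starts) == len(ends) == len(values)):
            raise ValueError("starts/ends/values length mismatch")
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(values < 0):
            raise ValueError("coverage values must be non-negative")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("coverage intervals overlap")
        self.chrom = chrom
        self.starts, self.ends, self.values = starts, ends, values

    @classmethod
    def from_intervals(cls, intervals: Sequence[GenomicInterval]) -> "CoverageTrack":
        if not intervals:
            raise ValueError("empty coverage")
        chroms = {iv.chrom for iv in intervals}
        if len(chroms) != 1:
            raise ValueError("one chromosome per track")
        return cls(
            intervals[0].chrom,
            [iv.start for iv in intervals],
            [iv.end for iv in intervals],
            [iv.score if iv.score is not None else 0.0 for iv in intervals],
        )

    def sum_over(self, start: int, end: int) -> float:
        """Integral of the per-base value over [start, end)."""
        lo = np.clip(self.starts, start, end)
        hi = np.clip(self.ends, start, end)
        return float(np.sum((hi - lo) * self.values))

    def per_base(self, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start, dtype=float)
        for s, e, v in zip(self.starts, self.ends, self.values):
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out[lo - start : hi - start] = v
        return out


# ---------------------------------------------------------------------------
# Readers / writers


def read_fasta(path) -> dict[str, GenomeSequence]:
    """Read a multi-record FASTA into {name: GenomeSequence}.

    Sequences are uppercased; characters outside {A,C,G,T,N} become N.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise ValueError(f"{path}: line 1: not a FASTA header")
    records: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record {rec.id!r}")
        records[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(path, genomes: Iterable[GenomeSequence], width: int = 60) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, g.length, width):
                fh.write(g.seq[i : i + width] + "\n")


def read_intervals(path, dialect: str = "BED6") -> list[GenomicInterval]:
    """Read BED3/BED6/bedGraph intervals, returned sorted by (chrom, start).

    Strand defaults to "." when absent; bedGraph's 4th column becomes the
    interval score.
    """
    if dialect not in ("BED3", "BED6", "bedGraph"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            strand, score = ".", None
            if dialect == "bedGraph":
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
                score = float(fields[3])
            elif dialect == "BED6" and len(fields) >= 6:
                score = float(fields[4]) if fields[4] != "." else None
                strand = fields[5]
            out.append(GenomicInterval(chrom, start, end, strand, score))
    out.sort()
    return out


def write_intervals(path, intervals: Sequence[GenomicInterval], dialect: str = "BED6") -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            if dialect == "BED3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bedGraph":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.score:g}\n")
            else:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# Interval algebra


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for ivs in out.values():
        ivs.sort()
    return out


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= max_gap (book-ended merge at 0)."""
    merged: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        cur_start = cur_end = None
        for iv in _by_chrom(intervals)[chrom]:
            if cur_end is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_end is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def cluster_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int
) -> list[tuple[GenomicInterval, int]]:
    """Assign dense cluster ids; consecutive intervals share an id iff their
    gap is <= max_gap. Ids increase along (chrom, start)."""
    out: list[tuple[GenomicInterval, int]] = []
    cid = -1
    for chrom in sorted(_by_chrom(intervals)):
        prev_end = None
        for iv in _by_chrom(intervals)[chrom]:
            if prev_end is None or iv.start - prev_end > max_gap:
                cid += 1
                prev_end = iv.end
            else:
                prev_end = max(prev_end, iv.end)
            out.append((iv, cid))
    return out


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    genome: Mapping[str, int],
    seed: int,
    same_chrom: bool = True,
    no_overlap: bool = True,
    exclude: Sequence[GenomicInterval] | None = None,
    max_tries: int = 1000,
) -> list[GenomicInterval]:
    """Place length-preserving random copies of ``intervals`` on ``genome``.

    ``genome`` maps chromosome name to length. With ``same_chrom`` each
    interval stays on its chromosome; otherwise chromosomes are drawn with
    probability proportional to the number of valid start positions.
    """
    rng = np.random.default_rng(seed)
    placed = _by_chrom(exclude) if exclude else {}
    excluded_fixed = {c: list(ivs) for c, ivs in placed.items()}
    result: list[GenomicInterval] = []
    chrom_names = sorted(genome)

    def conflicts(chrom: str, start: int, end: int) -> bool:
        for iv in excluded_fixed.get(chrom, []):
            if iv.start < end and start < iv.end:
                return True
        if no_overlap:
            for s, e in placed_new.get(chrom, []):
                if s < end and start < e:
                    return True
        return False

    placed_new: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        length = iv.length
        for _ in range(max_tries):
            if same_chrom:
                chrom = iv.chrom
            else:
                weights = np.array(
                    [max(genome[c] - length + 1, 0) for c in chrom_names], dtype=float
                )
                if weights.sum() == 0:
                    raise ValueError("no chromosome can hold interval")
                chrom = chrom_names[rng.choice(len(chrom_names), p=weights / weights.sum())]
            limit = genome[chrom] - length
            if limit < 0:
                raise ValueError(f"interval longer than chromosome {chrom}")
            start = int(rng.integers(0, limit + 1))
            if not conflicts(chrom, start, start + length):
                placed_new.setdefault(chrom, []).append((start, start + length))
                result.append(GenomicInterval(chrom, start, start + length, iv.strand))
                break
        else:
            raise RuntimeError(
                f"could not place {length}-bp interval after {max_tries} tries"
            )
    result.sort()
    return result


def overlap_count(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    slop: int = 0,
) -> int:
    """Number of A intervals sharing >=1 base with any B after extending B
    symmetrically by ``slop``. Each A counts once."""
    b_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in _by_chrom(b).items():
        ext = merge_intervals(
            [
                GenomicInterval(chrom, max(iv.start - slop, 0), iv.end + slop)
                for iv in ivs
            ]
        )
        b_by_chrom[chrom] = (
            np.array([iv.start for iv in ext]),
            np.array([iv.end for iv in ext]),
        )
    count = 0
    for iv in a:
        if iv.chrom not in b_by_chrom:
            continue
        starts, ends = b_by_chrom[iv.chrom]
        i = int(np.searchsorted(ends, iv.start, side="right"))
        if i < len(starts) and starts[i] < iv.end:
            count += 1
    return count


def overlap_flags(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval], slop: int = 0
) -> np.ndarray:
    """Boolean per-A flags for overlap with merged, slop-extended B."""
    b_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in _by_chrom(b).items():
        ext = merge_intervals(
            [
                GenomicInterval(chrom, max(iv.start - slop, 0), iv.end + slop)
                for iv in ivs
            ]
        )
        b_by_chrom[chrom] = (
            np.array([iv.start for iv in ext]),
            np.array([iv.end for iv in ext]),
        )
    flags = np.zeros(len(a), dtype=bool)
    for k, iv in enumerate(a):
        if iv.chrom not in b_by_chrom:
            continue
        starts, ends = b_by_chrom[iv.chrom]
        i = int(np.searchsorted(ends, iv.start, side="right"))
        flags[k] = i < len(starts) and starts[i] < iv.end
    return flags


def chisq_gof_enrichment(
    observed_overlap: float, n_total: int, expected_overlap: float
) -> tuple[float, float]:
    """Chi-square goodness of fit on the two categories {overlap, no overlap}.

    chi2 = (O-E)^2/E + ((n-O)-(n-E))^2/(n-E), 1 degree of freedom. Works for
    depletion (O < E) identically.
    """
    if not 0 < expected_overlap < n_total:
        raise ValueError("expected overlap must lie strictly inside (0, n_total)")
    o = np.array([observed_overlap, n_total - observed_overlap], dtype=float)
    e = np.array([expected_overlap, n_total - expected_overlap], dtype=float)
    chi2 = float(np.sum((o - e) ** 2 / e))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def expected_overlap_by_shuffle(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    genome: Mapping[str, int],
    seed: int,
    n_shuffles: int = 100,
    slop: int = 0,
    **shuffle_kwargs,
) -> float:
    """Mean overlap count of shuffled copies of A with B over seeded shuffles."""
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(n_shuffles):
        shuffled = shuffle_intervals(
            a, genome, seed=int(rng.integers(0, 2**31 - 1)), **shuffle_kwargs
        )
        total += overlap_count(shuffled, b, slop=slop)
    return total / n_shuffles


def nearest_distances(
    a_points: Sequence[GenomicInterval],
    b_points: Sequence[GenomicInterval],
    max_dist: int,
) -> list[float]:
    """Signed distances from each A point to every B point within max_dist.

    Distances are oriented by A's strand: negative means upstream of A.
    Points are taken as interval midpoints. Equidistant up/downstream
    neighbours both appear (all hits within range are reported).
    """
    b_pos: dict[str, np.ndarray] = {}
    for chrom, ivs in _by_chrom(b_points).items():
        b_pos[chrom] = np.array(sorted(iv.midpoint for iv in ivs))
    out: list[float] = []
    for a in a_points:
        if a.chrom not in b_pos:
            continue
        pos = b_pos[a.chrom]
        apos = a.midpoint
        lo = int(np.searchsorted(pos, apos - max_dist, side="left"))
        hi = int(np.searchsorted(pos, apos + max_dist, side="right"))
        for b in pos[lo:hi]:
            d = float(b - apos)
            if a.strand == "-":
                d = -d
            out.append(d)
    return out


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of the unions of A and B, as merged intervals."""
    a_m = _by_chrom(merge_intervals(a))
    b_m = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for chrom in sorted(set(a_m) & set(b_m)):
        ai = bi = 0
        avs, bvs = a_m[chrom], b_m[chrom]
        while ai < len(avs) and bi < len(bvs):
            lo = max(avs[ai].start, bvs[bi].start)
            hi = min(avs[ai].end, bvs[bi].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if avs[ai].end < bvs[bi].end:
                ai += 1
            else:
                bi += 1
    return out


def genome_sizes(genomes: Mapping[str, GenomeSequence]) -> dict[str, int]:
    return {name: g.length for name, g in genomes.items()}


def total_covered(intervals: Sequence[GenomicInterval]) -> int:
    """Total bases covered by the union of intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))
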