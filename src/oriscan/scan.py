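"""Paired-window G-rich hyper-motif genome scan.

The scanner slides paired 500-bp windows (default 100-bp stride) across each
chromosome and retains pairs whose base composition matches the origin
hyper-motif: a G-rich first window followed by a less-G-rich second window
(minimum 28% / 25% G, an 8-40 percentage-point G drop, and A and T each
capped at 21% over the combined pair). Both strand orientations are
evaluated — the reverse rule is the exact C-based mirror — and retained
pairs are merged into candidate origin regions carrying the dominant
orientation. A simple G-density caller for G-rich regions lives here too.

All threshold comparisons at stated minima/maxima are inclusive, except the
G-rich caller's documented strict ">37%". N bases count in window
denominators and match no nucleotide, so N-rich windows fail the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

from .core import GenomeSequence, GenomicInterval

# slack for count/window fractions compared against decimal thresholds
_EPS = 1e-9

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class HyperMotifParams:
    """Thresholds of the paired-window hyper-motif."""

    window: int = 500
    step: int = 100
    g1_min: float = 0.28
    g2_min: float = 0.25
    drop_min: float = 0.08
    drop_max: float = 0.40
    at_max: float = 0.21

    def __post_init__(self) -> None:
        if not (0 < self.g2_min <= self.g1_min < 1):
            raise ValueError("need 0 < g2_min <= g1_min < 1")
        if not (0 <= self.drop_min <= self.drop_max < 1):
            raise ValueError("need 0 <= drop_min <= drop_max < 1")
        if self.window % self.step:
            raise ValueError("window must be divisible by step")


@dataclass
class WindowPair:
    """Two consecutive windows with their per-base composition fractions."""

    chrom: str
    start: int
    comp1: dict[str, float]
    comp2: dict[str, float]
    orientation: str | None = None


def _base_cumsums(seq: str) -> dict[str, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return {
        b: np.concatenate(([0], np.cumsum(arr == ord(b), dtype=np.int64)))
        for b in BASES
    }


def _window_counts(
    cums: Mapping[str, np.ndarray], starts: np.ndarray, window: int
) -> dict[str, np.ndarray]:
    return {b: cums[b][starts + window] - cums[b][starts] for b in BASES}


def pair_compositions(
    genome: GenomeSequence, window: int = 500, step: int = 100
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Vectorised base-fraction arrays for every complete window pair.

    Returns (pair starts, first-window fractions, second-window fractions);
    fractions use the window length as denominator, so N bases dilute all
    four nucleotide fractions.
    """
    last = genome.length - 2 * window
    if last < 0:
        empty = np.array([], dtype=np.int64)
        return empty, {b: empty.astype(float) for b in BASES}, {
            b: empty.astype(float) for b in BASES
        }
    starts = np.arange(0, last + 1, step, dtype=np.int64)
    cums = _base_cumsums(genome.seq)
    c1 = {b: v / window for b, v in _window_counts(cums, starts, window).items()}
    c2 = {
        b: v / window
        for b, v in _window_counts(cums, starts + window, window).items()
    }
    return starts, c1, c2


def window_compositions(
    genome: GenomeSequence, window: int = 500, step: int = 100
) -> Iterator[WindowPair]:
    """Stream of WindowPair objects (thin view over pair_compositions)."""
    starts, c1, c2 = pair_compositions(genome, window, step)
    for i, s in enumerate(starts):
        yield WindowPair(
            genome.name,
            int(s),
            {b: float(c1[b][i]) for b in BASES},
            {b: float(c2[b][i]) for b in BASES},
        )


def _orientation_masks(
    c1: Mapping[str, np.ndarray],
    c2: Mapping[str, np.ndarray],
    params: HyperMotifParams,
) -> tuple[np.ndarray, np.ndarray]:
    a_pair = (np.asarray(c1["A"]) + np.asarray(c2["A"])) / 2.0
    t_pair = (np.asarray(c1["T"]) + np.asarray(c2["T"])) / 2.0
    at_ok = (a_pair <= params.at_max + _EPS) & (t_pair <= params.at_max + _EPS)

    g1, g2 = np.asarray(c1["G"]), np.asarray(c2["G"])
    drop = g1 - g2
    fwd = (
        (g1 >= params.g1_min - _EPS)
        & (g2 >= params.g2_min - _EPS)
        & (drop >= params.drop_min - _EPS)
        & (drop <= params.drop_max + _EPS)
        & at_ok
    )
    # mirror rule: on the reverse strand G reads as C and window roles swap
    r1, r2 = np.asarray(c2["C"]), np.asarray(c1["C"])
    rdrop = r1 - r2
    rev = (
        (r1 >= params.g1_min - _EPS)
        & (r2 >= params.g2_min - _EPS)
        & (rdrop >= params.drop_min - _EPS)
        & (rdrop <= params.drop_max + _EPS)
        & at_ok
    )
    return fwd, rev


def hypermotif_orientations(
    pair: WindowPair, params: HyperMotifParams | None = None
) -> tuple[bool, bool]:
    """(forward retained, reverse retained) for a single window pair."""
    params = params or HyperMotifParams()
    c1 = {b: np.array([pair.comp1[b]]) for b in BASES}
    c2 = {b: np.array([pair.comp2[b]]) for b in BASES}
    fwd, rev = _orientation_masks(c1, c2, params)
    return bool(fwd[0]), bool(rev[0])


def hypermotif_filter(pair: WindowPair, params: HyperMotifParams | None = None) -> bool:
    """True iff the pair is retained in either orientation."""
    fwd, rev = hypermotif_orientations(pair, params)
    return fwd or rev


@dataclass
class ScanResult:
    regions: list[GenomicInterval]
    retained_pairs: int
    retained_starts: dict[str, np.ndarray]   # per-chromosome retained pair starts
    retained_strands: dict[str, np.ndarray]  # '+'/'-' per retained pair

    def candidates(self, window: int = 500) -> list[GenomicInterval]:
        """Retained pairs as oriented pair-footprint intervals."""
        out = []
        for chrom in sorted(self.retained_starts):
            for s, st in zip(self.retained_starts[chrom], self.retained_strands[chrom]):
                out.append(GenomicInterval(chrom, int(s), int(s) + 2 * window, str(st)))
        return out


def scan_chromosome(
    genome: GenomeSequence, params: HyperMotifParams | None = None
) -> tuple[list[GenomicInterval], np.ndarray, np.ndarray, np.ndarray]:
    """Scan one chromosome.

    Returns (merged candidate regions with dominant orientation in the
    strand field, retained pair starts, forward/reverse flags per retained
    pair). A pair position retained by both orientations is counted once.
    """
    params = params or HyperMotifParams()
    starts, c1, c2 = pair_compositions(genome, params.window, params.step)
    fwd, rev = _orientation_masks(c1, c2, params)
    keep = fwd | rev
    kept_starts = starts[keep]
    kept_fwd, kept_rev = fwd[keep], rev[keep]

    span = 2 * params.window
    regions: list[GenomicInterval] = []
    i = 0
    n = len(kept_starts)
    while i < n:
        j = i
        cur_end = kept_starts[i] + span
        while j + 1 < n and kept_starts[j + 1] <= cur_end:
            j += 1
            cur_end = max(cur_end, kept_starts[j] + span)
        n_fwd = int(kept_fwd[i : j + 1].sum())
        n_rev = int(kept_rev[i : j + 1].sum())
        strand = "+" if n_fwd >= n_rev else "-"
        regions.append(
            GenomicInterval(genome.name, int(kept_starts[i]), int(cur_end), strand)
        )
        i = j + 1
    return regions, kept_starts, kept_fwd, kept_rev


def scan_genome(
    genomes: Mapping[str, GenomeSequence] | GenomeSequence,
    params: HyperMotifParams | None = None,
) -> ScanResult:
    """Run the hyper-motif scan over one or many chromosomes.

    Candidate regions are the book-ended merge of retained pair footprints
    ([start, start + 2*window)); each carries the dominant orientation
    (ties go to forward). The retained-pair count de-duplicates positions
    retained by both orientations.
    """
    params = params or HyperMotifParams()
    if isinstance(genomes, GenomeSequence):
        genomes = {genomes.name: genomes}
    all_regions: list[GenomicInterval] = []
    retained_starts: dict[str, np.ndarray] = {}
    retained_strands: dict[str, np.ndarray] = {}
    total = 0
    for name in sorted(genomes):
        regions, kept_starts, kept_fwd, _ = scan_chromosome(genomes[name], params)
        all_regions.extend(regions)
        retained_starts[name] = kept_starts
        # a pair retained by both orientations is reported once, as forward
        retained_strands[name] = np.where(kept_fwd, "+", "-")
        total += len(kept_starts)
    return ScanResult(sorted(all_regions), total, retained_starts, retained_strands)


def grich_regions(
    genome: GenomeSequence,
    g_min: float = 0.37,
    window: int = 500,
    step: int = 100,
) -> list[GenomicInterval]:
    """Merged regions where the windowed G fraction strictly exceeds g_min."""
    last = genome.length - window
    if last < 0:
        return []
    starts = np.arange(0, last + 1, step, dtype=np.int64)
    cums = _base_cumsums(genome.seq)
    g = _window_counts(cums, starts, window)["G"] / window
    kept = starts[g > g_min + _EPS]
    regions: list[GenomicInterval] = []
    for s in kept:
        s = int(s)
        if regions and s <= regions[-1].end:
            regions[-1] = GenomicInterval(
                genome.name, regions[-1].start, max(regions[-1].end, s + window)
            )
        else:
            regions.append(GenomicInterval(genome.name, s, s + window))
    return regions
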