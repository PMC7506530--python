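"""Seeded synthetic genomes with planted origin signatures.

The generator emulates the statistical structure the analysis assumes:

* background sequence i.i.d. at the mammalian genomic base fractions
  (A = T = 0.30, G = C = 0.20);
* planted oriented origin cassettes — a G-rich 500-bp window followed by a
  less-G-rich 500-bp window whose composition satisfies every hyper-motif
  threshold with a wide margin, half planted reverse-complemented. The
  G-rich window of origin cassettes is CpG-structured (C and G laid down
  as CG dinucleotide tokens), echoing the CpG-island character of strong
  origins;
* optional decoy cassettes with the *same* base composition but shuffled
  (CpG-poor) G-rich windows: indistinguishable to the composition-only
  scanner, separable by dinucleotide features — these play the role of
  G-rich elements that host no origin;
* optional out-of-threshold cassettes (flat G profile with no G drop and
  A/T above the cap) for scanner specificity checks;
* log-normal per-origin activity observed through Poisson counts across
  samples, over a Poisson background, producing the strongly skewed
  Q1-Q10 activity spread;
* read pileups around a true summit placed 300 bp downstream (in the
  origin frame) of the cassette boundary;
* TADs tiling the genome with a tunable origin-density border enrichment.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import CoverageTrack, GenomeSequence, GenomicInterval, revcomp
from .repertoire import ActivityMatrix

BASES = ("A", "C", "G", "T")

# Cassette compositions: chosen so that every scanner threshold holds with
# a >= ~3 SD margin at the worst window phase (see docs/methods.md).
DEFAULT_UP = {"A": 0.10, "C": 0.28, "G": 0.52, "T": 0.10}
DEFAULT_DOWN = {"A": 0.19, "C": 0.29, "G": 0.33, "T": 0.19}
# Flat G-rich profile that violates both the G-drop range and the A/T cap.
OFFTHRESHOLD = {"A": 0.225, "C": 0.180, "G": 0.370, "T": 0.225}


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic genome."""

    genome_length: int = 10_000_000
    chrom: str = "sim1"
    base_probs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.30, "C": 0.20, "G": 0.20, "T": 0.30}
    )
    n_origins: int = 500
    n_decoys: int = 0
    n_offthreshold: int = 0
    up_len: int = 500
    down_len: int = 500
    up_comp: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UP))
    down_comp: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DOWN))
    min_spacing: int = 3_000
    n_samples: int = 19
    activity_mu: float = 1.0      # log-normal location of latent activity
    activity_sigma: float = 1.7   # spread; puts ~80% of signal in the top 2 deciles
    background_rate: float = 1.0  # Poisson background counts per origin/sample
    summit_offset: int = 300      # true summit downstream of the cassette boundary
    read_spread: float = 50.0     # SD of read positions around the true summit
    reads_per_origin: int = 500
    tad_count: int = 20
    border_factor: float = 1.53   # origin-density enrichment of TAD border bins
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs.values()) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")


@dataclass
class TruthSet:
    """Ground truth of the planted configuration."""

    origins: list[GenomicInterval]        # cassette footprints, oriented
    boundaries: list[int]                 # G-rich / downstream window boundary
    true_summits: list[int]
    decoys: list[GenomicInterval]
    offthreshold: list[GenomicInterval]
    mean_activity: np.ndarray | None = None
    tads: list[GenomicInterval] | None = None
    border_factor: float | None = None


def _sample_window(rng: np.random.Generator, comp: dict[str, float], length: int) -> str:
    probs = np.array([comp[b] for b in BASES])
    idx = rng.choice(4, size=length, p=probs / probs.sum())
    return "".join(BASES[i] for i in idx)


def _target_counts(comp: dict[str, float], length: int) -> dict[str, int]:
    counts = {b: int(round(comp[b] * length)) for b in BASES}
    # fix rounding drift on the most abundant base
    drift = length - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    return counts


def _cpg_window(rng: np.random.Generator, comp: dict[str, float], length: int) -> str:
    """Window with exact composition and C/G laid down as CG tokens."""
    c = _target_counts(comp, length)
    k = min(c["C"], c["G"])
    tokens = (
        ["CG"] * k
        + ["G"] * (c["G"] - k)
        + ["C"] * (c["C"] - k)
        + ["A"] * c["A"]
        + ["T"] * c["T"]
    )
    rng.shuffle(tokens)
    return "".join(tokens)


def _shuffled_window(rng: np.random.Generator, comp: dict[str, float], length: int) -> str:
    """Window with the same exact composition but no dinucleotide structure."""
    c = _target_counts(comp, length)
    bases = list("".join(b * c[b] for b in BASES))
    rng.shuffle(bases)
    return "".join(bases)


def _place_nonoverlapping(
    rng: np.random.Generator, n: int, span: int, spacing: int, genome_length: int
) -> np.ndarray:
    """Uniformly distributed sorted starts with pairwise gaps >= spacing.

    Uses the spacing-removal construction: draw n sorted uniforms on the
    slack, then re-insert the mandatory span+spacing offsets — uniform
    over all valid configurations and free of rejection loops.
    """
    slack = genome_length - n * span - (n - 1) * spacing
    if slack < 0:
        raise ValueError("cannot place cassettes: genome too short for spacing")
    u = np.sort(rng.integers(0, slack + 1, size=n))
    return u + np.arange(n) * (span + spacing)


def generate_genome(spec: SyntheticSpec) -> tuple[GenomeSequence, TruthSet]:
    """Background genome with planted origin / decoy / off-threshold cassettes.

    Cassette starts are uniform with the configured minimum spacing; half
    of each cassette class (rounded down) is planted reverse-complemented.
    """
    rng = np.random.default_rng(spec.seed)
    probs = np.array([spec.base_probs[b] for b in BASES])
    idx = rng.choice(4, size=spec.genome_length, p=probs / probs.sum())
    lut = np.frombuffer("".join(BASES).encode(), dtype=np.uint8)
    seq_arr = lut[idx]

    span = spec.up_len + spec.down_len
    n_total = spec.n_origins + spec.n_decoys + spec.n_offthreshold
    origins: list[GenomicInterval] = []
    boundaries: list[int] = []
    summits: list[int] = []
    decoys: list[GenomicInterval] = []
    off: list[GenomicInterval] = []
    if n_total:
        starts = _place_nonoverlapping(
            rng, n_total, span, spec.min_spacing, spec.genome_length
        )
        kinds = (
            ["origin"] * spec.n_origins
            + ["decoy"] * spec.n_decoys
            + ["off"] * spec.n_offthreshold
        )
        rng.shuffle(kinds)
        rev_countdown = {
            "origin": spec.n_origins // 2,
            "decoy": spec.n_decoys // 2,
            "off": spec.n_offthreshold // 2,
        }
        for start, kind in zip(starts, kinds):
            start = int(start)
            if kind == "origin":
                up = _cpg_window(rng, spec.up_comp, spec.up_len)
                down = _sample_window(rng, spec.down_comp, spec.down_len)
            elif kind == "decoy":
                up = _shuffled_window(rng, spec.up_comp, spec.up_len)
                down = _sample_window(rng, spec.down_comp, spec.down_len)
            else:
                up = _sample_window(rng, OFFTHRESHOLD, spec.up_len)
                down = _sample_window(rng, OFFTHRESHOLD, spec.down_len)
            cassette = up + down
            reverse = rev_countdown[kind] > 0
            if reverse:
                rev_countdown[kind] -= 1
                cassette = revcomp(cassette)
            seq_arr[start : start + span] = np.frombuffer(
                cassette.encode(), dtype=np.uint8
            )
            strand = "-" if reverse else "+"
            iv = GenomicInterval(spec.chrom, start, start + span, strand)
            if kind == "origin":
                boundary = start + (spec.down_len if reverse else spec.up_len)
                summit = boundary + (-spec.summit_offset if reverse else spec.summit_offset)
                origins.append(iv)
                boundaries.append(boundary)
                summits.append(summit)
            elif kind == "decoy":
                decoys.append(iv)
            else:
                off.append(iv)

    genome = GenomeSequence(spec.chrom, seq_arr.tobytes().decode("ascii"))
    return genome, TruthSet(origins, boundaries, summits, decoys, off)


def simulate_activity(truth: TruthSet, spec: SyntheticSpec) -> ActivityMatrix:
    """Log-normal latent activity per origin, Poisson counts per sample.

    Background counts are Poisson at ``background_rate``. The truth set's
    ``mean_activity`` records the latent (expected) activities.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = len(truth.origins)
    latent = rng.lognormal(spec.activity_mu, spec.activity_sigma, size=n)
    counts = rng.poisson(latent[:, None], size=(n, spec.n_samples)).astype(float)
    background = rng.poisson(
        spec.background_rate, size=(n, spec.n_samples)
    ).astype(float)
    truth.mean_activity = latent
    samples = [f"sample_{j + 1}" for j in range(spec.n_samples)]
    return ActivityMatrix(list(truth.origins), samples, counts, background)


def simulate_coverage(truth: TruthSet, spec: SyntheticSpec) -> CoverageTrack:
    """Read pileup around each origin's true summit as a coverage track."""
    rng = np.random.default_rng(spec.seed + 2)
    positions: list[np.ndarray] = []
    for summit in truth.true_summits:
        reads = np.rint(
            rng.normal(summit, spec.read_spread, size=spec.reads_per_origin)
        ).astype(np.int64)
        positions.append(np.clip(reads, 0, spec.genome_length - 1))
    if not positions:
        return CoverageTrack(spec.chrom, [], [], [])
    pos = np.concatenate(positions)
    per_base = np.bincount(pos, minlength=spec.genome_length)
    nz = np.flatnonzero(per_base)
    # compress identical-value runs of consecutive bases
    breaks = np.flatnonzero(
        (np.diff(nz) != 1) | (np.diff(per_base[nz]) != 0)
    )
    starts = nz[np.concatenate(([0], breaks + 1))]
    ends = nz[np.concatenate((breaks, [len(nz) - 1]))] + 1
    values = per_base[starts]
    return CoverageTrack(spec.chrom, starts, ends, values.astype(float))


def simulate_tads(
    spec: SyntheticSpec, border_factor: float | None = None, n_placed: int = 10_000
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Equal TADs tiling the genome plus origins placed with border enrichment.

    Placement probability is proportional to ``border_factor`` in the 20
    border bins (1-10, 91-100 of 100) and 1 elsewhere; positions are
    uniform within the chosen bin.
    """
    bf = spec.border_factor if border_factor is None else border_factor
    rng = np.random.default_rng(spec.seed + 3)
    tad_len = spec.genome_length // spec.tad_count
    tads = [
        GenomicInterval(spec.chrom, i * tad_len, (i + 1) * tad_len)
        for i in range(spec.tad_count)
    ]
    weights = np.ones(100)
    weights[:10] = bf
    weights[90:] = bf
    weights = weights / weights.sum()
    placed: list[GenomicInterval] = []
    tad_idx = rng.integers(0, spec.tad_count, size=n_placed)
    bins = rng.choice(100, size=n_placed, p=weights)
    bin_len = tad_len / 100.0
    offsets = rng.random(n_placed)
    for t, b, u in zip(tad_idx, bins, offsets):
        pos = int(tads[t].start + (b + u) * bin_len)
        pos = min(pos, tads[t].end - 1)
        placed.append(GenomicInterval(spec.chrom, pos, pos + 1))
    return tads, sorted(placed)
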