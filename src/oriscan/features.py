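"""Sequence predictors for genome-scan candidates.

Each retained window pair gets 22 sequence features computed over a 4-kb
span centred on the boundary between its two 500-bp windows, in the pair's
own orientation (reverse-oriented candidates are read off the reverse
complement, so "UP" is always the G-rich side of the motif):

* UP_/Down_{A,C,G,T}_fraction — base fractions of the upstream and
  downstream 2 kb;
* G_content_2kb / G_content_4kb — G fraction of the central 2 kb / 4 kb;
* rampG — least-squares slope of the G fraction across eight 500-bp
  segments of the span, per kb;
* CC, CG, GG, GC, CGCG, AAA, TTT, GGG, CCC — overlapping k-mer counts per
  kb of the central 1-kb pair;
* log10_inter_candidate_distance — log10 of the centre-to-centre distance
  to the nearest other candidate, capped at 6;
* at_max_pair — max of the A and T fractions over the central pair.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomeSequence, GenomicInterval, overlap_flags, revcomp

FEATURE_NAMES: tuple[str, ...] = (
    "UP_A_fraction",
    "UP_C_fraction",
    "UP_G_fraction",
    "UP_T_fraction",
    "Down_A_fraction",
    "Down_C_fraction",
    "Down_G_fraction",
    "Down_T_fraction",
    "G_content_2kb",
    "G_content_4kb",
    "rampG",
    "CC",
    "CG",
    "GG",
    "GC",
    "CGCG",
    "AAA",
    "TTT",
    "GGG",
    "CCC",
    "log10_inter_candidate_distance",
    "at_max_pair",
)

_KMERS = ("CC", "CG", "GG", "GC", "CGCG", "AAA", "TTT", "GGG", "CCC")

FLANK = 2_000          # half-width of the feature span around the pair centre
SEGMENT = 500          # rampG segment length
MAX_LOG_DIST = 6.0


def _fraction(seq: str, base: str) -> float:
    return seq.count(base) / len(seq) if seq else 0.0


def _kmer_density_per_kb(seq: str, kmer: str) -> float:
    if len(seq) < len(kmer):
        return 0.0
    count = 0
    start = seq.find(kmer)
    while start != -1:
        count += 1
        start = seq.find(kmer, start + 1)  # overlapping occurrences
    return count / (len(seq) / 1000.0)


def _ramp_g(seq: str, center_off: int) -> float:
    """Slope of the G fraction over full 500-bp segments of the span, per kb."""
    xs, ys = [], []
    for i in range(2 * FLANK // SEGMENT):
        lo = center_off - FLANK + i * SEGMENT
        hi = lo + SEGMENT
        if lo < 0 or hi > len(seq):
            continue  # clipped at a chromosome edge
        xs.append((lo + hi) / 2.0 - center_off)
        ys.append(_fraction(seq[lo:hi], "G"))
    if len(xs) < 2:
        return 0.0
    slope = np.polyfit(np.array(xs) / 1000.0, ys, 1)[0]
    return float(slope)


def extract_features(
    genome: GenomeSequence,
    candidate: GenomicInterval,
    all_centers: Sequence[int] | None = None,
    window: int = 500,
) -> dict[str, float]:
    """Feature vector of one candidate pair position.

    ``candidate`` spans the pair footprint ([start, start + 2*window)) and
    carries its orientation in the strand field. ``all_centers`` are the
    pair centres of every candidate on the same chromosome (used for the
    inter-candidate distance). Spans are truncated at chromosome edges and
    fractions use the available bases.
    """
    center = candidate.start + window
    lo, hi = max(center - FLANK, 0), min(center + FLANK, genome.length)
    if lo >= hi:
        raise ValueError("candidate span entirely off chromosome")
    seq = genome.seq[lo:hi]
    center_off = center - lo
    if candidate.strand == "-":
        seq = revcomp(seq)
        center_off = len(seq) - center_off

    up = seq[:center_off]
    down = seq[center_off:]
    central2 = seq[max(center_off - 1000, 0) : center_off + 1000]
    pair = seq[max(center_off - window, 0) : center_off + window]

    feats: dict[str, float] = {}
    for b in "ACGT":
        feats[f"UP_{b}_fraction"] = _fraction(up, b)
        feats[f"Down_{b}_fraction"] = _fraction(down, b)
    feats["G_content_2kb"] = _fraction(central2, "G")
    feats["G_content_4kb"] = _fraction(seq, "G")
    feats["rampG"] = _ramp_g(seq, center_off)
    for k in _KMERS:
        feats[k] = _kmer_density_per_kb(pair, k)
    if all_centers is not None and len(all_centers) > 1:
        others = np.asarray([c for c in all_centers if c != center])
        if others.size:
            dist = float(np.min(np.abs(others - center)))
            feats["log10_inter_candidate_distance"] = min(
                np.log10(max(dist, 1.0)), MAX_LOG_DIST
            )
        else:
            feats["log10_inter_candidate_distance"] = MAX_LOG_DIST
    else:
        feats["log10_inter_candidate_distance"] = MAX_LOG_DIST
    feats["at_max_pair"] = max(_fraction(pair, "A"), _fraction(pair, "T"))
    return feats


def feature_matrix(
    genomes: Mapping[str, GenomeSequence],
    candidates: Sequence[GenomicInterval],
    origins: Sequence[GenomicInterval] | None = None,
    window: int = 500,
) -> pd.DataFrame:
    """Candidates x 22 feature matrix plus a 0/1 ``label`` column.

    A candidate is labelled 1 iff its pair footprint shares at least one
    base with an origin interval. Row order follows the input candidates;
    column order is ``FEATURE_NAMES`` then ``label``.
    """
    centers_by_chrom: dict[str, list[int]] = {}
    for c in candidates:
        centers_by_chrom.setdefault(c.chrom, []).append(c.start + window)
    rows = [
        extract_features(
            genomes[c.chrom], c, centers_by_chrom[c.chrom], window=window
        )
        for c in candidates
    ]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if origins is not None and len(origins):
        df["label"] = overlap_flags(candidates, origins).astype(int)
    else:
        df["label"] = 0
    return df
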